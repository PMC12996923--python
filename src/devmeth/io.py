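"""Readers and writers for the pipeline's tabular and region formats.

Tabular files are TSV with a header row; regions are BED6 (0-based,
half-open); gene sets are GMT. Manifest positions are 1-based on disk and in
memory — only BED output converts.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd

from .types import BetaMatrix, GeneSetCollection, ProbeManifest, RegionSet, SampleSheet

logger = logging.getLogger(__name__)


def read_beta_matrix(path, manifest: ProbeManifest | None = None) -> BetaMatrix:
    """Read a probes-x-samples beta TSV, restricted to manifest probes.

    The first column is the probe id; remaining columns are samples. A
    malformed numeric cell or a value outside [0, 1] (beyond 1e-9) raises a
    hard error naming the offending cell. Probes absent from the manifest
    are dropped with a logged count.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    data = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            probe = raw.index[bad][0]
            raise ValueError(
                f"malformed numeric value {raw.loc[probe, col]!r} at "
                f"probe {probe!r}, sample {col!r} in {path}")
        if converted.isna().any():
            probe = raw.index[converted.isna()][0]
            raise ValueError(f"missing beta value at probe {probe!r}, "
                             f"sample {col!r} in {path}")
        out_of_range = (converted < -1e-9) | (converted > 1 + 1e-9)
        if out_of_range.any():
            probe = raw.index[out_of_range][0]
            raise ValueError(
                f"beta value {converted[out_of_range].iloc[0]} outside [0,1] "
                f"at probe {probe!r}, sample {col!r} in {path}")
        data[col] = converted
    if manifest is not None:
        keep = data.index.isin(manifest.probe_ids)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("%d probes in %s absent from manifest; dropped",
                           n_drop, path)
        data = data.loc[keep]
    return BetaMatrix(data)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.data.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")


def read_manifest(path) -> ProbeManifest:
    tab = pd.read_csv(path, sep="\t", index_col=0,
                      dtype={"chrom": str}, keep_default_na=False,
                      na_values=[])
    tab["pos"] = tab["pos"].astype(int)
    tab["genes"] = [tuple(g.split(";")) if g else () for g in tab["genes"]]
    for col in ("flagged", "mfg_change_flagged", "autosomal"):
        tab[col] = tab[col].map(
            {"True": True, "False": False, True: True, False: False})
    return ProbeManifest(tab)


def write_manifest(manifest: ProbeManifest, path) -> None:
    tab = manifest.table.copy()
    tab["genes"] = [";".join(g) for g in tab["genes"]]
    tab.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path) -> SampleSheet:
    tab = pd.read_csv(path, sep="\t", index_col=0, dtype={"chip_id": str})
    return SampleSheet(tab)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index_label="sample_id",
                       float_format="%.12g")


def read_regions(path) -> RegionSet:
    """Read a BED file (first four columns used; extra columns ignored)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def write_regions(regions: RegionSet, path, scores=None) -> None:
    """Write BED6 (score column 0 unless given; strand '.')."""
    t = regions.sorted().table
    with open(path, "w") as fh:
        for i, row in enumerate(t.itertuples(index=False)):
            score = 0 if scores is None else scores[i]
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}"
                     f"\t{score:g}\t.\n")


def write_dmr_bed(dmrs, path) -> None:
    """Export called DMRs as BED6.

    Internal DMR coordinates are 1-based inclusive outermost probe
    positions; the BED line is 0-based half-open (start-1, end). The name
    is the annotated gene symbols joined by ";" and the score is
    -log10(adjusted P) capped at 1000.
    """
    with open(path, "w") as fh:
        for dmr in dmrs:
            name = ";".join(dmr.genes) if dmr.genes else "."
            if dmr.adjusted_p <= 0:
                score = 1000.0
            else:
                score = max(0.0, min(1000.0, -math.log10(dmr.adjusted_p)))
            fh.write(f"{dmr.chrom}\t{dmr.start - 1}\t{dmr.end}\t{name}"
                     f"\t{score:g}\t.\n")


def read_gmt(path) -> GeneSetCollection:
    terms = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            # de-duplicate while preserving order
            genes = tuple(dict.fromkeys(g for g in parts[2:] if g))
            terms[parts[0]] = (parts[1], genes)
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for tid, (name, genes) in collection.terms.items():
            fh.write("\t".join([tid, name, *genes]) + "\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
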