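"""Core domain types for the methylation analysis pipeline.

The central container is :class:`BetaMatrix` (probes x samples, beta values in
[0, 1]); :class:`ProbeManifest` carries per-probe genomic coordinates and
annotations; :class:`SampleSheet` carries per-sample design covariates.
Genomic conventions: manifest positions are 1-based single-bp coordinates;
exported interval sets (:class:`RegionSet`) are BED-style 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURES = ("promoter", "gene_body", "intergenic")
BIOTYPES = ("protein_coding", "snoRNA", "other_noncoding", "NA")
GENOTYPES = ("WT", "HET")
AGE_LABELS = ("E14.5", "E18.5", "P7", "P35", "P70")

#: Days since E14.5 for each developmental stage (E-stages are gestational;
#: birth falls at ~E19, so P7 = 4.5 + 19 + ... ~ 26 days after E14.5).
AGE_DAYS = {"E14.5": 0.0, "E18.5": 4.0, "P7": 26.0, "P35": 54.0, "P70": 89.0}

BETA_TOL = 1e-9


class DataValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class ProbeManifest:
    """Per-probe annotation table.

    ``table`` is indexed by probe id with columns ``chrom`` (str; ``"0"``
    permitted on input but removed by QC), ``pos`` (1-based bp), ``genes``
    (tuple of gene symbols, possibly empty), ``feature``, ``biotype``,
    ``flagged`` (manifest technical-variability flag), ``mfg_change_flagged``
    and ``autosomal``.
    """

    table: pd.DataFrame

    REQUIRED = ("chrom", "pos", "genes", "feature", "biotype",
                "flagged", "mfg_change_flagged", "autosomal")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataValidationError(f"manifest missing columns: {missing}")
        if not self.table.index.is_unique:
            dup = self.table.index[self.table.index.duplicated()][:5].tolist()
            raise DataValidationError(f"duplicate probe ids in manifest: {dup}")
        pos = self.table["pos"]
        if (pos < 1).any():
            raise DataValidationError("manifest positions must be >= 1 (1-based)")
        bad_feat = set(self.table["feature"]) - set(FEATURES)
        if bad_feat:
            raise DataValidationError(f"unknown feature classes: {sorted(bad_feat)}")
        bad_bio = set(self.table["biotype"]) - set(BIOTYPES)
        if bad_bio:
            raise DataValidationError(f"unknown biotypes: {sorted(bad_bio)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def autosomal_ids(self) -> pd.Index:
        return self.table.index[self.table["autosomal"].astype(bool)]

    def gene_probe_pairs(self, feature: str | None = None) -> pd.DataFrame:
        """Explode the ``genes`` column into (gene, probe_id) rows.

        A probe annotated to several genes contributes one row per gene.
        ``feature="promoter"`` restricts to promoter probes.
        """
        tab = self.table
        if feature is not None:
            tab = tab[tab["feature"] == feature]
        rows = [(g, pid) for pid, gs in tab["genes"].items() for g in gs]
        return pd.DataFrame(rows, columns=["gene", "probe_id"])

    def gene_biotypes(self) -> pd.Series:
        """Map each annotated gene to its biotype (first seen wins)."""
        out: dict[str, str] = {}
        for _, row in self.table.iterrows():
            for g in row["genes"]:
                out.setdefault(g, row["biotype"])
        return pd.Series(out, dtype=object)

    def gene_bodies(self) -> pd.DataFrame:
        """Per-gene 1-based inclusive span of its annotated probes."""
        pairs = self.gene_probe_pairs()
        pairs = pairs.join(self.table[["chrom", "pos"]], on="probe_id")
        grp = pairs.groupby("gene")
        out = grp.agg(chrom=("chrom", "first"),
                      start=("pos", "min"), end=("pos", "max"))
        return out.reset_index()


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation proportions.

    All values must lie in [0, 1] (a tolerance of 1e-9 is forgiven and
    clipped); missing values are disallowed after QC and rejected here.
    """

    data: pd.DataFrame  # index = probe ids, columns = sample ids

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float, copy=False)
        if np.isnan(vals).any():
            raise DataValidationError("beta matrix contains missing values")
        lo, hi = vals.min(initial=0.0), vals.max(initial=1.0)
        if lo < -BETA_TOL or hi > 1 + BETA_TOL:
            r, c = np.unravel_index(
                int(np.argmax((vals < -BETA_TOL) | (vals > 1 + BETA_TOL))),
                vals.shape)
            raise DataValidationError(
                f"beta value {vals[r, c]!r} outside [0,1] at probe "
                f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}")
        if lo < 0 or hi > 1:
            self.data = self.data.clip(0.0, 1.0)
        if not self.data.index.is_unique or not self.data.columns.is_unique:
            raise DataValidationError("probe and sample ids must be unique")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[list(probe_ids)])

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.data[list(sample_ids)])


@dataclass
class SampleSheet:
    """Per-sample design table: genotype, age, chip, derived covariates."""

    table: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        t = self.table
        for col in ("genotype", "age_label", "chip_id"):
            if col not in t.columns:
                raise DataValidationError(f"sample sheet missing column {col!r}")
        if not t.index.is_unique:
            raise DataValidationError("duplicate sample ids")
        if t["genotype"].isna().any() or t["age_label"].isna().any():
            raise DataValidationError("genotype and age_label must be non-missing")
        bad_gt = set(t["genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise DataValidationError(f"unknown genotypes: {sorted(bad_gt)}")
        bad_age = set(t["age_label"]) - set(AGE_LABELS)
        if bad_age:
            raise DataValidationError(f"unknown age labels: {sorted(bad_age)}")
        if "age_days" not in t.columns:
            t = t.copy()
            t["age_days"] = t["age_label"].map(AGE_DAYS)
            self.table = t
        for col in ("neuronal_prop", "pseudo_age"):
            if col not in self.table.columns:
                self.table[col] = np.nan

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class RegionSet:
    """A set of named genomic intervals, 0-based half-open (BED convention)."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "name"]))

    def __post_init__(self) -> None:
        t = self.table
        for col in ("chrom", "start", "end", "name"):
            if col not in t.columns:
                raise DataValidationError(f"region set missing column {col!r}")
        if len(t) and (t["start"] >= t["end"]).any():
            raise DataValidationError("regions must satisfy start < end")

    def sorted(self) -> "RegionSet":
        t = self.table.sort_values(["chrom", "start", "end"],
                                   kind="mergesort").reset_index(drop=True)
        return RegionSet(t)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCollection:
    """term_id -> (term name, member gene symbols)."""

    terms: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if len(set(genes)) != len(genes):
                raise DataValidationError(f"duplicate genes within term {tid!r}")

    def members(self, term_id: str) -> tuple[str, ...]:
        return self.terms[term_id][1]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)
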