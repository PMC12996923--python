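"""Differentially methylated region calling.

A DMR is a run of more than one consecutive tested probe in which every
probe has a nominally significant genotype effect (P < 0.05) in the same
direction and every adjacent pair is spaced strictly less than 1500 bp
apart. By default an intervening tested probe that is non-significant or of
opposite sign terminates a run (consecutive is read as consecutive among
tested probes); ``skip_nonsignificant=True`` gives the permissive reading
in which such probes are ignored and only distance between qualifying
probes matters. Member P values are combined with Empirical Brown's method
and region P values are Bonferroni-adjusted over the number of candidate
regions considered genome-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .brown import brown_combine
from .types import BetaMatrix, ProbeManifest

logger = logging.getLogger(__name__)


@dataclass
class DmrResult:
    chrom: str
    start: int                 # outermost probe positions, 1-based inclusive
    end: int
    probe_ids: list[str]
    direction: str             # "hypo" | "hyper"
    combined_p: float
    adjusted_p: float = float("nan")
    genes: list[str] = field(default_factory=list)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def _candidate_runs(positions, pvals, signs, gap_bp, nominal_p,
                    skip_nonsignificant):
    """Maximal qualifying runs over one chromosome's tested probes."""
    runs = []
    current: list[int] = []
    current_sign = 0
    for i in range(len(positions)):
        qualifies = pvals[i] < nominal_p and signs[i] != 0
        if not qualifies:
            if not skip_nonsignificant:
                if len(current) >= 2:
                    runs.append(current)
                current, current_sign = [], 0
            continue
        if current and (signs[i] == current_sign
                        and positions[i] - positions[current[-1]] < gap_bp):
            current.append(i)
        else:
            if len(current) >= 2:
                runs.append(current)
            current, current_sign = [i], signs[i]
    if len(current) >= 2:
        runs.append(current)
    return runs


def call_dmrs(probe_results: pd.DataFrame, manifest: ProbeManifest,
              beta: BetaMatrix, gap_bp: int = 1500,
              nominal_p: float = 0.05,
              skip_nonsignificant: bool = False) -> list[DmrResult]:
    """Scan each chromosome for qualifying probe runs and combine P values.

    ``probe_results`` holds the tested probes (``p_genotype``,
    ``direction``); probes are sorted by position internally (logged when
    the manifest order needed fixing). The Bonferroni denominator is the
    number of candidate regions found genome-wide.
    """
    tab = manifest.table.loc[
        manifest.table.index.intersection(probe_results.index),
        ["chrom", "pos"]]
    merged = tab.join(probe_results[["p_genotype", "direction"]], how="inner")

    candidates: list[DmrResult] = []
    for chrom, sub in merged.groupby("chrom", sort=True):
        if not sub["pos"].is_monotonic_increasing:
            logger.info("probes on %s not position-sorted; sorting", chrom)
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy()
        p = sub["p_genotype"].to_numpy(dtype=float)
        sgn = sub["direction"].to_numpy(dtype=int)
        for run in _candidate_runs(pos, p, sgn, gap_bp, nominal_p,
                                   skip_nonsignificant):
            probes = list(sub.index[run])
            combined = brown_combine(
                p[run], beta.data.loc[probes].to_numpy(dtype=float))
            candidates.append(DmrResult(
                chrom=str(chrom), start=int(pos[run[0]]),
                end=int(pos[run[-1]]), probe_ids=probes,
                direction="hypo" if sgn[run[0]] < 0 else "hyper",
                combined_p=combined))

    n_candidates = len(candidates)
    for dmr in candidates:
        dmr.adjusted_p = min(1.0, dmr.combined_p * n_candidates)
    candidates.sort(key=lambda d: (d.chrom, d.start))
    return candidates


def annotate_dmrs(dmrs: list[DmrResult], gene_bodies: pd.DataFrame,
                  pad_bp: int = 1500) -> list[DmrResult]:
    """Annotate each DMR to genes whose body, expanded by ``pad_bp`` on each
    side, overlaps it (closed-interval overlap on 1-based coordinates).

    ``gene_bodies`` columns: gene, chrom, start, end (1-based inclusive).
    """
    by_chrom = {c: g for c, g in gene_bodies.groupby("chrom")}
    for dmr in dmrs:
        genes: list[str] = []
        sub = by_chrom.get(dmr.chrom)
        if sub is not None:
            hit = ((sub["start"] - pad_bp <= dmr.end)
                   & (sub["end"] + pad_bp >= dmr.start))
            genes = sorted(sub.loc[hit, "gene"])
        dmr.genes = genes
    return dmrs


def dmrs_to_frame(dmrs: list[DmrResult]) -> pd.DataFrame:
    rows = [(d.chrom, d.start, d.end, d.n_probes, d.direction,
             d.combined_p, d.adjusted_p, ";".join(d.genes),
             ";".join(d.probe_ids)) for d in dmrs]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes",
                                       "direction", "combined_p",
                                       "adjusted_p", "genes", "probe_ids"])
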