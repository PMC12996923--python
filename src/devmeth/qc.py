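"""Sample QC gates, probe filtering, quantile normalization and the
variable-probe rule that defines the analysis background.

Detection P values are consumed as precomputed summaries (per-sample failure
fractions and per-probe failure counts); intensity-level computation is out
of scope. QC runs before normalization; variable-probe selection runs after,
on the normalized matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import BetaMatrix, ProbeManifest

logger = logging.getLogger(__name__)

REMOVAL_REASONS = ("flagged_manifest", "mfg_change_flagged", "chrom0",
                   "detection_fail", "none")


@dataclass
class SampleQcSummary:
    """Signal-intensity and detection summaries for one sample."""

    sample_id: str
    median_meth_intensity: float
    median_unmeth_intensity: float
    frac_probes_failing_detection: float
    bisulfite_conversion_pct: float


@dataclass
class SampleQcThresholds:
    min_median_intensity: float = 2000.0
    max_detection_fail_frac: float = 0.01
    min_bisulfite_pct: float = 90.0   # inclusive pass


def apply_sample_qc(summaries: list[SampleQcSummary],
                    thresholds: SampleQcThresholds | None = None
                    ) -> pd.DataFrame:
    """Evaluate each sample against intensity/detection/conversion gates.

    Returns a frame indexed by sample id with a ``passed`` flag and the
    first failed criterion (empty string when passing). Intensity and
    conversion thresholds pass inclusively; the detection-failure fraction
    must be below its maximum (strict).
    """
    thresholds = thresholds or SampleQcThresholds()
    rows = []
    for s in summaries:
        failed = ""
        if min(s.median_meth_intensity,
               s.median_unmeth_intensity) < thresholds.min_median_intensity:
            failed = "intensity"
        elif s.frac_probes_failing_detection >= thresholds.max_detection_fail_frac:
            failed = "detection"
        elif s.bisulfite_conversion_pct < thresholds.min_bisulfite_pct:
            failed = "bisulfite_conversion"
        rows.append((s.sample_id, failed == "", failed))
    return pd.DataFrame(rows, columns=["sample_id", "passed", "failed_criterion"]
                        ).set_index("sample_id")


def filter_probes(beta: BetaMatrix, manifest: ProbeManifest,
                  detection_fail_counts: pd.Series,
                  max_fail_samples: int = 1
                  ) -> tuple[BetaMatrix, pd.DataFrame]:
    """Remove flagged, MFG-change-flagged, chromosome-0 and detection-failing
    probes.

    A probe is removed for detection failure only when it fails in more
    than ``max_fail_samples`` samples (the study rule: more than 1). Each
    removed probe gets exactly one removal reason, assigned in the fixed
    precedence order flagged_manifest > mfg_change_flagged > chrom0 >
    detection_fail; the retained set is independent of that order.
    """
    tab = manifest.table.loc[manifest.table.index.intersection(beta.probe_ids)]
    status = pd.DataFrame(index=beta.probe_ids)
    status["removed_reason"] = "none"
    fails = detection_fail_counts.reindex(beta.probe_ids).fillna(0)

    detect = fails > max_fail_samples
    chrom0 = tab["chrom"].reindex(beta.probe_ids).eq("0").fillna(False)
    mfg = tab["mfg_change_flagged"].reindex(beta.probe_ids).fillna(False)
    flagged = tab["flagged"].reindex(beta.probe_ids).fillna(False)
    status.loc[detect, "removed_reason"] = "detection_fail"
    status.loc[chrom0, "removed_reason"] = "chrom0"
    status.loc[mfg.astype(bool), "removed_reason"] = "mfg_change_flagged"
    status.loc[flagged.astype(bool), "removed_reason"] = "flagged_manifest"

    keep = status["removed_reason"] == "none"
    logger.info("probe filtering removed %d of %d probes",
                int((~keep).sum()), len(keep))
    return beta.subset_probes(beta.probe_ids[keep]), status


def quantile_normalize(beta: BetaMatrix) -> BetaMatrix:
    """Force every sample onto the across-sample mean sorted distribution.

    Ties within a sample receive the average of the reference values at
    their rank positions. Normalizing an already-normalized matrix is a
    fixed point. A single-sample matrix is returned unchanged with a
    warning.
    """
    X = beta.data.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    if n_samples < 2:
        logger.warning("quantile normalization is identity for one sample")
        return BetaMatrix(beta.data.copy())
    reference = np.sort(X, axis=0).mean(axis=1)
    ranks = beta.data.rank(axis=0, method="average").to_numpy() - 1.0
    out = np.empty_like(X)
    grid = np.arange(n_probes, dtype=float)
    for j in range(n_samples):
        out[:, j] = np.interp(ranks[:, j], grid, reference)
    return BetaMatrix(pd.DataFrame(out, index=beta.probe_ids,
                                   columns=beta.sample_ids))


def select_variable_probes(beta: BetaMatrix, min_range: float = 0.05,
                           inner_fraction: float = 0.8) -> pd.Series:
    """Flag probes whose beta range across the inner 80% of samples exceeds
    the threshold.

    Per probe the sample values are sorted and the range between the
    lower and upper quantiles bounding the inner ``inner_fraction`` of
    samples (10th and 90th percentiles by default, linear-interpolation
    quantiles) is computed; a probe is variable iff that range is strictly
    greater than ``min_range``.
    """
    if beta.shape[1] < 3:
        raise ValueError("variable-probe selection requires >= 3 samples")
    tail = (1.0 - inner_fraction) / 2.0
    X = beta.data.to_numpy(dtype=float)
    lo = np.quantile(X, tail, axis=1)
    hi = np.quantile(X, 1.0 - tail, axis=1)
    return pd.Series(hi - lo > min_range, index=beta.probe_ids,
                     name="is_variable")
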