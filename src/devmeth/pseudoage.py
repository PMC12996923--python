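"""DNA methylation pseudo-age: weighted sums over age-associated sites.

The score for a sample is sum_i s_i * beta_i over a panel of clock sites,
where s_i is the per-day OLS slope of methylation on chronological age at
site i. The score is a raw weighted sum — no intercept and no rescaling to
days — so it is unitless and only its association with age is meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import BetaMatrix, DataValidationError, SampleSheet

logger = logging.getLogger(__name__)


@dataclass
class ClockModel:
    """Age-clock site ids and their methylation-per-day slopes."""

    site_ids: list[str]
    slopes: np.ndarray

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        if len(self.site_ids) != len(self.slopes):
            raise DataValidationError("site_ids and slopes length mismatch")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise DataValidationError("clock site ids must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site_id": self.site_ids, "slope": self.slopes})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ClockModel":
        return cls(list(frame["site_id"]), frame["slope"].to_numpy())


def fit_clock(reference_beta: BetaMatrix, ages) -> ClockModel:
    """Per-site OLS slope of beta on chronological age (days).

    ``ages`` is a per-sample vector aligned to the matrix columns; at least
    3 distinct ages are required.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != reference_beta.shape[1]:
        raise ValueError("ages must align with the matrix samples")
    if len(np.unique(ages)) < 3:
        raise ValueError("fitting a clock requires >= 3 distinct ages")
    x = ages - ages.mean()
    denom = float(x @ x)
    y = reference_beta.data.to_numpy(dtype=float)
    slopes = (y - y.mean(axis=1, keepdims=True)) @ x / denom
    return ClockModel(list(reference_beta.probe_ids), slopes)


def score_samples(beta: BetaMatrix, clock: ClockModel) -> pd.Series:
    """Pseudo-age score per sample: sum of slope * beta over clock sites.

    Clock sites missing from the matrix are dropped with a warning; zero
    available sites is an error.
    """
    present = [i for i, sid in enumerate(clock.site_ids)
               if sid in beta.data.index]
    n_missing = len(clock.site_ids) - len(present)
    if not present:
        raise ValueError("no clock sites present in the beta matrix")
    if n_missing:
        logger.warning("%d of %d clock sites absent from beta matrix; "
                       "scoring on the remainder", n_missing, len(clock.site_ids))
    sites = [clock.site_ids[i] for i in present]
    weights = clock.slopes[present]
    scores = weights @ beta.data.loc[sites].to_numpy(dtype=float)
    return pd.Series(scores, index=beta.sample_ids, name="pseudo_age")


def test_age_genotype_effects(scores: pd.Series, samples: SampleSheet) -> dict:
    """Linear model score ~ age_days + genotype (HET vs WT).

    Returns the age slope per day and the genotype effect, each with a
    two-sided t-test P value.
    """
    t = samples.table.loc[scores.index]
    n = len(scores)
    if n < 4:
        raise ValueError("insufficient degrees of freedom: need >= 4 samples")
    X = np.column_stack([np.ones(n),
                         t["age_days"].to_numpy(float),
                         (t["genotype"] == "HET").to_numpy(float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is rank deficient (age or genotype constant)")
    y = scores.to_numpy(float)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    pvals = np.where(se > 0, pvals, 1.0)
    return {
        "age_slope": float(coef[1]), "age_se": float(se[1]),
        "age_p": float(pvals[1]),
        "genotype_effect": float(coef[2]), "genotype_se": float(se[2]),
        "genotype_p": float(pvals[2]),
    }
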