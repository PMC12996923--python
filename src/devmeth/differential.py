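"""Probe-level differential methylation.

Main model (per probe, OLS):

    normalized beta ~ genotype + age + chip + neuronal proportion

with age categorical (E14.5 reference), genotype coded 0/1 (WT reference;
negative coefficients mean hypomethylated in the heterozygote), and the
estimated neuronal proportion as a continuous covariate. The genotype
effect is tested with a two-sided t-test. Genotype-by-age interactions are
tested by an F contrast of this model against

    normalized beta ~ genotype * age + chip + neuronal proportion

with numerator df = (number of ages - 1). Fits are vectorised across
probes: the design matrix is shared, so coefficients for all probes come
from one least-squares solve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import AGE_LABELS, BetaMatrix, SampleSheet

_TINY_P = np.finfo(float).tiny


def build_design(samples: SampleSheet, interaction: bool = False
                 ) -> pd.DataFrame:
    """Shared design matrix; raises naming aliased columns if rank deficient."""
    t = samples.table
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(t))}
    cols["genotype_HET"] = (t["genotype"] == "HET").to_numpy(float)
    ages = [a for a in AGE_LABELS if a in set(t["age_label"])]
    for a in ages[1:]:
        cols[f"age_{a}"] = (t["age_label"] == a).to_numpy(float)
    chips = sorted(t["chip_id"].unique())
    for c in chips[1:]:
        cols[f"chip_{c}"] = (t["chip_id"] == c).to_numpy(float)
    if t["neuronal_prop"].notna().all():
        cols["neuronal_prop"] = t["neuronal_prop"].to_numpy(float)
    elif t["neuronal_prop"].notna().any():
        raise ValueError("neuronal_prop is partially missing")
    if interaction:
        for a in ages[1:]:
            cols[f"genotype_HET:age_{a}"] = (cols["genotype_HET"]
                                             * cols[f"age_{a}"])
    X = pd.DataFrame(cols, index=t.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR-like greedy scan
        aliased = []
        kept: list[str] = []
        for name in X.columns:
            trial = X[kept + [name]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(name)
            else:
                aliased.append(name)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return X


def _ols_all_probes(Y: np.ndarray, X: np.ndarray):
    """Coefficients, residual sums of squares and (X'X)^-1 for every probe."""
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ Y          # p x n_probes
    resid = Y - X @ coef
    rss = (resid ** 2).sum(axis=0)
    return coef, rss, XtX_inv


def fit_probe_models(beta: BetaMatrix, samples: SampleSheet) -> pd.DataFrame:
    """Per-probe OLS genotype effect with covariate adjustment.

    Returns a frame indexed by probe id with ``beta_genotype``, ``se``,
    ``p_genotype`` and ``direction``. Probes with a zero-variance fit
    (constant beta) get coefficient 0 and P = 1 by convention.
    """
    Xdf = build_design(samples)
    X = Xdf.to_numpy(dtype=float)
    g = list(Xdf.columns).index("genotype_HET")
    Y = beta.data.to_numpy(dtype=float).T      # samples x probes
    n, p = X.shape
    coef, rss, XtX_inv = _ols_all_probes(Y, X)
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = rss / df
    se = np.sqrt(sigma2 * XtX_inv[g, g])
    b = coef[g]
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = b / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), _TINY_P, 1.0)
    # constant probes: zero-variance fit, coefficient 0 and P = 1
    constant = Y.max(axis=0) - Y.min(axis=0) == 0
    b = np.where(constant, 0.0, b)
    pvals = np.where(constant, 1.0, pvals)
    out = pd.DataFrame({
        "beta_genotype": b, "se": se, "p_genotype": pvals,
        "direction": np.sign(b).astype(int),
    }, index=beta.probe_ids)
    return out


def test_interaction(beta: BetaMatrix, samples: SampleSheet) -> pd.DataFrame:
    """Nested-model F test of genotype-by-age interaction per probe."""
    X0 = build_design(samples, interaction=False).to_numpy(dtype=float)
    X1 = build_design(samples, interaction=True).to_numpy(dtype=float)
    Y = beta.data.to_numpy(dtype=float).T
    n = X0.shape[0]
    df_num = X1.shape[1] - X0.shape[1]
    df_den = n - X1.shape[1]
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom for interaction model")
    _, rss0, _ = _ols_all_probes(Y, X0)
    _, rss1, _ = _ols_all_probes(Y, X1)
    diff = np.maximum(rss0 - rss1, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (diff / df_num) / (rss1 / df_den)
    # identical fits (diff == 0) -> F = 0, P = 1, including zero-variance probes
    F = np.where(diff <= 1e-300, 0.0, F)
    F = np.where(np.isfinite(F), F, np.inf)
    p = stats.f.sf(F, df_num, df_den)
    p = np.clip(p, _TINY_P, 1.0)
    return pd.DataFrame({"F_interaction": F, "p_interaction": p,
                         "df_num": df_num, "df_den": df_den},
                        index=beta.probe_ids)


def bonferroni_dmps(results: pd.DataFrame, n_tests: int | None = None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Classify DMPs at the Bonferroni-adjusted threshold alpha / n_tests.

    ``n_tests`` defaults to the number of probes actually tested; pass the
    full post-QC site count to reproduce the genome-wide convention (with
    262,086 sites the threshold prints as 1.91e-07). Classification is
    strict: P exactly at the threshold is not a DMP.
    """
    if n_tests is None:
        n_tests = len(results)
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = alpha / n_tests
    out = results.copy()
    out["bonferroni_threshold"] = threshold
    out["is_dmp"] = out["p_genotype"] < threshold
    out["dmp_direction"] = np.where(
        ~out["is_dmp"], "",
        np.where(out["direction"] < 0, "hypo", "hyper"))
    return out
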