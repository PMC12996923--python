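"""Empirical Brown's method for combining dependent P values.

Fisher's statistic Psi = -2 sum_i ln p_i follows chi-square with 2k df only
when the k tests are independent. Brown's extension models Psi as a scaled
chi-square c * chi2_f whose variance term includes the covariances between
the transformed test statistics; the empirical variant estimates those
covariances from the data underlying each test. For each test i the data
row x_i (one value per sample) is standardized and pushed through
w_i(s) = -2 ln(ECDF_i(x_i(s))), using the right-continuous empirical CDF
with values rank/n in (0, 1] so the logarithm is finite. Then

    E[Psi]   = 2k
    Var[Psi] = 4k + 2 * sum_{i<j} cov(w_i, w_j)
    f = 2 E^2 / Var,  c = Var / (2 E),  combined p = P(chi2_f > Psi / c).

The degrees of freedom are capped at Fisher's 2k (c floored at 1), so the
method never claims more independent information than Fisher's would.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def transform_row(x: np.ndarray) -> np.ndarray:
    """Standardize a data row and map it through -2 ln ECDF.

    Returns a zero vector for a degenerate (constant) row, which
    contributes nothing to the covariance sum (treated as independent).
    """
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    z = (x - x.mean()) / sd
    n = len(z)
    # right-continuous ECDF evaluated at the sample points: rank / n
    ranks = stats.rankdata(z, method="max")
    return -2.0 * np.log(ranks / n)


def brown_combine(p_values, data_rows) -> float:
    """Combine k dependent P values with Empirical Brown's method.

    ``data_rows`` is a k x n_samples array whose rows are the data behind
    each test, used only to estimate the dependence. k = 1 returns the
    single P unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    k = len(p)
    if k < 1:
        raise ValueError("need at least one p value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    if k == 1:
        return float(p[0])
    rows = np.asarray(data_rows, dtype=float)
    if rows.shape[0] != k:
        raise ValueError("data_rows must have one row per p value")

    W = np.vstack([transform_row(r) for r in rows])
    cov = np.cov(W)                      # k x k, ddof=1
    cov_sum = float(np.sum(np.triu(cov, k=1)))

    expected = 2.0 * k
    variance = 4.0 * k + 2.0 * cov_sum
    df = 2.0 * expected ** 2 / variance
    c = variance / (2.0 * expected)
    if df > 2.0 * k or not np.isfinite(df):   # never beat Fisher
        df = 2.0 * k
        c = 1.0
    psi = float(-2.0 * np.sum(np.log(p)))
    return float(stats.chi2.sf(psi / c, df))
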