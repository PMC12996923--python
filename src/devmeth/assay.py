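"""Colorimetric assay quantification: standard curves and mitochondrial
complex I net activity.

Net activity is the rotenone-sensitive rate of dye reduction: absorbance is
converted to dye concentration via a linear standard curve, the rate dC/dt
is taken over the kinetic window (OLS slope by default; a two-point
first-minus-last variant is available), and

    net activity = (rate_without_rotenone - rate_with_rotenone)
                   / protein_mass * dilution

so units resolve to concentration per time per microgram of mitochondrial
protein. Group comparisons use a two-way ANOVA with Sidak-adjusted post hoc
pairwise tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KineticSeries:
    """Absorbance readings over a fixed time grid for one reaction."""

    timepoints: np.ndarray       # seconds
    absorbance: np.ndarray       # A600
    condition: str               # "rotenone-" | "rotenone+"
    protein_conc: float = 0.66   # ug/uL
    volume_ul: float = 2.0       # loaded volume, uL
    dilution: float = 1.0

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if len(self.timepoints) != len(self.absorbance):
            raise ValueError("timepoints and absorbance length mismatch")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.protein_conc <= 0 or self.dilution <= 0:
            raise ValueError("protein concentration and dilution must be > 0")

    @property
    def protein_mass_ug(self) -> float:
        return self.protein_conc * self.volume_ul


@dataclass
class StandardCurve:
    """Linear map from absorbance to concentration, fitted on standards."""

    slope: float
    intercept: float
    conc_range: tuple[float, float]

    def predict(self, absorbance) -> np.ndarray:
        return self.slope * np.asarray(absorbance, dtype=float) + self.intercept


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """OLS of known concentration on measured absorbance (>= 3 standards)."""
    conc = np.asarray(concentrations, dtype=float)
    ab = np.asarray(absorbances, dtype=float)
    if len(conc) < 3:
        raise ValueError("standard curve requires >= 3 standards")
    res = stats.linregress(ab, conc)
    return StandardCurve(slope=float(res.slope),
                         intercept=float(res.intercept),
                         conc_range=(float(conc.min()), float(conc.max())))


def _rate(series: KineticSeries, curve: StandardCurve,
          method: str) -> float:
    conc = curve.predict(series.absorbance)
    t = series.timepoints
    if method == "slope":
        return float(stats.linregress(t, conc).slope)
    if method == "first_last":
        return float((conc[-1] - conc[0]) / (t[-1] - t[0]))
    raise ValueError(f"unknown rate method {method!r}")


def net_complex1_activity(minus_rotenone: KineticSeries,
                          plus_rotenone: KineticSeries,
                          curve: StandardCurve,
                          rate_method: str = "slope") -> dict:
    """Rotenone-sensitive complex I activity, normalised to protein mass.

    Both series must share the time grid. Negative net activity (more
    signal with the inhibitor) is permitted and flagged in the result.
    """
    if not np.array_equal(minus_rotenone.timepoints,
                          plus_rotenone.timepoints):
        raise ValueError("kinetic series have mismatched time grids")
    rate_minus = _rate(minus_rotenone, curve, rate_method)
    rate_plus = _rate(plus_rotenone, curve, rate_method)
    mass = minus_rotenone.protein_mass_ug
    d = minus_rotenone.dilution
    activity = (rate_minus - rate_plus) / mass * d
    return {
        "activity": float(activity),
        "rate_minus_rotenone": rate_minus,
        "rate_plus_rotenone": rate_plus,
        "inhibitor_insensitive": activity < 0,
    }


def sidak_adjust(p, m: int) -> np.ndarray:
    """Sidak multiple-comparison adjustment: 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


def compare_groups(activities, genotypes, timepoint_factor) -> dict:
    """Two-way ANOVA of activity on genotype x a second factor, with
    Sidak-adjusted pairwise genotype contrasts within each factor level.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"activity": np.asarray(activities, float),
                       "genotype": list(genotypes),
                       "factor": list(timepoint_factor)})
    both_factors = df["factor"].nunique() > 1
    formula = ("activity ~ C(genotype) * C(factor)" if both_factors
               else "activity ~ C(genotype)")
    model = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    genotype_row = [r for r in table.index if "genotype" in r][0]
    fval = float(table.loc[genotype_row, "F"])
    pval = float(table.loc[genotype_row, "PR(>F)"])

    levels = sorted(df["factor"].unique())
    pairwise = []
    for lev in levels:
        sub = df[df["factor"] == lev]
        gts = sorted(sub["genotype"].unique())
        if len(gts) != 2:
            continue
        a = sub.loc[sub["genotype"] == gts[0], "activity"]
        b = sub.loc[sub["genotype"] == gts[1], "activity"]
        t, p = stats.ttest_ind(a, b)
        pairwise.append({"factor_level": lev, "t": float(t), "p_raw": float(p)})
    m = max(1, len(pairwise))
    for row in pairwise:
        row["p_sidak"] = float(sidak_adjust(row["p_raw"], m))
    return {"F_genotype": fval, "p_genotype": pval,
            "anova_table": table, "pairwise": pairwise}
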