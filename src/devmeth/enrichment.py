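"""Functional enrichment with probe-density bias correction, plus overlap
tests.

Methylation arrays annotate more probes to some genes than others, so a
naive gene-set test is confounded by probe density. Term enrichment is
therefore a binomial (logit-link) regression of differential-methylation
status on term membership, covarying for log10 probe density, fitted over
the full gene universe (genes annotated to at least one variable probe).
Independence between significant terms is established by greedy conditional
refitting; biotype enrichment reuses the same model with a biotype
indicator; plain set intersections use Fisher's exact test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

from .types import GeneSetCollection

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene universe

def build_universe(dm_genes, manifest, variable_probe_ids) -> pd.DataFrame:
    """Gene universe: every gene annotated to >= 1 variable probe.

    Columns: ``is_dm``, ``probe_density`` (count of variable probes
    annotated to the gene), ``biotype`` (modal biotype over the gene's
    probes).
    """
    pairs = manifest.gene_probe_pairs()
    pairs = pairs[pairs["probe_id"].isin(set(variable_probe_ids))]
    density = pairs.groupby("gene").size()
    bio = pairs.join(manifest.table["biotype"], on="probe_id")
    biotype = bio.groupby("gene")["biotype"].agg(
        lambda s: s.value_counts().idxmax())
    uni = pd.DataFrame({"probe_density": density, "biotype": biotype})
    uni["is_dm"] = uni.index.isin(set(dm_genes))
    return uni


# ---------------------------------------------------------------------------
# penalized logistic fit (IRLS with optional ridge)

def _logit_irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                max_iter: int = 100, tol: float = 1e-10):
    """Logistic regression by IRLS; ridge penalty (not on the intercept)
    stabilises separated fits. Returns (coef, cov, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, ridge)
    pen[0] = 0.0
    P = np.diag(pen)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        H = X.T @ (X * w[:, None]) + P
        grad = X.T @ (y - mu) - pen * beta
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            cov = np.linalg.inv(H)
            return beta, cov, True
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    H = X.T @ (X * w[:, None]) + P
    return beta, np.linalg.inv(H), False


_SEPARATION_RIDGE = 1e-2


def _fit_membership_model(y: np.ndarray, X: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit the logit model; on (near-)separation refit with a small ridge.

    Returns (coef, se, separation_flagged).
    """
    coef, cov, converged = _logit_irls(X, y, ridge=0.0)
    flagged = (not converged or cov is None
               or np.any(np.abs(coef[1:]) > 12)
               or np.any(np.diag(cov) > 1e4))
    if flagged:
        coef, cov, _ = _logit_irls(X, y, ridge=_SEPARATION_RIDGE)
        if cov is None:
            cov = np.eye(X.shape[1]) * np.inf
    se = np.sqrt(np.diag(cov))
    return coef, se, flagged


def _table_or(a_and_b: int, a_not_b: int, b_not_a: int, neither: int
              ) -> float:
    """Raw 2x2 odds ratio with Haldane-Anscombe correction on zero cells."""
    cells = np.array([a_and_b, a_not_b, b_not_a, neither], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    return float(cells[0] * cells[3] / (cells[1] * cells[2]))


# ---------------------------------------------------------------------------
# term enrichment

@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    n_background: int
    n_dm: int
    odds_ratio: float          # exp(membership coefficient)
    unadjusted_or: float       # raw 2x2 table OR
    p: float
    p_bonferroni: float = float("nan")
    separation_flagged: bool = False
    conditioned_on: tuple[str, ...] = ()


def _wald_p(coef: float, se: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return 1.0
    return float(2 * stats.norm.sf(abs(coef) / se))


def term_enrichment(universe: pd.DataFrame, terms: GeneSetCollection,
                    min_genes: int = 10,
                    extra_covariates: pd.DataFrame | None = None
                    ) -> list[EnrichmentResult]:
    """Density-adjusted over-representation test per term.

    Terms with fewer than ``min_genes`` genes in the universe are skipped.
    ``extra_covariates`` (genes x columns, aligned to the universe) are
    added to every fit — used by the conditional-independence procedure.
    """
    y = universe["is_dm"].to_numpy(dtype=float)
    log_density = np.log10(universe["probe_density"].to_numpy(dtype=float))
    base_cols = [np.ones(len(universe))]
    if log_density.std() > 0:      # constant density is aliased to intercept
        base_cols.append(log_density)
    if extra_covariates is not None:
        for c in extra_covariates.columns:
            base_cols.append(
                extra_covariates[c].reindex(universe.index).to_numpy(float))
    results = []
    for tid in terms:
        name, genes = terms.terms[tid]
        member = universe.index.isin(set(genes)).astype(float)
        n_bg = int(member.sum())
        if n_bg < min_genes:
            continue
        X = np.column_stack([base_cols[0], member, *base_cols[1:]])
        coef, se, flagged = _fit_membership_model(y, X)
        n_dm = int((member.astype(bool) & universe["is_dm"]).sum())
        raw_or = _table_or(
            n_dm, n_bg - n_dm,
            int(universe["is_dm"].sum()) - n_dm,
            len(universe) - n_bg - int(universe["is_dm"].sum()) + n_dm)
        results.append(EnrichmentResult(
            term_id=tid, term_name=name, n_background=n_bg, n_dm=n_dm,
            odds_ratio=float(np.exp(coef[1])), unadjusted_or=raw_or,
            p=_wald_p(coef[1], se[1]), separation_flagged=flagged))
    m = len(results)
    for r in results:
        r.p_bonferroni = min(1.0, r.p * m)
    return results


def conditional_term_selection(results: list[EnrichmentResult],
                               universe: pd.DataFrame,
                               terms: GeneSetCollection,
                               alpha: float = 0.05,
                               bonferroni_alpha: float = 0.05
                               ) -> list[EnrichmentResult]:
    """Greedy selection of mutually independent enriched terms.

    Starting from the Bonferroni-significant terms, the term with the
    largest marginal odds ratio (ties: smaller P, then term id) is
    retained and added to the model as a covariate; the remaining
    significant terms are refitted conditionally and only those still
    significant (conditional P < ``alpha``) stay candidates; iterate until
    none remain. A candidate whose membership column is collinear with the
    retained covariates is dropped (conditional P = 1).
    """
    candidates = {r.term_id: r for r in results
                  if r.p_bonferroni < bonferroni_alpha}
    retained: list[EnrichmentResult] = []
    retained_cols = pd.DataFrame(index=universe.index)
    while candidates:
        best = min(candidates.values(),
                   key=lambda r: (-r.odds_ratio, r.p, r.term_id))
        retained.append(best)
        del candidates[best.term_id]
        member = universe.index.isin(
            set(terms.members(best.term_id))).astype(float)
        retained_cols[best.term_id] = member
        if not candidates:
            break
        ld = np.log10(universe["probe_density"].to_numpy(float))
        dens_cols = [ld] if ld.std() > 0 else []
        base = np.column_stack(
            [np.ones(len(universe)), *dens_cols,
             retained_cols.to_numpy(float)])
        y = universe["is_dm"].to_numpy(float)
        survivors: dict[str, EnrichmentResult] = {}
        base_rank = np.linalg.matrix_rank(base)
        for tid, r in candidates.items():
            cand_member = universe.index.isin(
                set(terms.members(tid))).astype(float)
            X = np.column_stack([base[:, :1], cand_member, base[:, 1:]])
            if np.linalg.matrix_rank(X) <= base_rank:
                logger.info("term %s collinear with retained terms; dropped",
                            tid)
                continue
            coef, se, flagged = _fit_membership_model(y, X)
            cond_p = _wald_p(coef[1], se[1])
            if cond_p < alpha:
                survivors[tid] = EnrichmentResult(
                    term_id=tid, term_name=r.term_name,
                    n_background=r.n_background, n_dm=r.n_dm,
                    odds_ratio=float(np.exp(coef[1])),
                    unadjusted_or=r.unadjusted_or, p=cond_p,
                    p_bonferroni=r.p_bonferroni,
                    separation_flagged=flagged,
                    conditioned_on=tuple(retained_cols.columns))
        candidates = survivors
    return retained


def biotype_enrichment(universe: pd.DataFrame, biotype: str,
                       adjust_for: list[str] | None = None,
                       terms: GeneSetCollection | None = None
                       ) -> EnrichmentResult:
    """Density-adjusted enrichment of a gene biotype among DM genes.

    ``adjust_for`` lists term ids whose membership indicators are added as
    covariates (the shared-DMP adjustment implemented as conditioning).
    """
    if biotype not in set(universe["biotype"]):
        raise ValueError(f"biotype {biotype!r} absent from universe")
    y = universe["is_dm"].to_numpy(float)
    is_bio = (universe["biotype"] == biotype).to_numpy(float)
    cols = [np.ones(len(universe)), is_bio]
    ld = np.log10(universe["probe_density"].to_numpy(float))
    if ld.std() > 0:
        cols.append(ld)
    conditioned: tuple[str, ...] = ()
    if adjust_for:
        if terms is None:
            raise ValueError("adjust_for requires the term collection")
        for tid in adjust_for:
            cols.append(universe.index.isin(
                set(terms.members(tid))).astype(float))
        conditioned = tuple(adjust_for)
    X = np.column_stack(cols)
    coef, se, flagged = _fit_membership_model(y, X)
    n_bio = int(is_bio.sum())
    n_dm_bio = int((is_bio.astype(bool) & universe["is_dm"]).sum())
    raw_or = _table_or(n_dm_bio, n_bio - n_dm_bio,
                       int(universe["is_dm"].sum()) - n_dm_bio,
                       len(universe) - n_bio
                       - int(universe["is_dm"].sum()) + n_dm_bio)
    return EnrichmentResult(
        term_id=f"biotype:{biotype}", term_name=biotype,
        n_background=n_bio, n_dm=n_dm_bio,
        odds_ratio=float(np.exp(coef[1])), unadjusted_or=raw_or,
        p=_wald_p(coef[1], se[1]), p_bonferroni=float("nan"),
        separation_flagged=flagged, conditioned_on=conditioned)


# ---------------------------------------------------------------------------
# Fisher overlap tests

def fisher_overlap(set_a, set_b, background) -> tuple[float, float]:
    """Two-sided Fisher's exact test of the overlap of two gene sets.

    Returns (conditional-MLE odds ratio, P). Both sets must be subsets of
    the background.
    """
    bg = set(background)
    a, b = set(set_a), set(set_b)
    if not a <= bg or not b <= bg:
        raise ValueError("sets must be subsets of the background")
    both = len(a & b)
    table = np.array([[both, len(a) - both],
                      [len(b) - both, len(bg) - len(a | b)]])
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    orr = _cond_odds_ratio(table, kind="conditional").statistic
    return float(orr), p


def threshold_sweep_overlap(probe_results: pd.DataFrame, target_regions,
                            thresholds, manifest,
                            background_probe_ids=None) -> pd.DataFrame:
    """Fisher overlap of DMP probes with target regions at a sweep of P
    cutoffs.

    Targets are 0-based half-open regions; a probe (1-based position) is
    inside a region when start < pos <= end. For each cutoff the 2x2 table
    of (P < cutoff) x (in target) is tested; the odds ratio carries a
    Woolf-logit 95% CI (Haldane correction on zero cells). Cutoffs
    yielding an empty DMP set are skipped with a warning.
    """
    if len(thresholds) < 2:
        raise ValueError("need >= 2 thresholds for a sweep")
    if background_probe_ids is None:
        background_probe_ids = probe_results.index
    res = probe_results.loc[probe_results.index.intersection(
        background_probe_ids)]
    tab = manifest.table.loc[res.index, ["chrom", "pos"]]
    regions = target_regions.table if hasattr(target_regions, "table") \
        else target_regions
    in_target = np.zeros(len(res), dtype=bool)
    for chrom, sub in regions.groupby("chrom"):
        mask = tab["chrom"].to_numpy() == chrom
        if not mask.any():
            continue
        pos = tab["pos"].to_numpy()[mask]
        hit = np.zeros(mask.sum(), dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            hit |= (pos > s) & (pos <= e)
        in_target[mask] |= hit
    p = res["p_genotype"].to_numpy(float)
    rows = []
    for cutoff in thresholds:
        is_dmp = p < cutoff
        if not is_dmp.any():
            warnings.warn(f"no DMPs at threshold {cutoff}; skipped",
                          stacklevel=2)
            continue
        a = int((is_dmp & in_target).sum())
        b = int((is_dmp & ~in_target).sum())
        c = int((~is_dmp & in_target).sum())
        d = int((~is_dmp & ~in_target).sum())
        fisher_p = float(stats.fisher_exact([[a, b], [c, d]])[1])
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            # target status (or DMP status) is constant: no association
            orr, lo, hi = 1.0, 1.0, 1.0
            fisher_p = 1.0
        else:
            cells = np.array([a, b, c, d], dtype=float)
            if (cells == 0).any():
                cells = cells + 0.5
            orr = cells[0] * cells[3] / (cells[1] * cells[2])
            se_log = float(np.sqrt(np.sum(1.0 / cells)))
            lo = float(np.exp(np.log(orr) - 1.959963984540054 * se_log))
            hi = float(np.exp(np.log(orr) + 1.959963984540054 * se_log))
        rows.append((cutoff, a + b, orr, lo, hi, fisher_p))
    return pd.DataFrame(rows, columns=["threshold", "n_dmps", "odds_ratio",
                                       "ci_low", "ci_high", "p"])
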