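"""Reference-based cell-type deconvolution (Houseman-style constrained
projection) with a reconstruction-error quality score.

A two-cell-type reference (NeuN+ neuronal vs NeuN- non-neuronal nuclei) is
trained by per-site one-way ANOVA feature selection: among autosomal sites
with P below a stringent threshold, the top-k most significant hypo- and
hyper-methylated sites per cell type are retained (union, deduplicated; for
two cell types "hypo in A" coincides with "hyper in B", so the default
top-50 per direction per type yields 100 distinct sites). Bulk proportions
are estimated by non-negative least squares against the per-type mean
profiles — no sum-to-one constraint, matching the constrained-projection
formulation — and each sample gets an error score: the root-mean-square
deviation between its observed and reconstructed profile over panel sites
(the CETYGO-style metric).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .types import BetaMatrix, ProbeManifest

logger = logging.getLogger(__name__)


@dataclass
class ReferencePanel:
    """Selected discriminatory sites and per-type mean profiles."""

    selected_sites: list[str]
    profile_matrix: pd.DataFrame     # sites x cell types, mean beta
    selection_stats: pd.DataFrame    # per selected site: F, p, direction info

    @property
    def cell_types(self) -> list[str]:
        return list(self.profile_matrix.columns)


def _anova_by_site(X: np.ndarray, groups: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-row one-way ANOVA across group labels."""
    labels = np.unique(groups)
    k = len(labels)
    n = X.shape[1]
    grand = X.mean(axis=1)
    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    for lab in labels:
        sub = X[:, groups == lab]
        m = sub.mean(axis=1)
        ss_between += sub.shape[1] * (m - grand) ** 2
        ss_within += ((sub - m[:, None]) ** 2).sum(axis=1)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    F = np.where(np.isfinite(F), F, np.inf)
    p = stats.f.sf(F, df1, df2)
    p = np.where(ss_between == 0, 1.0, p)   # no between-type difference
    return F, p


def train_reference(reference_beta: BetaMatrix, labels: pd.Series,
                    manifest: ProbeManifest | None = None,
                    p_threshold: float = 1e-8, top_k: int = 50
                    ) -> ReferencePanel:
    """ANOVA site selection and per-type mean profiles.

    Sites are filtered to autosomes (when a manifest is supplied), ranked
    by one-way ANOVA P across cell types, and among those with
    P < ``p_threshold`` the ``top_k`` most significant sites in which a
    type's mean lies below all other types' means (hypo) and above them
    (hyper) are taken per type; the panel is the deduplicated union.
    Fewer than ``top_k`` qualifying sites in a direction takes all
    available with a warning; zero qualifying sites overall is an error.
    """
    labels = labels.reindex(reference_beta.sample_ids)
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need >= 2 labelled cell types")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("need >= 2 reference samples per cell type")

    beta = reference_beta
    if manifest is not None:
        auto = manifest.autosomal_ids()
        beta = beta.subset_probes(beta.probe_ids.intersection(auto))

    X = beta.data.to_numpy(dtype=float)
    groups = labels.to_numpy()
    F, p = _anova_by_site(X, groups)
    means = {t: X[:, groups == t].mean(axis=1) for t in types}

    qualifying = p < p_threshold
    if not qualifying.any():
        raise ValueError(
            f"no sites with ANOVA P < {p_threshold}; cannot train reference")

    order = np.lexsort((F * -1, p))   # by p ascending, then F descending
    selected: dict[str, dict] = {}
    for t in types:
        others = [o for o in types if o != t]
        hypo = means[t] < np.min([means[o] for o in others], axis=0)
        hyper = means[t] > np.max([means[o] for o in others], axis=0)
        for direction, mask in (("hypo", hypo), ("hyper", hyper)):
            pool = [i for i in order if qualifying[i] and mask[i]]
            if len(pool) < top_k:
                warnings.warn(
                    f"only {len(pool)} qualifying {direction} sites for "
                    f"{t} (requested {top_k})", stacklevel=2)
            for i in pool[:top_k]:
                site = beta.probe_ids[i]
                selected.setdefault(site, {
                    "F": F[i], "p": p[i],
                    "direction": f"{direction}_{t}"})
    sites = [s for s in beta.probe_ids if s in selected]   # genomic order
    profile = pd.DataFrame(
        {t: pd.Series(means[t], index=beta.probe_ids).loc[sites]
         for t in types})
    sel_stats = pd.DataFrame.from_dict(
        {s: selected[s] for s in sites}, orient="index")
    return ReferencePanel(selected_sites=sites, profile_matrix=profile,
                          selection_stats=sel_stats)


def project_proportions(sample_beta: BetaMatrix | pd.Series,
                        panel: ReferencePanel,
                        min_site_overlap: float = 0.8) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions by non-negative least
    squares against the panel profiles.

    Solves min ||b - M w||^2 subject to w >= 0 (no sum-to-one constraint;
    weights may sum below 1 for profiles unlike any reference). The error
    score is sqrt(mean((b - M w)^2)) over panel sites. Requires at least
    ``min_site_overlap`` of panel sites present in the input.
    """
    if isinstance(sample_beta, pd.Series):
        data = sample_beta.to_frame()
    else:
        data = sample_beta.data
    present = [s for s in panel.selected_sites if s in data.index]
    if len(present) < min_site_overlap * len(panel.selected_sites):
        raise ValueError(
            f"only {len(present)}/{len(panel.selected_sites)} panel sites "
            f"present; need >= {min_site_overlap:.0%}")
    M = panel.profile_matrix.loc[present].to_numpy(dtype=float)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("reference profiles are rank deficient "
                         "(cell types indistinguishable over panel sites)")
    rows = []
    for sid in data.columns:
        b = data.loc[present, sid].to_numpy(dtype=float)
        w, _ = nnls(M, b)
        resid = b - M @ w
        err = float(np.sqrt(np.mean(resid ** 2)))
        rows.append((sid, *w, err))
    cols = ["sample_id", *panel.cell_types, "error_score"]
    return pd.DataFrame(rows, columns=cols).set_index("sample_id")
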