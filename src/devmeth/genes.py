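"""Gene-level aggregation of probe P values with Empirical Brown's method.

Probes are grouped by their annotated genes (a probe annotated to several
genes contributes to each); per gene the raw genotype P values are
Brown-combined using the normalized beta rows for dependence estimation,
and combined P values are Bonferroni-adjusted over the number of genes
with at least one contributing probe. The secondary ``promoter_only`` mode
restricts annotation to promoter probes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .brown import brown_combine
from .types import BetaMatrix, ProbeManifest


def aggregate_by_gene(probe_results: pd.DataFrame, beta: BetaMatrix,
                      manifest: ProbeManifest,
                      mode: str = "all_sites") -> pd.DataFrame:
    """Brown-combined gene statistics.

    ``probe_results`` must be indexed by probe id with a ``p_genotype``
    column (as produced by :func:`devmeth.differential.fit_probe_models`);
    only probes present there contribute.
    """
    if mode not in ("all_sites", "promoter_only"):
        raise ValueError(f"unknown annotation mode {mode!r}")
    feature = "promoter" if mode == "promoter_only" else None
    pairs = manifest.gene_probe_pairs(feature=feature)
    pairs = pairs[pairs["probe_id"].isin(probe_results.index)]
    if pairs.empty:
        return pd.DataFrame(columns=["gene", "n_probes", "combined_p",
                                     "adjusted_p", "annotation_mode"]
                            ).set_index("gene")

    data = beta.data
    pvals = probe_results["p_genotype"]
    records = []
    for gene, grp in pairs.groupby("gene", sort=True):
        probes = list(grp["probe_id"])
        p = pvals.loc[probes].to_numpy(dtype=float)
        rows = data.loc[probes].to_numpy(dtype=float)
        combined = brown_combine(p, rows)
        records.append((gene, len(probes), combined))
    out = pd.DataFrame(records, columns=["gene", "n_probes", "combined_p"]
                       ).set_index("gene")
    n_genes = len(out)
    out["adjusted_p"] = np.minimum(out["combined_p"] * n_genes, 1.0)
    out["annotation_mode"] = mode
    return out


def significant_genes(gene_results: pd.DataFrame,
                      alpha: float = 0.05) -> list[str]:
    """Genes significant after the Bonferroni adjustment over genes."""
    return list(gene_results.index[gene_results["adjusted_p"] < alpha])
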