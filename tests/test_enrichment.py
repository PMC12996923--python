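"""Density-adjusted term enrichment, conditional term selection, biotype
enrichment and Fisher overlap tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devmeth import (GeneSetCollection, biotype_enrichment, build_universe,
                     conditional_term_selection, fisher_overlap,
                     term_enrichment, threshold_sweep_overlap)


def make_universe(n_genes=800, frac_dm=0.1, seed=0, constant_density=False):
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    density = (np.ones(n_genes, dtype=int) * 5 if constant_density
               else rng.integers(1, 40, n_genes))
    return pd.DataFrame({
        "probe_density": density,
        "biotype": "protein_coding",
        "is_dm": rng.random(n_genes) < frac_dm,
    }, index=genes)


def term_of(universe, genes, tid="T1", name="term"):
    return GeneSetCollection({tid: (name, tuple(genes))})


class TestTermEnrichment:
    def test_small_term_excluded(self):
        uni = make_universe()
        terms = term_of(uni, uni.index[:9])
        assert term_enrichment(uni, terms, min_genes=10) == []
        terms = term_of(uni, uni.index[:10])
        assert len(term_enrichment(uni, terms, min_genes=10)) == 1

    def test_null_wald_p_uniform(self):
        """Membership independent of DM status and density: Wald P is
        uniform across random terms."""
        rng = np.random.default_rng(42)
        uni = make_universe(n_genes=2000, seed=42)
        terms = {f"T{t}": ("x", tuple(rng.choice(uni.index,
                                                 size=int(rng.integers(20, 200)),
                                                 replace=False)))
                 for t in range(500)}
        res = term_enrichment(uni, GeneSetCollection(terms))
        pvals = [r.p for r in res]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_enriched_term_detected(self):
        uni = make_universe(seed=1)
        dm = list(uni.index[uni["is_dm"]])
        bg = list(uni.index[~uni["is_dm"]])
        terms = term_of(uni, dm[: int(0.8 * len(dm))] + bg[:20])
        res = term_enrichment(uni, terms)
        assert res[0].p_bonferroni < 0.05
        assert res[0].odds_ratio > 1
        assert res[0].unadjusted_or > 1

    def test_constant_density_matches_density_free_logit(self):
        """With constant probe density the density covariate is aliased to
        an intercept shift; the membership coefficient matches a plain
        logistic fit (statsmodels oracle)."""
        import statsmodels.api as sm
        uni = make_universe(constant_density=True, seed=2)
        member_genes = list(uni.index[:100])
        res = term_enrichment(uni, term_of(uni, member_genes))[0]
        y = uni["is_dm"].to_numpy(float)
        member = uni.index.isin(member_genes).astype(float)
        X = np.column_stack([np.ones(len(uni)), member])
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.log(res.odds_ratio) == pytest.approx(fit.params[1],
                                                       abs=1e-8)

    def test_bonferroni_over_tested_terms(self):
        uni = make_universe(seed=3)
        rng = np.random.default_rng(3)
        terms = {f"T{t}": ("x", tuple(rng.choice(uni.index, 50,
                                                 replace=False)))
                 for t in range(10)}
        res = term_enrichment(uni, GeneSetCollection(terms))
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p * 10))

    def test_perfect_separation_flagged_not_crashed(self):
        uni = make_universe(seed=4)
        uni["is_dm"] = False
        dm_genes = list(uni.index[:30])
        uni.loc[dm_genes, "is_dm"] = True
        res = term_enrichment(uni, term_of(uni, dm_genes))[0]
        assert res.separation_flagged
        assert np.isfinite(res.p)


class TestConditionalSelection:
    def test_disjoint_enriched_terms_both_retained(self):
        uni = make_universe(n_genes=1200, frac_dm=0.0, seed=5)
        rng = np.random.default_rng(5)
        a = list(uni.index[:100])
        b = list(uni.index[100:200])
        dm = list(rng.choice(a, 40, replace=False)) \
            + list(rng.choice(b, 40, replace=False)) \
            + list(rng.choice(uni.index[200:], 30, replace=False))
        uni.loc[dm, "is_dm"] = True
        terms = GeneSetCollection({"TA": ("a", tuple(a)),
                                   "TB": ("b", tuple(b))})
        res = term_enrichment(uni, terms)
        kept = conditional_term_selection(res, uni, terms)
        assert {r.term_id for r in kept} == {"TA", "TB"}

    def test_duplicate_term_dropped_after_first(self):
        uni = make_universe(n_genes=600, frac_dm=0.0, seed=6)
        a = list(uni.index[:80])
        uni.loc[a[:40], "is_dm"] = True
        terms = GeneSetCollection({"T1": ("x", tuple(a)),
                                   "T2": ("copy", tuple(a))})
        res = term_enrichment(uni, terms)
        kept = conditional_term_selection(res, uni, terms)
        assert len(kept) == 1

    def test_single_significant_term_returned_unchanged(self):
        uni = make_universe(seed=7)
        dm = list(uni.index[uni["is_dm"]])
        terms = term_of(uni, dm[:40] + list(uni.index[~uni["is_dm"]][:20]))
        res = term_enrichment(uni, terms)
        kept = conditional_term_selection(res, uni, terms)
        assert [r.term_id for r in kept] == ["T1"]

    def test_no_significant_terms_empty(self):
        uni = make_universe(seed=8)
        rng = np.random.default_rng(8)
        terms = term_of(uni, rng.choice(uni.index, 50, replace=False))
        res = term_enrichment(uni, terms)
        if not any(r.p_bonferroni < 0.05 for r in res):
            assert conditional_term_selection(res, uni, terms) == []


class TestBiotypeEnrichment:
    def _nested_universe(self, seed=9):
        """snoRNA genes nested in DM host genes that form a pathway."""
        rng = np.random.default_rng(seed)
        uni = make_universe(n_genes=900, frac_dm=0.05, seed=seed)
        hosts = list(uni.index[:60])
        uni.loc[hosts, "is_dm"] = True
        sno = [f"Sno{i}" for i in range(20)]
        sno_rows = pd.DataFrame({
            "probe_density": 1, "biotype": "snoRNA",
            "is_dm": [i < 14 for i in range(20)]}, index=sno)
        uni = pd.concat([uni, sno_rows])
        terms = GeneSetCollection(
            {"HOSTS": ("host pathway", tuple(hosts + sno[:14]))})
        return uni, terms

    def test_attenuation_after_conditioning(self):
        uni, terms = self._nested_universe()
        before = biotype_enrichment(uni, "snoRNA")
        after = biotype_enrichment(uni, "snoRNA", adjust_for=["HOSTS"],
                                   terms=terms)
        assert before.p < 0.05
        assert after.odds_ratio < before.odds_ratio

    def test_zero_dm_biotype_not_enriched(self):
        uni = make_universe(seed=10)
        uni.loc[uni.index[:30], "biotype"] = "snoRNA"
        uni.loc[uni.index[:30], "is_dm"] = False
        res = biotype_enrichment(uni, "snoRNA")
        assert res.odds_ratio <= 1 or res.p > 0.05

    def test_empty_adjust_equals_unadjusted(self):
        uni, terms = self._nested_universe()
        a = biotype_enrichment(uni, "snoRNA")
        b = biotype_enrichment(uni, "snoRNA", adjust_for=[], terms=terms)
        assert a.odds_ratio == pytest.approx(b.odds_ratio, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_missing_biotype_rejected(self):
        uni = make_universe(seed=11)
        with pytest.raises(ValueError, match="biotype"):
            biotype_enrichment(uni, "lncRNA")


class TestFisherOverlap:
    def test_independence_table(self):
        bg = {f"g{i}" for i in range(40)}
        a = {f"g{i}" for i in range(20)}
        b = {f"g{i}" for i in range(10, 30)}
        orr, p = fisher_overlap(a, b, bg)
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_complete_overlap_infinite_or(self):
        bg = {f"g{i}" for i in range(200)}
        a = {f"g{i}" for i in range(100)}
        orr, p = fisher_overlap(a, a, bg)
        assert orr == np.inf
        assert p < 1e-20

    def test_symmetry(self):
        rng = np.random.default_rng(12)
        bg = {f"g{i}" for i in range(100)}
        a = set(rng.choice(sorted(bg), 30, replace=False))
        b = set(rng.choice(sorted(bg), 40, replace=False))
        or_ab, p_ab = fisher_overlap(a, b, bg)
        or_ba, p_ba = fisher_overlap(b, a, bg)
        assert or_ab == pytest.approx(or_ba, rel=1e-9)
        assert p_ab == pytest.approx(p_ba, rel=1e-12)

    def test_matches_hypergeometric_enumeration(self):
        """Exact oracle: two-sided P as the sum of hypergeometric point
        probabilities no larger than the observed one."""
        rng = np.random.default_rng(13)
        bg = sorted(f"g{i}" for i in range(200))
        for _ in range(50):
            na, nb = rng.integers(5, 80, 2)
            a = set(rng.choice(bg, na, replace=False))
            b = set(rng.choice(bg, nb, replace=False))
            _, p = fisher_overlap(a, b, set(bg))
            N, K, n = len(bg), len(a), len(b)
            k_obs = len(a & b)
            pmf = stats.hypergeom.pmf(np.arange(0, min(K, n) + 1), N, K, n)
            p_oracle = pmf[pmf <= pmf[k_obs] * (1 + 1e-12)].sum()
            assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError, match="subsets"):
            fisher_overlap({"x"}, {"y"}, {"y"})


class TestThresholdSweep:
    def _inputs(self, default_dataset):
        from devmeth import fit_probe_models
        ds = default_dataset
        ds.samples.table["neuronal_prop"] = ds.truth.true_proportions
        res = fit_probe_models(ds.beta, ds.samples)
        return ds, res

    def test_planted_targets_or_increases_with_stringency(
            self, default_dataset):
        ds, res = self._inputs(default_dataset)
        sweep = threshold_sweep_overlap(res, ds.truth.dmr_regions,
                                        [0.05, 1e-3, 1e-5], ds.manifest)
        ors = sweep["odds_ratio"].to_numpy()
        assert (np.diff(ors) >= 0).all()
        assert (sweep["ci_low"] <= sweep["odds_ratio"]).all()
        assert (sweep["odds_ratio"] <= sweep["ci_high"]).all()

    def test_targets_covering_all_probes_give_or_one(self, default_dataset):
        import devmeth
        ds, res = self._inputs(default_dataset)
        all_cover = pd.DataFrame(
            [(c, 0, 10**9, "all") for c in
             ds.manifest.table["chrom"].unique()],
            columns=["chrom", "start", "end", "name"])
        sweep = threshold_sweep_overlap(
            res, devmeth.RegionSet(all_cover), [0.05, 1e-3], ds.manifest)
        assert (sweep["odds_ratio"] == 1.0).all()

    def test_empty_dmp_threshold_skipped_with_warning(self, default_dataset):
        ds, res = self._inputs(default_dataset)
        with pytest.warns(UserWarning, match="skipped"):
            sweep = threshold_sweep_overlap(
                res, ds.truth.dmr_regions, [0.05, 1e-300], ds.manifest)
        assert list(sweep["threshold"]) == [0.05]

    def test_single_threshold_rejected(self, default_dataset):
        ds, res = self._inputs(default_dataset)
        with pytest.raises(ValueError, match="thresholds"):
            threshold_sweep_overlap(res, ds.truth.dmr_regions, [0.05],
                                    ds.manifest)


def test_build_universe_density_and_nesting(default_dataset):
    from devmeth import select_variable_probes
    ds = default_dataset
    variable = select_variable_probes(ds.beta)
    uni = build_universe(ds.truth.dm_genes, ds.manifest,
                         variable.index[variable])
    assert (uni["probe_density"] >= 1).all()
    assert (uni["biotype"] == "snoRNA").sum() > 0
    # every universe gene is annotated to >= 1 variable probe by construction
    pairs = ds.manifest.gene_probe_pairs()
    pairs = pairs[pairs["probe_id"].isin(set(variable.index[variable]))]
    assert set(uni.index) == set(pairs["gene"])
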