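"""One-command end-to-end run on simulated data, with a recovery report.

Stage order mirrors the study's analysis: sample QC -> probe filtering ->
quantile normalization -> variable-probe selection -> cell-type
deconvolution (estimated neuronal proportion threaded into all models) ->
pseudo-age scoring -> probe-level differential methylation and interaction
tests -> gene-level Brown aggregation -> DMR calling -> density-adjusted
enrichment. When the inputs are simulated, the report includes recovery
metrics against the planted truth (DMP sensitivity and false-discovery
proportion, probe-level Jaccard on planted DMR blocks, effect-size RMSE).

The neuronal proportion used in the models is always the deconvolution
estimate, not the simulation truth, so covariate-estimation error
propagates exactly as it would on real data (``use_true_proportions``
injects the truth for ablation runs).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import io as dio
from .config import Config
from .deconvolution import project_proportions, train_reference
from .differential import bonferroni_dmps, fit_probe_models, test_interaction
from .dmr import annotate_dmrs, call_dmrs, dmrs_to_frame
from .enrichment import (biotype_enrichment, build_universe,
                         conditional_term_selection, fisher_overlap,
                         term_enrichment, threshold_sweep_overlap)
from .genes import aggregate_by_gene, significant_genes
from .pseudoage import score_samples, test_age_genotype_effects
from .qc import (SampleQcSummary, apply_sample_qc, filter_probes,
                 quantile_normalize, select_variable_probes)
from .simulate import (SimulationDesign, simulate_dataset, simulate_gene_sets,
                       simulate_reference_panel)


@dataclass
class RunReport:
    """Stage counts plus recovery metrics against planted truth."""

    n_samples_input: int = 0
    n_samples_pass_qc: int = 0
    n_probes_input: int = 0
    n_probes_retained: int = 0
    n_probes_variable: int = 0
    n_dmps: int = 0
    n_dmps_hypo: int = 0
    n_dmps_hyper: int = 0
    n_genes_tested: int = 0
    n_genes_significant: int = 0
    n_dmr_candidates: int = 0
    n_dmrs_significant: int = 0
    n_terms_tested: int = 0
    n_terms_significant: int = 0
    pseudo_age_age_slope: float = float("nan")
    pseudo_age_age_p: float = float("nan")
    pseudo_age_genotype_p: float = float("nan")
    dmp_sensitivity: float = float("nan")
    dmp_fdp: float = float("nan")
    effect_size_rmse: float = float("nan")
    dmr_block_jaccard: float = float("nan")
    clipping_fraction: float = float("nan")

    def validate(self) -> None:
        assert self.n_probes_variable <= self.n_probes_retained \
            <= self.n_probes_input


def _simulated_qc_summaries(samples, rng) -> list[SampleQcSummary]:
    out = []
    for sid in samples.sample_ids:
        out.append(SampleQcSummary(
            sample_id=sid,
            median_meth_intensity=float(rng.uniform(2500, 4000)),
            median_unmeth_intensity=float(rng.uniform(2500, 4000)),
            frac_probes_failing_detection=float(rng.uniform(0, 0.008)),
            bisulfite_conversion_pct=float(rng.uniform(93, 98))))
    return out


def run_pipeline(design: SimulationDesign | None = None,
                 config: Config | None = None,
                 out_dir=None,
                 use_true_proportions: bool = False,
                 run_enrichment: bool = True) -> tuple[RunReport, dict]:
    """Execute the full simulated-data pipeline; returns (report, stages).

    ``stages`` holds every intermediate object keyed by stage name. With
    ``out_dir`` the stage outputs, truth tables and the report are written
    as TSV/BED/JSON. Deterministic under a fixed design seed.
    """
    config = config or Config()
    design = design or SimulationDesign(seed=config.seed)
    seeds = np.random.SeedSequence(design.seed).generate_state(4) % (2**31)
    report = RunReport()
    stages: dict = {}

    ds = simulate_dataset(design)
    truth = ds.truth
    stages["dataset"] = ds
    report.n_samples_input = ds.beta.shape[1]
    report.n_probes_input = ds.beta.shape[0]
    report.clipping_fraction = truth.clipping_fraction

    # --- sample QC ------------------------------------------------------
    qc_rng = np.random.default_rng(seeds[0])
    summaries = _simulated_qc_summaries(ds.samples, qc_rng)
    sample_qc = apply_sample_qc(summaries)
    keep_samples = sample_qc.index[sample_qc["passed"]]
    beta = ds.beta.subset_samples(keep_samples)
    samples = ds.samples
    samples.table = samples.table.loc[keep_samples]
    report.n_samples_pass_qc = len(keep_samples)
    stages["sample_qc"] = sample_qc

    # --- probe filtering and normalization ------------------------------
    beta, probe_status = filter_probes(
        beta, ds.manifest, truth.detection_fail_counts,
        max_fail_samples=config.max_detection_fail_samples)
    report.n_probes_retained = beta.shape[0]
    stages["probe_status"] = probe_status
    beta = quantile_normalize(beta)
    stages["normalized_beta"] = beta

    is_variable = select_variable_probes(
        beta, min_range=config.variable_min_range,
        inner_fraction=config.inner_fraction)
    variable_ids = is_variable.index[is_variable]
    report.n_probes_variable = len(variable_ids)
    stages["is_variable"] = is_variable

    # --- deconvolution ---------------------------------------------------
    ref_beta, ref_labels = simulate_reference_panel(truth.reference,
                                                    seed=int(seeds[1]))
    panel = train_reference(ref_beta, ref_labels, ds.manifest,
                            p_threshold=config.anova_p, top_k=config.top_k)
    stages["reference_panel"] = panel
    decon = project_proportions(beta, panel)
    stages["deconvolution"] = decon
    if use_true_proportions:
        samples.table["neuronal_prop"] = truth.true_proportions.loc[
            samples.sample_ids]
    else:
        samples.table["neuronal_prop"] = decon["NeuN+"].loc[samples.sample_ids]

    # --- pseudo-age -------------------------------------------------------
    scores = score_samples(beta, truth.clock)
    samples.table["pseudo_age"] = scores.loc[samples.sample_ids]
    age_geno = test_age_genotype_effects(scores, samples)
    report.pseudo_age_age_slope = age_geno["age_slope"]
    report.pseudo_age_age_p = age_geno["age_p"]
    report.pseudo_age_genotype_p = age_geno["genotype_p"]
    stages["pseudo_age"] = age_geno

    # --- probe-level models ----------------------------------------------
    beta_var = beta.subset_probes(variable_ids)
    probe_results = fit_probe_models(beta_var, samples)
    probe_results = probe_results.join(test_interaction(beta_var, samples))
    probe_results = bonferroni_dmps(probe_results, n_tests=config.n_tests,
                                    alpha=config.alpha)
    stages["probe_results"] = probe_results
    report.n_dmps = int(probe_results["is_dmp"].sum())
    report.n_dmps_hypo = int((probe_results["dmp_direction"] == "hypo").sum())
    report.n_dmps_hyper = int((probe_results["dmp_direction"] == "hyper").sum())

    # --- gene aggregation --------------------------------------------------
    gene_results = aggregate_by_gene(probe_results, beta_var, ds.manifest,
                                     mode="all_sites")
    stages["gene_results"] = gene_results
    sig_genes = significant_genes(gene_results, alpha=config.alpha)
    report.n_genes_tested = len(gene_results)
    report.n_genes_significant = len(sig_genes)

    # --- DMRs ---------------------------------------------------------------
    dmrs = call_dmrs(probe_results, ds.manifest, beta_var,
                     gap_bp=config.dmr_gap_bp, nominal_p=config.nominal_p)
    dmrs = annotate_dmrs(dmrs, ds.manifest.gene_bodies())
    stages["dmrs"] = dmrs
    report.n_dmr_candidates = len(dmrs)
    report.n_dmrs_significant = sum(d.adjusted_p < config.alpha for d in dmrs)

    # --- enrichment ----------------------------------------------------------
    if run_enrichment:
        gene_sets = simulate_gene_sets(ds.manifest, truth.dm_genes,
                                       seed=int(seeds[2]))
        universe = build_universe(sig_genes, ds.manifest, variable_ids)
        enr = term_enrichment(universe, gene_sets,
                              min_genes=config.min_term_genes)
        stages["gene_sets"] = gene_sets
        stages["enrichment"] = enr
        report.n_terms_tested = len(enr)
        report.n_terms_significant = sum(
            r.p_bonferroni < config.alpha for r in enr)
        stages["independent_terms"] = conditional_term_selection(
            enr, universe, gene_sets, alpha=config.alpha)
        if (universe["biotype"] == "snoRNA").any():
            stages["snorna_enrichment"] = biotype_enrichment(
                universe, "snoRNA")
        if sig_genes:
            stages["fisher_designed"] = fisher_overlap(
                set(sig_genes),
                set(gene_sets.members("TERM_DESIGNED")) & set(universe.index),
                set(universe.index))
        if len(truth.dmr_regions):
            stages["threshold_sweep"] = threshold_sweep_overlap(
                probe_results, truth.dmr_regions,
                thresholds=[0.05, 1e-3, 1e-5], manifest=ds.manifest)
        stages["universe"] = universe

    # --- recovery vs planted truth -------------------------------------------
    planted = set(truth.planted_dmps["probe_id"])
    block_probes = {p for b in truth.dmr_blocks for p in b["probe_ids"]}
    called = set(probe_results.index[probe_results["is_dmp"]])
    all_planted = planted | block_probes
    if planted:
        report.dmp_sensitivity = len(called & planted) / len(planted)
    if called:
        report.dmp_fdp = len(called - all_planted) / len(called)
    if all_planted:
        deltas = pd.Series(0.0, index=probe_results.index)
        for _, row in truth.planted_dmps.iterrows():
            if row["probe_id"] in deltas.index:
                deltas[row["probe_id"]] = row["delta"]
        for b in truth.dmr_blocks:
            for p in b["probe_ids"]:
                if p in deltas.index:
                    deltas[p] = b["delta"]
        est = probe_results["beta_genotype"]
        report.effect_size_rmse = float(
            np.sqrt(np.mean((est - deltas) ** 2)))
    if block_probes:
        # per planted block: Jaccard against the union of called regions
        # sharing at least one probe with it (a block split by a wide gap
        # is recovered as two regions), averaged over blocks
        jaccards = []
        for b in truth.dmr_blocks:
            members = set(b["probe_ids"])
            called_here: set[str] = set()
            for d in dmrs:
                if members & set(d.probe_ids):
                    called_here |= set(d.probe_ids)
            union = members | called_here
            jaccards.append(len(members & called_here) / len(union))
        report.dmr_block_jaccard = float(np.mean(jaccards))

    report.validate()
    stages["samples"] = samples
    if out_dir is not None:
        _write_outputs(out_dir, design, config, report, stages)
    return report, stages


def _write_outputs(out_dir, design, config, report, stages) -> None:
    out = dio.ensure_dir(out_dir)
    ds = stages["dataset"]
    dio.write_beta_matrix(stages["normalized_beta"], out / "beta_normalized.tsv")
    dio.write_sample_sheet(stages["samples"], out / "samples.tsv")
    dio.write_manifest(ds.manifest, out / "manifest.tsv")
    stages["probe_results"].to_csv(out / "probe_results.tsv", sep="\t",
                                   index_label="probe_id")
    stages["gene_results"].to_csv(out / "gene_results.tsv", sep="\t")
    dmrs_to_frame(stages["dmrs"]).to_csv(out / "dmrs.tsv", sep="\t",
                                         index=False)
    dio.write_dmr_bed(stages["dmrs"], out / "dmrs.bed")
    truth_dir = dio.ensure_dir(out / "truth")
    ds.truth.planted_dmps.to_csv(truth_dir / "planted_dmps.tsv", sep="\t",
                                 index=False)
    dio.write_regions(ds.truth.dmr_regions, truth_dir / "planted_dmrs.bed")
    ds.truth.true_proportions.to_frame().to_csv(
        truth_dir / "true_proportions.tsv", sep="\t", index_label="sample_id")
    if "enrichment" in stages:
        pd.DataFrame([asdict(r) for r in stages["enrichment"]]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False)
    rep = {k: (v if not isinstance(v, float) or np.isfinite(v) else None)
           for k, v in asdict(report).items()}
    with open(out / "report.json", "w") as fh:
        json.dump({"report": rep, "seed": design.seed,
                   "config": {k: v for k, v in asdict(config).items()}},
                  fh, indent=2, default=str)
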