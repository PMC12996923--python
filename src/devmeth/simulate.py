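"""Synthetic methylation-array data with the structure the analysis assumes.

The generator emulates a 2-genotype x 5-age mouse cortex design (n per cell
configurable, default 5): probe-level beta values are a cell-type mixture of
neuronal and glial reference profiles, plus categorical age effects, a
planted age-clock trend, chip batch shifts, planted genotype effects
(isolated DMPs and clustered DMR blocks with a common sign), and Gaussian
beta-scale noise, clipped to [0, 1]. Planted truth is returned alongside the
data so every downstream stage can compute recovery metrics.

Effects are additive on the beta scale (then clipped), matching the analysis
models, so planted effect sizes are directly interpretable as the fitted
genotype coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pseudoage import ClockModel
from .types import (AGE_DAYS, AGE_LABELS, BetaMatrix, GeneSetCollection,
                    ProbeManifest, RegionSet, SampleSheet)


@dataclass
class SimulationDesign:
    """Parameters of the synthetic study.

    Defaults give a desk-scale version of the study design: 5,000 probes,
    50 samples (2 genotypes x 5 ages x 5), 50 isolated planted DMPs and 8
    planted DMR blocks of 3-8 probes at |delta| = 0.15, 2 chips with
    sd 0.01 batch shifts, and beta-scale noise sd 0.02.
    """

    n_probes: int = 5000
    n_per_cell: int = 5
    n_chips: int = 2
    # planted genotype effects (beta-scale shifts in HET)
    n_isolated_dmps: int = 50
    dmp_effect_size: float = 0.15
    n_dmr_blocks: int = 8
    dmr_block_size: tuple[int, int] = (3, 8)
    dmr_effect_size: float = 0.15
    n_wide_gap_blocks: int = 2     # blocks containing one >=1500 bp internal gap
    # nuisance structure
    age_effect_sd: float = 0.02
    age_effect_prob: float = 0.5
    chip_effect_sd: float = 0.01
    noise_sd: float = 0.02
    # age clock
    n_clock_sites: int = 105
    clock_slope_range: tuple[float, float] = (0.0005, 0.003)
    # cell-type mixture
    n_discriminatory_sites: int = 600
    discriminatory_delta: float = 0.5
    neuronal_base: float = 0.35
    neuronal_age_slope: float = 0.0025   # per day
    neuronal_sd: float = 0.03
    reference_n_per_type: int = 25
    reference_within_sd: float = 0.05
    # manifest layout
    probes_per_gene: int = 10
    n_autosomes: int = 5
    frac_chrx: float = 0.04
    n_chr0_probes: int = 15
    frac_flagged: float = 0.004
    frac_mfg_flagged: float = 0.002
    n_snorna_genes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("design must have at least one probe")
        if self.n_per_cell <= 0:
            raise ValueError("design must have at least one sample per cell")
        for name in ("age_effect_sd", "chip_effect_sd", "noise_sd",
                     "neuronal_sd", "reference_within_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ReferenceTruth:
    """True per-cell-type mean methylation profiles for the sorted-nuclei panel."""

    m_neuron: pd.Series
    m_glia: pd.Series
    n_per_type: int = 25
    within_sd: float = 0.05


@dataclass
class SimulationTruth:
    """Planted ground truth written alongside every simulated dataset."""

    planted_dmps: pd.DataFrame          # probe_id, gene, delta (isolated DMPs)
    dmr_blocks: list[dict]              # chrom, start, end, probe_ids, delta
    dmr_regions: RegionSet              # 0-based half-open block spans
    dm_genes: set[str]                  # genes hosting any planted effect
    true_proportions: pd.Series         # per-sample neuronal fraction
    reference: ReferenceTruth
    clock: ClockModel
    detection_fail_counts: pd.Series    # per-probe samples failing detection
    clipping_fraction: float


@dataclass
class SimulatedDataset:
    beta: BetaMatrix
    samples: SampleSheet
    manifest: ProbeManifest
    truth: SimulationTruth


def _build_manifest(design: SimulationDesign, rng: np.random.Generator):
    """Lay out probes on chromosomes in gene blocks with intergenic spacers."""
    n = design.n_probes
    n_chr0 = min(design.n_chr0_probes, max(0, n - 10))
    n_x = int((n - n_chr0) * design.frac_chrx)
    n_auto = n - n_chr0 - n_x
    chrom_sizes = [n_auto // design.n_autosomes] * design.n_autosomes
    chrom_sizes[0] += n_auto - sum(chrom_sizes)
    chroms = [f"chr{i + 1}" for i in range(design.n_autosomes)]
    if n_x > 0:
        chroms.append("chrX")
        chrom_sizes.append(n_x)
    if n_chr0 > 0:
        chroms.append("0")
        chrom_sizes.append(n_chr0)

    rows = []
    gene_counter = 0
    for chrom, size in zip(chroms, chrom_sizes):
        pos = int(rng.integers(10_000, 50_000))
        placed = 0
        in_gene = 0
        gene = None
        while placed < size:
            if chrom == "0":
                rows.append((f"cg{len(rows):07d}", chrom, pos, (),
                             "intergenic"))
            elif in_gene == 0:
                # start a new gene block (or drop an intergenic spacer probe)
                if gene is not None:
                    rows.append((f"cg{len(rows):07d}", chrom, pos, (),
                                 "intergenic"))
                    pos += int(rng.integers(3000, 10_000))
                    placed += 1
                    if placed >= size:
                        break
                gene_counter += 1
                gene = f"Gene{gene_counter:04d}"
                in_gene = design.probes_per_gene
                rows.append((f"cg{len(rows):07d}", chrom, pos, (gene,),
                             "promoter"))
                in_gene -= 1
            else:
                rows.append((f"cg{len(rows):07d}", chrom, pos, (gene,),
                             "gene_body"))
                in_gene -= 1
                if in_gene == 0:
                    pos += int(rng.integers(3000, 10_000))
                    placed += 1
                    continue
            pos += int(rng.integers(200, 800))
            placed += 1

    tab = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "genes",
                                      "feature"]).set_index("probe_id")
    tab["biotype"] = np.where(tab["genes"].map(len) > 0, "protein_coding", "NA")
    tab["flagged"] = rng.random(len(tab)) < design.frac_flagged
    tab["mfg_change_flagged"] = rng.random(len(tab)) < design.frac_mfg_flagged
    tab["autosomal"] = tab["chrom"].str.match(r"chr\d+$")
    return tab


def simulate_dataset(design: SimulationDesign) -> SimulatedDataset:
    """Generate a full bulk dataset plus planted truth, deterministically."""
    rng = np.random.default_rng(design.seed)
    tab = _build_manifest(design, rng)
    probe_ids = tab.index
    n_probes = len(tab)

    # samples: genotype x age x replicate, chips alternating within each cell
    sample_rows = []
    for gt in ("WT", "HET"):
        for age in AGE_LABELS:
            for rep in range(design.n_per_cell):
                chip = f"chip{rep % design.n_chips + 1}"
                sample_rows.append((f"{gt}_{age}_{rep + 1}", gt, age, chip))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "genotype",
                                                 "age_label", "chip_id"]
                           ).set_index("sample_id")
    samples["age_days"] = samples["age_label"].map(AGE_DAYS)
    n_samples = len(samples)

    clean = (tab["autosomal"] & ~tab["flagged"] & ~tab["mfg_change_flagged"]
             & (tab["genes"].map(len) > 0))
    clean_body = clean & (tab["feature"] == "gene_body")

    # --- cell-type reference truth -------------------------------------
    base = rng.uniform(0.1, 0.9, n_probes)
    small_delta = rng.normal(0.0, 0.02, n_probes)
    m_neuron = np.clip(base + small_delta / 2, 0.02, 0.98)
    m_glia = np.clip(base - small_delta / 2, 0.02, 0.98)
    disc_pool = np.flatnonzero(clean.to_numpy())
    n_disc = min(design.n_discriminatory_sites, len(disc_pool))
    disc_idx = rng.choice(disc_pool, size=n_disc, replace=False)
    half = design.discriminatory_delta / 2
    centers = rng.uniform(0.02 + half, 0.98 - half, n_disc)
    signs = np.where(np.arange(n_disc) % 2 == 0, 1.0, -1.0)
    m_neuron[disc_idx] = centers + signs * half
    m_glia[disc_idx] = centers - signs * half
    m_neuron = pd.Series(m_neuron, index=probe_ids)
    m_glia = pd.Series(m_glia, index=probe_ids)
    reference = ReferenceTruth(m_neuron, m_glia,
                               n_per_type=design.reference_n_per_type,
                               within_sd=design.reference_within_sd)

    taken = set(disc_idx.tolist())

    # --- planted genotype effects --------------------------------------
    gene_of = tab["genes"].map(lambda g: g[0] if g else None)
    candidate = clean_body.to_numpy() & ~np.isin(np.arange(n_probes),
                                                 list(taken))
    bulk_base_mid = ((m_neuron + m_glia) / 2).to_numpy()
    candidate &= (bulk_base_mid > 0.25) & (bulk_base_mid < 0.75)

    delta = np.zeros(n_probes)
    dmp_rows = []
    cand_idx = np.flatnonzero(candidate)
    rng.shuffle(cand_idx)
    used_genes: set[str] = set()
    for idx in cand_idx:
        if len(dmp_rows) >= design.n_isolated_dmps:
            break
        g = gene_of.iloc[idx]
        if g in used_genes:
            continue
        used_genes.add(g)
        sign = rng.choice([-1.0, 1.0])
        if bulk_base_mid[idx] + sign * design.dmp_effect_size > 0.95:
            sign = -1.0
        elif bulk_base_mid[idx] - design.dmp_effect_size < 0.05:
            sign = 1.0
        delta[idx] = sign * design.dmp_effect_size
        taken.add(int(idx))
        dmp_rows.append((probe_ids[idx], g, delta[idx]))
    planted_dmps = pd.DataFrame(dmp_rows, columns=["probe_id", "gene", "delta"])

    # DMR blocks: runs of consecutive probes within one gene, common sign
    positions = tab["pos"].to_numpy().copy()
    block_specs: list[dict] = []
    gene_groups = [(g, np.flatnonzero((gene_of == g).to_numpy()))
                   for g in pd.unique(gene_of.dropna())]
    rng.shuffle(gene_groups)
    for g, idxs in gene_groups:
        if len(block_specs) >= design.n_dmr_blocks:
            break
        if g in used_genes or len(idxs) < design.dmr_block_size[1]:
            continue
        if any(i in taken for i in idxs):
            continue
        if not clean_body.iloc[idxs[1]]:
            continue
        size = int(rng.integers(design.dmr_block_size[0],
                                design.dmr_block_size[1] + 1))
        member = idxs[1:1 + size]     # gene-body probes after the promoter
        mid = bulk_base_mid[member].mean()
        sign = rng.choice([-1.0, 1.0])
        if mid + sign * design.dmr_effect_size > 0.9:
            sign = -1.0
        elif mid - design.dmr_effect_size < 0.1:
            sign = 1.0
        if len(block_specs) < design.n_wide_gap_blocks and len(member) >= 4:
            # widen one internal gap beyond the caller's 1500 bp rule
            split_at = member[len(member) // 2]
            positions[split_at:] = positions[split_at:] + 2000
        delta[member] = sign * design.dmr_effect_size
        taken.update(int(i) for i in member)
        used_genes.add(g)
        block_specs.append({"member": member, "gene": g,
                            "delta": sign * design.dmr_effect_size})
    tab = tab.assign(pos=positions)
    blocks = [{"chrom": tab["chrom"].iloc[spec["member"][0]],
               "start": int(positions[spec["member"][0]]),
               "end": int(positions[spec["member"][-1]]),
               "probe_ids": list(probe_ids[spec["member"]]),
               "gene": spec["gene"], "delta": spec["delta"]}
              for spec in block_specs]
    dmr_regions = RegionSet(pd.DataFrame(
        [(b["chrom"], b["start"] - 1, b["end"], b["gene"]) for b in blocks],
        columns=["chrom", "start", "end", "name"]))

    # --- snoRNA genes nested inside host genes -------------------------
    dm_genes = set(planted_dmps["gene"]) | {b["gene"] for b in blocks}
    host_pool = sorted(dm_genes)
    other_pool = [g for g, idxs in sorted(gene_groups) if g not in dm_genes
                  and tab["autosomal"].iloc[idxs[0]]]
    n_sno_dm = min(len(host_pool), int(round(design.n_snorna_genes * 0.6)))
    hosts = (list(rng.choice(host_pool, size=n_sno_dm, replace=False))
             if n_sno_dm else [])
    n_sno_null = design.n_snorna_genes - len(hosts)
    if n_sno_null and other_pool:
        hosts += list(rng.choice(other_pool,
                                 size=min(n_sno_null, len(other_pool)),
                                 replace=False))
    genes_col = tab["genes"].copy()
    biotype_col = tab["biotype"].copy()
    for k, host in enumerate(hosts):
        host_idx = np.flatnonzero((gene_of == host).to_numpy())
        planted_here = [i for i in host_idx if delta[i] != 0]
        target = planted_here[0] if planted_here else host_idx[-1]
        sno = f"Snord{k + 1:03d}"
        genes_col.iloc[target] = genes_col.iloc[target] + (sno,)
        biotype_col.iloc[target] = "snoRNA"
        if planted_here:
            dm_genes.add(sno)
    tab = tab.assign(genes=genes_col, biotype=biotype_col)

    # --- age clock ------------------------------------------------------
    clock_pool = [i for i in np.flatnonzero(clean.to_numpy())
                  if i not in taken and 0.3 < bulk_base_mid[i] < 0.7]
    n_clock = min(design.n_clock_sites, len(clock_pool))
    clock_idx = (rng.choice(clock_pool, size=n_clock, replace=False)
                 if n_clock else np.array([], dtype=int))
    lo, hi = design.clock_slope_range
    clock_slopes = rng.uniform(lo, hi, n_clock) * rng.choice([-1, 1], n_clock)
    clock = ClockModel(list(probe_ids[clock_idx]), clock_slopes)
    taken.update(int(i) for i in clock_idx)

    # --- assemble the beta matrix ---------------------------------------
    w = np.clip(design.neuronal_base
                + design.neuronal_age_slope * samples["age_days"].to_numpy()
                + rng.normal(0.0, design.neuronal_sd, n_samples), 0.0, 1.0)
    mean = (np.outer(m_neuron.to_numpy(), w)
            + np.outer(m_glia.to_numpy(), 1.0 - w))

    age_idx = samples["age_label"].map(
        {a: i for i, a in enumerate(AGE_LABELS)}).to_numpy()
    has_age_effect = rng.random(n_probes) < design.age_effect_prob
    has_age_effect[clock_idx] = False
    age_eff = rng.normal(0.0, design.age_effect_sd, (n_probes, len(AGE_LABELS)))
    age_eff -= age_eff.mean(axis=1, keepdims=True)
    age_eff[~has_age_effect] = 0.0
    mean += age_eff[:, age_idx]

    age_days = samples["age_days"].to_numpy()
    if n_clock:
        centered_days = age_days - age_days.mean()
        mean[clock_idx, :] += np.outer(clock_slopes, centered_days)

    chip_codes = samples["chip_id"].astype("category").cat.codes.to_numpy()
    chip_eff = rng.normal(0.0, design.chip_effect_sd,
                          (n_probes, design.n_chips))
    mean += chip_eff[:, chip_codes]

    is_het = (samples["genotype"] == "HET").to_numpy(float)
    mean += np.outer(delta, is_het)

    raw = mean + rng.normal(0.0, design.noise_sd, (n_probes, n_samples))
    clipped = np.clip(raw, 0.0, 1.0)
    clip_frac = float(np.mean(raw != clipped))
    beta = BetaMatrix(pd.DataFrame(clipped, index=probe_ids,
                                   columns=samples.index))

    # --- QC side data ----------------------------------------------------
    fail = rng.choice([0, 1, 2, 3], size=n_probes,
                      p=[0.97, 0.02, 0.008, 0.002])
    fail[list(taken)] = 0
    detection_fail = pd.Series(fail, index=probe_ids,
                               name="n_samples_failing")

    truth = SimulationTruth(
        planted_dmps=planted_dmps, dmr_blocks=blocks, dmr_regions=dmr_regions,
        dm_genes=dm_genes,
        true_proportions=pd.Series(w, index=samples.index, name="neuronal"),
        reference=reference, clock=clock,
        detection_fail_counts=detection_fail, clipping_fraction=clip_frac)
    return SimulatedDataset(beta=beta, samples=SampleSheet(samples),
                            manifest=ProbeManifest(tab), truth=truth)


def simulate_reference_panel(truth: ReferenceTruth, seed: int,
                             ) -> tuple[BetaMatrix, pd.Series]:
    """Sorted-nuclei reference samples drawn around the per-type means."""
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    profiles = [("NeuN+", truth.m_neuron), ("NeuN-", truth.m_glia)]
    data = {}
    for label, m in profiles:
        for i in range(truth.n_per_type):
            sid = f"ref_{label}_{i + 1}"
            data[sid] = np.clip(
                m.to_numpy() + rng.normal(0.0, truth.within_sd, len(m)),
                0.0, 1.0)
            cols.append(sid)
            labels.append(label)
    beta = BetaMatrix(pd.DataFrame(data, index=truth.m_neuron.index)[cols])
    return beta, pd.Series(labels, index=cols, name="cell_type")


def simulate_clock_sites(probe_ids, n_sites: int = 105,
                         slope_range: tuple[float, float] = (0.0005, 0.003),
                         seed: int = 0) -> ClockModel:
    """Draw a synthetic age clock: random sites with signed per-day slopes."""
    rng = np.random.default_rng(seed)
    n_sites = min(n_sites, len(probe_ids))
    sites = rng.choice(np.asarray(probe_ids, dtype=object), size=n_sites,
                       replace=False)
    lo, hi = slope_range
    slopes = rng.uniform(lo, hi, n_sites) * rng.choice([-1, 1], n_sites)
    return ClockModel(list(sites), slopes)


def simulate_gene_sets(manifest: ProbeManifest, dm_genes,
                       n_terms: int = 100, enriched_term_overlap: float = 0.8,
                       seed: int = 0,
                       include_undersize: bool = True) -> GeneSetCollection:
    """Random GO-like terms plus one designed term hosting planted DM genes.

    ``enriched_term_overlap`` is the fraction of planted DM genes placed in
    the designed term (0 makes it behave as a null term). A deliberately
    undersized term (5 genes) is included to exercise the downstream
    minimum-size filter.
    """
    rng = np.random.default_rng(seed)
    genes = sorted({g for gs in manifest.table["genes"] for g in gs})
    terms: dict[str, tuple[str, tuple[str, ...]]] = {}
    for t in range(n_terms):
        size = int(rng.integers(10, min(200, max(11, len(genes)))))
        members = tuple(rng.choice(genes, size=min(size, len(genes)),
                                   replace=False))
        terms[f"TERM{t + 1:04d}"] = (f"random term {t + 1}", members)
    if include_undersize and len(genes) >= 5:
        terms["TERM_SMALL"] = ("undersized term",
                               tuple(rng.choice(genes, size=5, replace=False)))
    dm_sorted = sorted(set(dm_genes) & set(genes))
    n_in = int(round(enriched_term_overlap * len(dm_sorted)))
    chosen = (list(rng.choice(dm_sorted, size=n_in, replace=False))
              if n_in else [])
    filler_pool = [g for g in genes if g not in chosen]
    n_filler = max(0, max(20, n_in // 4))
    filler = list(rng.choice(filler_pool,
                             size=min(n_filler, len(filler_pool)),
                             replace=False))
    members = tuple(dict.fromkeys(chosen + filler))
    terms["TERM_DESIGNED"] = ("designed enriched term", members)
    return GeneSetCollection(terms)
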