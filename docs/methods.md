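# Methods

This note documents the statistical procedures devmeth implements, the
choices made where a convention had to be fixed, what the synthetic data
generator does and does not emulate, and known limitations.

## Data model and conventions

Beta values are methylation proportions in [0, 1]; values within 1e-9 of
the interval are clipped, anything further out is an error naming the cell.
Manifest positions are 1-based single-bp probe coordinates; every exported
interval (BED) is 0-based half-open. Developmental stages are mapped to
days since E14.5 (E14.5→0, E18.5→4, P7→26, P35→54, P70→89, taking birth at
~E19) and this continuous encoding is used *only* where age enters a model
as a slope (pseudo-age association, per-day trends); all differential
models treat age as categorical. Missing betas are disallowed after QC —
the pipeline drops failing probes entirely rather than imputing.

## QC and normalization

Sample gates: minimum median methylated and unmethylated intensity 2000
(inclusive), detection-failure fraction strictly below 1% at detection
P = 0.05, bisulfite conversion ≥ 90% (inclusive). Detection P values are
consumed as precomputed summaries (per-sample fractions, per-probe
failure counts); raw intensity processing is out of scope. Probe removal:
manifest technical-variability flag, MFG-change flag, chromosome "0", or
detection failure in more than one sample. Each removed probe is assigned
one reason in a fixed precedence order (flag > MFG > chr0 > detection);
the retained set is order-independent.

Quantile normalization forces every sample onto the across-sample mean of
sorted values; ties within a sample get the average of the reference values
at their rank positions. On tie-free data the transform is an exact fixed
point; boundary clipping can create ties whose averaged values shift
slightly on re-normalization — a property shared with the standard
implementations, documented here because tests check the fixed point on
tie-free data only.

Variable probes: per probe, the sample values' 10th-to-90th-percentile
range (linear-interpolation quantiles) must *strictly* exceed 0.05. The
"inner 80%" could alternatively be read as trimming 10% of samples per
tail; the interpolated-quantile reading is the default and the fraction is
configurable.

## Cell-type deconvolution

Two-cell-type reference training: autosomal sites only; per-site one-way
ANOVA across cell types; among sites with P < 1e-8, the top 50 most
significant sites where a type's mean lies below all other types' means
(hypo) and the top 50 above (hyper) are taken per type, and the panel is
the deduplicated union. With two types, "hypo in A" coincides with "hyper
in B", so four top-50 lists deduplicate to 100 sites; for more than two
types the panel is 2×50 per type pre-deduplication. Fewer than 50
qualifying sites in a direction takes all available with a warning.

Proportions are estimated per sample by non-negative least squares against
the per-type mean profiles — no sum-to-one constraint, so weights may sum
below 1 for profiles unlike any reference; the reported neuronal
proportion is the raw NeuN+ weight. The error score is the RMS deviation
between observed and reconstructed profile over panel sites; it tracks the
observation noise (≈ the noise sd for well-modelled samples) and rises for
samples with unmodelled composition. Projection requires ≥ 80% of panel
sites to be present in the data.

## Pseudo-age

Score = Σ sᵢ·βᵢ over the clock sites present (missing sites are dropped
with a warning), with sᵢ the per-day OLS slope of methylation on
chronological age. The score is a raw weighted sum — no intercept, no
rescaling to days — so it is unitless; only its association with age (and
any genotype shift) is interpretable, tested with
`score ~ age_days + genotype`. The clock is treated as an input table; a
fitting helper and a synthetic-clock generator are provided because the
original site weights derive from an external blood-tissue study.

## Probe-level differential methylation

Per probe, OLS of normalized beta on genotype (0/1, WT reference; negative
coefficients = hypomethylated in the heterozygote), categorical age
(E14.5 reference), categorical chip, and the *estimated* neuronal
proportion. Fits are vectorised: one shared design matrix, one linear
solve for all probes; a rank-deficient design is an error naming the
aliased columns. Constant probes get coefficient 0 and P = 1 by convention
so downstream aggregation stays total; otherwise P values are clipped into
(0, 1]. Interactions are tested by the nested F contrast against the
genotype×age model (numerator df = n_ages − 1).

Bonferroni DMP threshold: 0.05 divided by the number of probes *actually
tested* by default (statistically defensible), with an `n_tests` override
to reproduce the genome-wide convention in which the denominator is the
full post-QC site count (0.05/262,086 prints as 1.91e-7). Classification
is strict (< threshold). Litter is recorded in the sample sheet but not
modelled; the study design balances litters across groups.

## Empirical Brown's method

Fisher's Ψ = −2Σ ln pᵢ is modelled as a scaled chi-square c·χ²_f with
Var[Ψ] = 4k + 2Σ_{i<j} cov(wᵢ, wⱼ), where wᵢ(s) = −2 ln ECDFᵢ(xᵢ(s)) is
computed from each test's standardized data row. The ECDF is
right-continuous with values rank/n in (0, 1], avoiding log(0); this
choice shifts the small-sample covariance slightly and is therefore fixed
and documented. Degrees of freedom are capped at Fisher's 2k (c floored at
1), so the correction can only be conservative relative to Fisher. k = 1
returns the input P; a degenerate (constant) data row contributes zero
covariance. Dependence is estimated from the same normalized beta rows the
models were fitted on, not from residuals (the cited method's usage); a
residual-based variant would remove covariate-driven dependence and is a
possible extension. The Kost–McDermott analytic covariance approximation
is intentionally not implemented (empirical only).

Gene aggregation groups probes by annotated gene (multi-gene probes fan
out to each), optionally restricted to promoter probes, and applies a
Bonferroni adjustment over the number of genes with ≥ 1 contributing
probe.

## DMR calling

A candidate region is a maximal run of ≥ 2 probes, each with nominal
genotype P < 0.05 and a common direction, in which adjacent probes are
spaced strictly less than 1500 bp apart. "Consecutive" is read as
consecutive among *tested* probes: an intervening tested probe that is
non-significant or of opposite sign terminates a run (this prevents
regions spanning contradictory evidence); `skip_nonsignificant=True`
implements the permissive reading. Member P values are Brown-combined;
the Bonferroni denominator is the number of candidate regions found
genome-wide, i.e. data-dependent. Region bounds are the outermost member
probe positions (not extended beyond probes). Annotation: any gene whose
body expanded by 1500 bp overlaps the region (closed intervals, 1-based).

Because candidates are pre-selected for all-member nominal significance,
their combined P values are conditionally small and the candidate-count
Bonferroni is liberal by construction: null data typically yields a few
"significant" two-probe regions per genome-scale run. This is a property
of the regional procedure itself, visible in the pipeline's recovery
report; region calls should be read as prioritised candidates, not
familywise-error-controlled discoveries.

## Enrichment

The gene universe is every gene annotated to ≥ 1 variable probe; probe
density (count of variable probes per gene) enters the logit model as
log₁₀(count) because density spans orders of magnitude. Terms with < 10
background genes are excluded. Both the model-based odds ratio
(exponentiated membership coefficient, Wald P) and the raw 2×2 odds ratio
are always reported. Perfect separation triggers a flagged ridge-penalised
IRLS refit (λ = 0.01, intercept unpenalised) rather than a crash; a
constant-density universe drops the aliased density column.

Conditional independence of significant terms: greedily retain the
Bonferroni-significant term with the largest marginal odds ratio (ties:
smaller P, then term id), add its membership as a covariate, refit the
remaining significant terms, keep those with conditional P < 0.05
(unadjusted — the conditional criterion is a documented choice), iterate.
A candidate whose membership column does not increase the design-matrix
rank over retained covariates is collinear and dropped. Biotype
enrichment reuses the same model with a biotype indicator; the
shared-signal adjustment is implemented as conditioning on the supplied
term-membership covariates. Set-overlap tests use Fisher's exact test
with the conditional-MLE odds ratio; threshold sweeps report
Woolf-logit 95% CIs with Haldane correction, and a degenerate 2×2 table
(constant margin) reports OR = 1.

## Assay quantification

Standard curves regress known concentration on absorbance (≥ 3
standards). The kinetic rate ΔC/Δt is the OLS slope of concentration on
time over the full window — more robust than first-minus-last for noisy
kinetics, with a two-point variant available. Net activity is
(rate₋ᵣₒₜ − rate₊ᵣₒₜ)/(protein mass)·D with protein mass = concentration ×
loaded volume (0.66 μg/μL × 2 μL by default); the grouping of the
time/protein/dilution terms is stated here because display conventions for
the formula are ambiguous. Negative net activity (inhibitor-insensitive
signal) is permitted and flagged. Group comparison: two-way ANOVA
(genotype × timepoint factor) with Šidák-adjusted (1 − (1 − p)^m) pairwise
genotype contrasts per factor level.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study's design skeleton: 2 genotypes × 5
stages × 5 replicates, probes laid out in gene blocks (10 probes per gene,
promoter first, 200–800 bp within-gene spacing, 3–10 kb between genes)
across 5 autosomes plus a small X set and chromosome-"0"/flagged probes
for QC to remove. Betas are built as
w·m_neuron + (1 − w)·m_glia + age effects + clock trend + chip shift +
γ·δ + ε, clipped to [0, 1] (clipping fraction reported, < 1% under
defaults). Defaults: 5,000 probes; 600 cell-type discriminatory sites
(|Δ| = 0.5); neuronal fraction 0.35 + 0.0025/day ± 0.03; 50% of probes
with categorical age effects (sd 0.02); 105 clock sites with |slope| ∈
[5e-4, 3e-3]/day; 2 chips with sd 0.01 shifts; 50 isolated DMPs and 8 DMR
blocks (3–8 probes) at |δ| = 0.15, two blocks containing a deliberate
≥ 1500 bp internal gap to exercise region splitting; noise sd 0.02;
20 snoRNA genes nested in host genes, most of them hosts of planted
effects so biotype enrichment is exercised. All sizes were chosen so a
full run takes seconds while every stage operates well away from its
boundary conditions.

Deliberately not emulated: raw two-channel intensities and IDAT-level
detection statistics, realistic bimodal beta distributions (means are
uniform, noise Gaussian — adequate for calibration because the models act
per probe), probe-type chemistry differences, litter structure, spatial
correlation of null probes beyond gene-block layout. Passing tests
therefore demonstrate the *procedures* are correct and calibrated under
the assumed generative structure, not that effect sizes on real arrays
will match.

## Numerical choices and degenerate inputs

Quantile normalization of a single sample is the identity (warning).
Probes with exactly zero genotype coefficient never qualify for DMRs.
NNLS handles the w ≥ 0 constraint exactly; identical reference profiles
are rejected as rank-deficient. The interaction F statistic treats
RSS₀ − RSS₁ ≤ 1e-300 as an identical fit (F = 0, P = 1). P values are
floored at the smallest positive normal double rather than reported as 0.
All simulation randomness flows from a single integer seed through
`numpy.random.SeedSequence`, making every pipeline run bit-reproducible.

## Problem sizes used in the test and acceptance suites

Oracle and calibration checks run at deliberately small scale: 200-probe
toy chromosomes (20 random configurations) for the DMR enumeration
oracle; k = 5 tests over 200 samples for the Brown/Fisher comparison;
100 Monte-Carlo samples for deconvolution recovery; 1,000 probes for null
calibration of the probe model; 500 random terms for enrichment
calibration; 20 seeded full-pipeline null runs for familywise-error
behaviour; and the default 5,000-probe design for power and recovery.
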