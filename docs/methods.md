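# Methods

## Study design being modelled

The pipeline targets a bulk BRB-seq design over the GnRH neuron migratory
axis: four (stage, region) spacetime points — E12.5 nose, E14.5 nose, E14.5
brain, E18.5 brain — each sampled in two FACS fractions, GFP+ (GnRH
neurons) and GFP− (surrounding tissue), with a few biological replicates
per cell. Downstream, trajectory gene sets derived from the GFP+ fraction
are used as collapsing units for a rare-variant burden comparison of a CHH
patient cohort against summary-level reference-database controls.

## Synthetic data generator

`simulate_counts` draws per-gene baseline abundances from a log-normal
(natural-log mean 5, SD 1.5 → median ≈ 150 expected counts), per-sample
library factors from a log-normal with CV 0.2, and counts from
NB(mean = s_j·μ_gi, φ) with Var = μ + φμ² and φ = 0.1 — values typical of
small-replicate bulk RNA-seq. A planted gene's stage means follow
μ_{i+1} = μ_i · fold^{d_i} with fold 2.5 and d the trajectory code element.
The default planted mix is the six single-step codes (+00, −00, 0+0, 0−0,
00+, 00−), 50 genes each, mirroring the dominant "main trajectories" of a
stagewise design; replicates default to 4 per condition.

Planted (dynamic) genes draw their baseline from the **upper half** of the
abundance distribution (log-mean ≥ 5) while flat genes span the full
range. Rationale: developmentally regulated genes that a FACS/BRB-seq
design can classify are the robustly detected ones, and at fold 2.5 with 4
replicates the classification of low-abundance genes is noise-limited
rather than biology-limited; planting them would only measure shot noise.

The GFP− fraction is flat unless a ligand program is planted:
`simulate_lr_pairs` picks planted GFP+ genes as receptors (each serving up
to two pairs — ligand–receptor databases are hubby, which also gives the
module detector non-trivial components) and rewrites the GFP− stage means
of distinct flat genes. "Parallel" ligands reuse the receptor's stage
fold-pattern, "anti-parallel" ligands the reciprocal pattern (the opposing
trend — elementwise reversal of a non-monotone profile would not give a
scalar product near −1, trend inversion does), "independent" ligands stay
flat.

`simulate_variants` emulates the cohort design (defaults 425 cases,
54 704 controls): per trajectory set, case carriers are
Binomial(n_cases, p₁) with p₁ solving the planted odds ratio against the
base carrier rate on the odds scale (p₁ = OR·odds₀/(1+OR·odds₀); this is
always solvable, so the generator validates the base rate instead of an
"impossible OR"); control carriers are Binomial(n_controls, p₀) emitted as
summary allele counts over a handful of variant records without subject
ids, forcing the pipeline to exercise the distinct-individual assumption
and the carrier ceiling. Synonymous variants are matched at OR = 1. For
every passing variant, `qc_fail_fraction` decoys are emitted, each
violating exactly one named filter, cycling the full filter vocabulary
(indel-length decoys are given a frameshift consequence because a
synonymous SNV cannot carry an indel).

All randomness flows from one seed through `numpy.random.SeedSequence`
stream splitting, so sub-simulations are independently reproducible and
identical seeds give byte-identical outputs.

What the generator does **not** model: batch structure, GC/length biases,
sample swaps, ambient contamination of the FACS gates, linkage between
variants, relatedness or ancestry structure in the cohort. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to those real-data artifacts.

## Differential expression

TMM composition factors follow the standard recipe: reference sample by
upper-quartile closeness to the mean, pairwise per-gene log-ratios (M) and
average abundances (A), 30%/5% two-sided trims, inverse-variance precision
weights, factors rescaled to geometric mean 1 (verified against
`edgeR::calcNormFactors` to < 0.005 on fixtures). Effective library size =
column sum × factor; CPM are per-million of effective size.

Dispersion is estimated per gene by method of moments on counts scaled to
a common library size: per replicate group, φ̂ = (v − c̄·m)/(m² − v/n); the
denominator `m² − v/n` removes the first-order Jensen bias of m² (without
it the estimator runs ~3–10% low and the exact test turns anticonservative).
Group estimates are pooled with residual-df weights, a mean–dispersion
trend is fit as a running **mean** over 20 abundance bins (the per-gene
raw distribution is right-skewed, so a median trend sits low), and genes
are shrunk toward the trend with weight prior_df/(prior_df + residual_df),
prior_df = 10, floored at 1e-4.

The per-transition test conditions on the total of the two condition sums
after scaling counts to the common effective library size (sums rounded to
integers): with S₁ ~ NB(n₁μ, φ/n₁) and S₂ ~ NB(n₂μ, φ/n₂), the two-sided
p doubles the smaller conditional tail of the observed split, capped at 1.
Genes pass an expression filter (CPM > 1 in ≥ 2 samples) before testing;
all-zero genes are dropped. On null simulations at the study conditions
the realized type-I error at nominal 0.05 is ~0.05, and the p-value
ranking agrees with edgeR's exact test at Spearman ρ > 0.99 on fixtures.

## Trajectory encoding and its statistical ceiling

Codes use raw p < 0.01 (not FDR) plus |log2FC| > 1, per transition,
applied to the prior-count (0.5) fold changes. Study-style labels
(T01, T-03, …) are supported only through a user-supplied alias table;
canonical code strings are the primary identifiers.

A point worth stating explicitly: the FC > 2 gate is applied to the
*estimated* fold change. At planted fold 2.5 (true log2FC = 1.32),
dispersion 0.1 and 4v4 replicates, the sampling SD of any unbiased log2FC
estimate is at least √(2φ/4)/ln 2 ≈ 0.32 even at infinite counts, so
P(log2FĈ > 1) ≤ ~0.84 per transition and exact three-letter code recovery
is capped near 0.84·0.99² ≈ 0.82 — for any method. The implementation
measures ~0.81 with essentially all errors being missed fold calls, i.e.
it operates at the information-theoretic ceiling of the rule; flat genes
are misassigned at ~1–2%.

## Identity markers

Anchor ranking: Pearson r on log2(CPM+1) over all samples of both
fractions (Spearman available), p from the t transform with n−2 df, BH
across genes; the anchor is excluded from its own ranking. Module scores
bin genes into 25 equal-count bins by average expression and sample up to
100 non-set controls per set gene from its bin, expanding symmetrically to
the nearest non-empty bins when a bin holds no controls; if no control
exists anywhere the control mean is defined as 0. Scores are deterministic
under a fixed seed and are verified against an independently coded
procedural oracle to 1e-12.

## Communication network

Stage profiles are mean log2(CPM+1) per stage, centered and scaled to unit
norm; centering makes the scalar product a correlation, matching the
intended reading of "parallel/anti-parallel trends" (plain normalization
without centering would conflate abundance with trend). Constant raw
profiles are flagged degenerate and score 0. The expressed gate drops
pairs whose ligand or receptor never reaches CPM 1 in any stage of its
fraction. The 3-way class threshold τ = 0.5 and the module thresholds
(|strength| ≥ 0.8, ≥ 2 edges per connected component) are exposed as
parameters; module detection is deliberately simple connected components —
the finer sub-module structure in real data involves judgment calls no
threshold reproduces.

## Enrichment

One-sided hypergeometric upper tails with the background fixed to the
genes actually tested for trajectories (enrichment against untested genes
inflates significance). Bonferroni is the default adjustment, BH optional:
a transparent correction was preferred over emulating a web service's
proprietary one. Results are ordered by (adjusted p, recall) so ties break
toward higher recall.

## Burden test

The filter cascade applies the eleven hard thresholds listed in the
README; a missing popmax passes (absent from the control database), any
other missing QC value fails its filter — a variant is never retained on
unverifiable evidence. The SpliceAI qualifying cutoff is 0.5 (the tool's
conventional "possible splice-altering" threshold); splice-site ±2 bp and
SpliceAI predictions are treated as a union. Carrier counting is exactly
the stated approximation — distinct case subjects versus summed control
alleles with a ceiling at n_controls — including its conservative bias
(the worked-example OR ≈ 7 against a planted 8 reflects it); it is not
"corrected". Bonferroni multiplies by the number of trajectory sets,
per stratum (all / KS / nCHH). Retention requires both the corrected
Fisher p and the one-sided z comparing ln OR_PTV to ln OR_syn (Woolf SEs,
Haldane +0.5 on all four cells only when some cell is zero, and only for
OR/CI/z — the exact test always sees raw counts).

Calibration facts the suite verifies: Woolf 95% intervals cover a true
OR 3 in 93–97% of tables at the cohort's scale; the z comparison holds
its 5% level (3–7%) in the moderate-count regime (expected case carriers
~20). At very small expected counts (~4) the z test is conservative
(~2–3%) because E[1/a] > 1/E[a] — a known property of the Woolf SE, so the
calibration check is run where the normal approximation is meant to hold.

## Problem sizes

Simulation-based checks use: 2000-gene null and planted studies at 4
replicates (one study shared across the suite), 200 burden simulations for
OR recovery, 50 for the synonymous-enriched negative control, 1000 tables
each for CI coverage and z calibration, 200 small studies for the
independent ligand–receptor null, and exhaustive tail-probability grids
(row margins ≤ 30 for Fisher, backgrounds ≤ 50 for enrichment) against
integer-combinatorics enumeration. These sizes give Monte-Carlo standard
errors comfortably below the asserted margins while keeping the whole
suite in the minutes range on one CPU.

## Known limitations

- The DE engine is an exact-style NB test, not a quasi-likelihood GLM: no
  covariates, no batch terms, single-batch designs only.
- Trajectory encoding is threshold-based by construction (no pseudotime or
  smoothing); its recovery ceiling under noisy fold estimates is discussed
  above.
- The burden test inherits the distinct-individual and carrier-ceiling
  approximations of summary-level controls, and performs no kinship or
  ancestry adjustment.
- Gene symbols are the only identifier namespace; users collapsing
  variants annotated with Ensembl IDs must map them first.
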