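# gnrhtraj

Analysis pipeline for the developmental transcriptomics of migrating GnRH
(gonadotropin-releasing hormone) neurons, and for linking their expression
trajectories to human reproductive genetics.

GnRH neurons are born in the nasal placode and migrate into the hypothalamus
during embryogenesis; failures of this program cause congenital
hypogonadotropic hypogonadism (CHH), including its anosmic form (Kallmann
syndrome, KS) and the normosmic form (nCHH). This package implements the
analytical chain for a bulk RNA-seq design that samples FACS-sorted GFP+
GnRH neurons and surrounding GFP− cells at four spacetime points — E12.5
nose, E14.5 nose, E14.5 brain, E18.5 brain — and a rare-variant cohort
analysis collapsed over the resulting trajectory gene sets:

1. **Stagewise differential expression** (`gnrhtraj.de`). Counts are
   TMM-normalized (trimmed mean of M-values: 30% M-trim, 5% A-trim,
   precision weights, factors rescaled to geometric mean 1). Per-gene NB
   dispersion φ (Var = μ + φμ²) is estimated by method of moments and
   shrunk toward a mean–dispersion trend with weight
   `prior_df / (prior_df + residual_df)`. Each of the three consecutive
   transitions (τ1: E12.5-nose→E14.5-nose, τ2: E14.5-nose→E14.5-brain,
   τ3: E14.5-brain→E18.5-brain) is tested with an NB exact-style
   conditional test (two-sided by doubling the smaller tail), with
   Benjamini–Hochberg FDR per transition and
   `log2FC = log2((CPM₂+0.5)/(CPM₁+0.5))`.
2. **Trajectory codes** (`gnrhtraj.trajectories`). Per transition, a gene is
   coded +1 if p < 0.01 and FC > 2, −1 if p < 0.01 and FC < 1/2, else 0,
   giving a 3-letter code over {+, 0, −} (e.g. `+00`; `000` is flat).
   Non-flat codes with ≥ 10 genes become trajectory gene sets (GMT).
3. **Identity signatures** (`gnrhtraj.identity`). All detected genes ranked
   by Pearson r with an anchor gene (Gnrh1 in the real study) on
   log2(CPM+1) across all samples, p from `t = r·√((n−2)/(1−r²))`, BH
   adjusted; plus a module score — mean expression of a gene set minus the
   mean of expression-bin-matched control genes (the Seurat
   ModuleScore / scanpy `score_genes` contract).
4. **Dynamic cell–cell communication** (`gnrhtraj.ccc`). For each curated
   ligand(GFP−)→receptor(GFP+) pair (CellTalkDB-style two-column table),
   edge strength is the scalar product of the two centered, unit-norm
   4-stage mean-expression profiles (a correlation in [−1, 1]); edges are
   parallel (> τ), anti-parallel (< −τ) or neutral (τ = 0.5), and modules
   are connected components among |strength| ≥ 0.8 edges.
5. **Trait-gene enrichment** (`gnrhtraj.enrichment`). One-sided
   hypergeometric over-representation of an external trait gene list (e.g.
   GWAS-catalog reproductive traits: age at menarche EFO_0004703, age at
   menopause EFO_0004704, age at first sexual intercourse EFO_0009749)
   within the trajectory sets, against the background of trajectory-tested
   genes; recall = intersection / term size; Bonferroni by default.
6. **Rare-variant burden** (`gnrhtraj.burden`). Protein-truncating variants
   (stop-gain, frameshift, splice site ±2 bp, or SpliceAI ≥ 0.5) and matched
   synonymous variants pass a hard QC cascade (popmax ≤ 0.01%, QUAL ≥ 50,
   MQ ≥ 55, MQRankSum ≥ −2.5, allele-depth ratio ≥ 20%, no segmental
   duplications, local-database count ≤ 3, pedigree count ≤ 5, no control-DB
   flag, indels ≤ 3 nt). Per trajectory set, distinct case carriers are
   counted against summary-level control allele counts (each control allele
   assumed a distinct individual, with a ceiling at the number of controls).
   A one-sided Fisher exact test gives the burden p; the odds ratio gets a
   Woolf 95% CI, `exp(ln OR ± 1.96·SE)`, `SE = √(1/a+1/b+1/c+1/d)`
   (Haldane–Anscombe +0.5 on all cells only when a cell is zero, never for
   the exact test); and a trajectory is retained only if its
   Bonferroni-corrected p passes **and**
   `z = (ln OR_PTV − ln OR_syn)/√(SE²_PTV + SE²_syn)` shows the PTV odds
   ratio significantly exceeding the synonymous one.

A synthetic-data generator (`gnrhtraj.simulate`) emulates every input with
known ground truth — NB counts over the 4×2 design with planted trajectory
codes, ligand–receptor co-dynamics, trait gene lists, and case/control
variant tables with planted odds ratios and QC-failing decoys — so the whole
chain is testable end to end.

## Worked example

The numbered drivers under `analysis/` run the whole chain on a synthetic
study (2000 genes, 4 replicates per condition, dispersion 0.1, planted fold
2.5, 6 planted single-step trajectories of 50 genes, 60 ligand–receptor
pairs, a 425-case / 54 704-control variant cohort with OR 8 planted on one
trajectory):

```bash
for step in analysis/0*.py; do python "$step" --out results; done
```

which prints, among other things:

```
simulated 2000 genes x 32 samples (300 planted across 6 trajectories)
GFP+ tau1: 2000 genes tested, 78 significant (FDR<0.05, FC>2)
GFP+: 265/2000 genes dynamic, 6 trajectory sets with >= 10 genes
planted-code exact recovery (GFP+): 81.3%
60 edges scored (tau=0.5); planted-class accuracy 100% on 42 planted pairs
planted trait list overlaps 0+0; top hit: 0+0 (recall 0.51, adjusted p 1.92e-29)
* +00: OR 7.01 [4.80, 10.26] Fisher p 2.16e-15 z_p 0.000 RETAINED
```

Reading the last line: the trajectory carrying the planted burden is the
only one retained — its case carrier count against the control allele
ceiling yields OR ≈ 7 with a Woolf interval covering the planted value 8,
it survives Bonferroni correction over the 6 trajectories, and the z gate
confirms the PTV odds ratio exceeds the synonymous one. The 81.3% exact
trajectory recovery reflects the sampling noise of the estimated fold
change against the FC > 2 gate at 4 replicates (see `docs/methods.md`).

The same steps are exposed as CLI subcommands
(`gnrhtraj simulate|de|trajectories|identity|ccc|enrich|burden`, each with
`--config`, `--seed`, `--out-dir`), writing TSV/GMT/GraphML outputs plus a
run manifest (parameters, seed, input hashes) beside them.

## Notes

- Gene identifiers are symbols, matched case-insensitively (mouse/human
  symbol case differs); variant tables for the burden test must use the
  same namespace.
- Trait gene lists are plain-text inputs (one symbol per line) or GMT; this
  package does not query the GWAS catalog.
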