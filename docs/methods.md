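# Methods

This note documents the model, the synthetic data it is exercised on, the
numerical conventions, and the design choices that were genuinely open.

## The risk model

The score for an individual with encoded genotypes `F_SNP` is produced by
three stages.

**Encoding.** An observed genotype with `k` alternative alleles maps to the
pair `(2−k, k)`; a missing genotype maps to `(0, 0)`. The three observed
states are affinely dependent (they lie on the line ref+alt = 2), so under a
*linear* aggregation the two-dimensional encoding is informationally
equivalent to the additive count except at missing entries — the distinct
(0,0) state is the encoding's genuine extra expressiveness. This is worth
knowing when interpreting ablations: with little missingness the
`additive_encoding` variant is expected to sit very close to the full model.
No imputation is performed anywhere.

**Partial connection layer.** For each gene g with m_g selected SNPs within
±250 kb of its interval (or linked by the nearest-gene fallback), a trainable
weight vector W_g of length 2·m_g produces the scalar gene feature
`F_gene,g = W_gᵀ F_SNP,g`, with no nonlinearity. Internally all gene columns
form one dense matrix under a boolean mask that fixes the sparsity pattern;
masked entries start at zero and every gradient is masked, so they remain
exactly zero through any number of optimizer steps (asserted by tests).
Genes that end up with no selected SNPs are dropped — the sequence the
recurrent layer sees covers only SNP-bearing genes. The 250 kb window is
anchored at the gene interval boundaries (not the TSS): the choice is
symmetric, testable, and does not require transcript annotation.
Nearest-gene distance is the distance to the closer interval edge (0 inside
the gene); equidistant ties go to the lexicographically smaller gene id.

**Per-chromosome BiLSTM and head.** Genes on a chromosome, in ascending
start-position order, form the input sequence of a bidirectional LSTM with 4
hidden units per direction; each chromosome has its own unshared parameters.
The per-step states h_t = (h→_t, h←_t) of all chromosomes are concatenated
(together with standardized covariates, when used) and mapped by a single
linear unit through a sigmoid. Because the head is linear over this
concatenation, interactions *across* chromosomes are not representable —
only loci on the same chromosome can interact through the recurrence. The
benchmark generator therefore plants its interacting pairs within
chromosomes (in different LD blocks and genes), which is the interaction
pattern the architecture is built to capture.

Variants: `no_partial_layer` feeds the encoded SNPs directly as the
per-chromosome sequences (one SNP per step, input dimension 2);
`additive_encoding` keeps the partial layer but uses 1-dimensional alt-count
inputs (missing → 0).

**Training.** The loss is class-weighted binary cross-entropy with
ω0 = n/(2(n−n₊)) and ω1 = n/(2n₊), computed once from the full training
split; probabilities are clamped at 1e-7. An L2 penalty (default 1e-4)
applies to the BiLSTM weight matrices only; inverted dropout (default 0.2)
acts on the BiLSTM outputs during training only. Optimization is Adam at a
fixed learning rate (library default 1e-3; the benchmarks use 3e-3, which
converges faster for these small networks within their epoch budget), batch
size 128, at most 50 epochs, with early stopping (patience 5) on a
stratified internal 80/20 validation split; the best-validation-loss
parameters are restored. All randomness — initialization, shuffling,
dropout, splits — flows from one integer seed, and two runs with the same
seed produce bit-identical scores. The network is small by construction
(hidden size 4, scalar gene features), so forward and backward passes are
written directly in numpy with hand-derived gradients; correctness is pinned
by finite-difference tests at relative tolerance 1e-4. Forget-gate biases
are initialized to 1, other parameters uniformly in ±1/√fan-in.

## SNP selection

Clumping is greedy: restrict to p ≤ threshold, visit SNPs by ascending
p-value (ties by (chrom, pos) then id); each unassigned SNP becomes an index
SNP and absorbs unassigned same-chromosome SNPs within 250 kb (radius
semantics: |Δpos| ≤ window) whose genotypic r² with it — the squared Pearson
correlation of alt-counts over complete cases in the reference panel —
reaches the r² threshold. Monomorphic panel SNPs neither absorb nor get
absorbed (r² treated as 0). The "none" r² setting disables clumping and the
window entirely: pure p-thresholding. These conventions are pinned by a
brute-force oracle that replays the greedy procedure from the full r²
matrix on random instances across the whole 20-point grid.

Grid search trains one candidate per parameter pair and scores it on a
stratified 80/20 split of the training cohort, so the grid is not chosen by
in-sample fit; `select_on_train=True` restores the looser protocol of
evaluating on the training cohort itself. Pairs selecting zero SNPs are
recorded as NaN and excluded from the argmax.

## Baselines

The pruning-and-thresholding PRS is the classical weighted sum of additive
alt-counts (missing → 0) with GWAS betas over the selected SNPs. The lasso
is an L1-penalized logistic classifier on additive counts, with the penalty
strength chosen by stratified cross-validated AUC over a log-spaced grid
(1e-3 … 1e2). Covariates, when supplied, are standardized and appended as
penalized features — the solver used cannot exempt a subset from the L1
penalty; the shipped benchmarks use no covariates, so this affects no
reported comparison.

## Risk stratification

Odds ratios follow the top-group contingency form OR = (TD·RE)/(TE·RD),
where the top group is the ⌈fraction·n⌉ highest scores (ties broken by
stable sample order, tie counts logged). An empty TE or RD cell reports +∞
with a flag — no silent continuity correction. The proportion of the
population at k-fold risk sweeps every top-k cutoff (k = 1 … n−1) and
returns the largest fraction whose odds ratio reaches the fold — the
natural operationalization of shaded fold-risk proportions, pinned by a
brute-force sweep oracle. Percentiles are average-rank based; bin b of the
100-bin prevalence curve covers percentiles (b, b+1], and the
sample-size-weighted mean of bin prevalences equals the overall prevalence
exactly. AUC is the tie-corrected Mann–Whitney statistic. Cross-validation
is stratified k-fold with selection and training nested inside each training
fold. The SNP-removal experiment drops the k smallest-p variants from the
summary statistics before selection, refits on a fixed stratified split, and
holds all seeds fixed across removal levels.

## The simulator

Genotypes come from a latent-Gaussian model: within an LD block each
haplotype's latent vector is √ρ·shared + √(1−ρ)·private, thresholded at the
normal quantile of the SNP's MAF, so marginal genotype frequencies are
Hardy–Weinberg at that MAF and adjacent SNPs correlate within blocks. This
is *not* a coalescent: it reproduces exchangeable within-block LD, MAF
spectra and missingness, but no recombination gradients, population
structure, relatedness or selection — so passing benchmarks demonstrate
method behaviour under controlled LD and architecture, not performance on
real biobank data, whose headline numbers are not reproducible without
access-restricted genotypes.

Phenotypes follow a liability threshold: liability = additive terms
(β per alt-count) + epistatic terms (a weight added when *both* loci of a
pair carry ≥ 1 alternative allele — the joint-carrier indicator, the
simplest interaction invisible to additive scores) + optional covariate
terms + Gaussian noise. The noise variance is set from the realized genetic
variance so that the genetic component explains the configured fraction
(`heritability_like_scale`) of liability variance in-sample; cases are the
samples above the (1−prevalence) quantile of the realized liability, so case
counts are controlled even at small n. In the benchmark builders, phenotypes
are generated from *complete* genotypes and assay missingness is masked in
afterwards — disease risk must not depend on which entries failed
genotyping. (The plain `simulate_phenotype` operation works on whatever
matrix it is given, treating missing entries as non-contributing.)

The discovery GWAS is a per-SNP allelic score test on the 2×2 allele-count
table over complete cases: β is the log odds ratio (Haldane 0.5 correction
only when a cell is empty) and p comes from the 1-df Pearson chi-square.
Monomorphic or all-missing SNPs report (β=0, p=1). Null p-values are
verified uniform by KS test.

## Benchmark study conditions

* **Epistatic**: 200 SNPs on 4 chromosomes (LD blocks of 10, ρ=0.3, MAF
  0.2–0.5, 2% missing), five joint-carrier pairs of weight 2.0 each and *no*
  additive effects, heritability-like scale 0.8, prevalence 0.2; panel
  n=500, discovery n=2000, cohort n=4000, 70/30 train/test, five seeds.
  Selection uses p ≤ 5e-3 without clumping — the interacting loci are
  marginally visible only through carrier-frequency leakage, and all methods
  must receive the same permissive SNP set for the comparison to isolate the
  modelling difference.
* **Additive**: same genome, 20 causal SNPs (one per block) with β = 0.35,
  heritability-like scale 0.5 — the regime where the linear baselines are
  near-optimal and the deep model should match, not beat, the lasso.
* **Robustness**: 100 SNPs, all causal with β decaying linearly from 0.4 to
  0.004, discovery n=3000, cohort n=2000. The graded spectrum makes each
  removal level (top 10/20/50 GWAS SNPs) strip real signal while leaving
  weaker loci selectable; the base threshold is p ≤ 0.05 because after
  removing the top 50 hits nothing on a 100-SNP genome survives the stricter
  grid thresholds.

Problem sizes (n=4000 cohorts, 200 SNPs, five seeds, 40-epoch budget) are
chosen so the complete benchmark suite runs in a few minutes on a single
CPU while keeping the planted effects well inside the power of the
discovery GWAS.

## Known limitations

* The simulator's LD is exchangeable within blocks; clumping behaviour on
  real, distance-decaying LD may differ in detail.
* Cross-chromosome epistasis is outside the architecture's hypothesis class
  (linear head over per-chromosome outputs).
* The lasso baseline penalizes covariates (see above).
* Checkpoints store dense masked weight matrices; genome-wide SNP sets would
  need a sparse representation and minibatched sequence packing.
* `heritability_like_scale` is an in-sample variance fraction on the
  liability scale, not a population heritability estimate.
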