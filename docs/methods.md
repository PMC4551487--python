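# Methods

This note documents the models behind `ricegs`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic data can and
cannot tell you about real populations.

## 1. The synthetic population

### Demographic model

The simulator reproduces the statistical structure of a 343-line rice
synthetic population derived from recurrent selection, in five stages:

1. **Founders.** `n_founders` (60) fully inbred accessions; the alternate
   allele frequency at each locus is an independent draw from a symmetric
   Beta(β, β) with β = 0.56, giving a U-shaped founder spectrum.  Loci are
   generated i.i.d. — founders carry no linkage disequilibrium.
2. **Recurrent-selection cycles.** `n_cycles` (120) generations of random
   mating in a finite pool of `cycle_pool_size` (14) plants.  Selection is
   not modelled (the breeding history applied very mild selection); the
   small pool is the engine that creates both drift and linkage
   disequilibrium.  Meiosis places Poisson(L_cM/100) crossovers uniformly on
   the genetic map, without interference.
3. **Enrichment.** Before the subpopulations separate, a fraction
   (`enrichment_fraction` = 0.22) of each subpopulation's parent pool is
   replaced by fresh donor accessions (`n_enrichment_founders` = 2).  Each
   donor genome copies one randomly chosen base haplotype and carries the
   alternative allele at loci the base has fixed, with per-locus activation
   probabilities drawn from the same beta law; a variant is private to one
   donor except with probability `enrichment_shared` (0.5).  This models the
   germplasm enrichments of real programs.
4. **Subpopulation drift.** Each of the four subpopulations drifts for
   `drift_generations` (1) additional generation in its own pool
   (32/28/48/53 plants) and is then expanded to its census of S0 lines
   (86/83/82/92).
5. **Single seed descent.** Every line is selfed `selfing_generations` (2)
   times, one offspring per generation, so expected heterozygosity falls by
   2^-2.  Finally the marker panel is ascertained at MAF ≥ `panel_maf_min`
   (0.01), mimicking a genotyping pipeline that drops near-monomorphic
   calls.

The map is 12 chromosomes × 150 cM (18 Morgans), physical length 31.1 Mb
per chromosome, with marker positions drawn uniformly (sorted) rather than
equally spaced: real panels have a skewed gap distribution (median adjacent
distance ~23 kb against a mean of ~45 kb), and the 0–25 kb LD bin would be
empty under equal ~45 kb spacing.  The genetic map is linear in the
physical map.

### Why enrichment is structural, not cosmetic

Under an i.i.d.-founder model every bit of LD must come from drift, but
drift also reshapes the allele-frequency spectrum: conditional on a locus
remaining polymorphic, the drifted spectrum flattens toward uniform (mean
MAF → 0.25) regardless of the founder beta shape.  Heavy drift therefore
buys short-range r² ≈ 0.5–0.9 at the cost of losing the rare-allele mass
that characterizes the real panel (mean MAF 15%, median ~10%).  The two
calibration targets are irreconcilable by drift alone; we verified this
across founder shapes 0.15–0.56, 25–120 cycles and pools of 14–28.  Donor
enrichment resolves the conflict the way the real history did: rare
variants enter late (so they survive), riding coherent donor haplotypes (so
they are in strong mutual LD).  Because each donor copies a base haplotype
as its backbone, the injection does not dilute the LD already accumulated
among older variants.

### Calibration

Defaults were calibrated once against the published population statistics
and then frozen.  Over eight replicate seeds the default configuration
gives: mean panel MAF 0.12–0.20 (replicate mean 0.151; published value
15.2%), mean r² 0.52–0.54 for marker pairs within 25 kb (published 0.59),
all pairwise Weir–Cockerham F_ST ≤ 0.04 (published 0.025–0.058), median
per-line heterozygosity 4.7–7.7% (published ~4.8%), and ~8.3k panel SNPs at
an average density of one per ~45 kb.  Realized F_ST varies substantially
between replicates because every locus shares a single pedigree; the
one-generation subpopulation drift default keeps the maximum safely under
0.06.

### Traits and the field trial

Traits are strictly additive: TBV_i = Σ_q a_q x_iq, centered.  The default
architectures mirror the four study traits — flowering time (h² 0.86,
100 QTL plus one major locus contributing 35% of genic variance), plant
height (0.58, 300 QTL), grain yield (0.29) and panicle weight (0.10) — with
N(0, 1) additive effects at panel loci.

Phenotypes follow the alpha-lattice model Y = μ + TBV + R_j + b_k(j) + e
with 2 replicates of 21 blocks × 17 plots, blocks randomized per replicate.
The residual variance is set by inverting the pipeline's own heritability
estimator: σ²_e = σ²_g (1 − h²)/h², capped at 10⁶ σ²_g as h² → 0.  An
entry-mean inversion (with the factor r = 2) was considered and rejected
because it would make the simulator target a different estimand than the
one the REML module reports; with the plot-basis inversion the recovery
loop (simulate at h², estimate ĥ²) is a fixed point.

## 2. Population characterization

* **Allele statistics.** p from mean dosage/2; Ho as the dosage-1 fraction;
  He = 2p(1−p)/4.  The divisor 4 deflates panmictic heterozygosity for two
  selfing generations, so He is the expected S2 heterozygosity (≤ 0.125).
* **LD.** r² is the squared Pearson correlation of unphased dosage vectors
  (composite LD).  Haplotype-level r² would require phase; with near-inbred
  lines the composite and haplotypic measures almost coincide.  Pairs are
  restricted to a chromosome whenever distance is reported; the decay
  profile reports binned means and the half-decay distance (first bin at or
  below half the 0-bin mean).
* **F_ST.** Weir–Cockerham θ from the (a, b, c) variance components,
  vectorized over loci; multilocus estimates are ratios of sums, reported
  pairwise and unclipped (negative estimates are informative; a truncation
  flag exists).
* **Ne.** The LD method: mean r² over inter-chromosomal pairs only
  (physical linkage never contributes), loci below a MAF floor (default
  0.05) removed, the finite-sample expectation E[r²] = 1/S + 3.19/S²
  (valid for S ≥ 30) subtracted, and the drift expectation inverted as
  N̂e = (1/3 + √(1/9 − 2.76 r²'))/(2 r²') for random mating.  r²' ≤ 0 is
  reported as infinite.  The parametric χ² confidence interval uses the raw
  pair count and therefore overstates independence; treat it as optimistic.
  The estimator assumes random-mating diploids: applied to twice-selfed
  lines it is biased, so recovery checks run on random-mating samples.
* **Kinship.** d_ij is the fraction of loci with differing dosage;
  s = 2(1 − d) maps identity to 2 and complete mismatch to 0.  The affine
  map was preferred over a min–max rescale, which would make the scale
  data-dependent.

## 3. Marker selection

Selection is MAF filter (≥ threshold, inclusive) followed by greedy
within-chromosome LD pruning in map order: a marker is kept iff its r² with
every already-kept marker on the chromosome is ≤ the ceiling, so the first
marker seen wins ties.  The order-based rule is deterministic and
idempotent; an alternative (drop the lower-MAF member of an offending pair)
is noted but not implemented as default.  Pruning is against retained
markers, not against all candidates — the statistically cleaner reading of
"pairwise r² with all other markers".  r² ≤ 1 retains everything, so the
no-pruning column of the factorial is the identity.  Designs are
column-centered (subtract 2p̂); variance standardization is optional and
off by default.  Random sets of given sizes are drawn uniformly without
replacement with per-(size, replicate) seeds derived from one master seed.

## 4. Phenotype analysis

EM-REML on Henderson's mixed-model equations for
y = Xβ + Z_g u_g + Z_b u_b + e with replicate fixed, genotype and
block-within-replicate random.  EM was chosen over average-information
because it is unconditionally stable and non-negative by construction, and
a ~700-plot lattice solves in well under a second per iteration; the cost
is slow convergence when a component approaches zero, which is why the
result carries a `converged` flag and the last iterate (the spec'd cap is
500 iterations at a 1e-8 relative tolerance).  The restricted likelihood is
available per iteration (`track_loglik=True`) and is non-decreasing, as EM
guarantees.  BLUPs come from the MME at the converged variances, with
per-line reliabilities 1 − PEV/σ²_g.

Heritability is reported as h² = σ²_g/(σ²_g + σ²_e) exactly as printed in
the source material.  Note the published variance components are not
internally consistent with the published h² values (e.g. 46.03/(46.03+4.16)
= 0.917 against a printed 0.86); the formula, not the printed h², is
implemented, and the printed h² ladder (0.86/0.58/0.29/0.10) is used only
as simulation targets.

## 5. Whole-genome regression

All methods consume an intercept plus a centered design X and a response y
(line BLUPs), and all expose `fit() -> GenomicResults` with `predict`.

* **RR-BLUP.** β̂ = (X'X + λI)⁻¹X'(y − μ̂) with λ = σ̂²_e/σ̂²_u from REML:
  one eigendecomposition of XX' (n × n), then Brent optimization of the
  restricted profile likelihood in log λ.  Constant responses yield a
  flagged degenerate model with β̂ = 0.
* **G-BLUP.** VanRaden method 1, G = ZZ'/(2Σp(1−p)), diagonal loading 1e-8
  for PSD tolerance (kept tiny so the RR-BLUP equivalence holds to 1e-6;
  non-PSD inputs raise with a loading hint).  Same spectral REML machinery;
  new individuals are predicted through their G rows against the training
  block, and the cross-validation engine builds one full-panel G per marker
  set so training and prediction stay on a common scale.
* **LASSO.** Cyclic coordinate descent on (1/2n)‖y − Xβ‖² + λ‖β‖₁ with
  Gram-free residual updates (numba kernel); the per-sweep objective is
  recorded and is non-increasing.  λ is selected by inner K-fold CV on the
  training fold only: 5 folds, 50 log-spaced penalties spanning 4 decades
  below λ_max = max|X'(y − ȳ)|/n, warm-started along the path, inner folds
  seeded from the outer seed.  The in-package solver exists because the
  objective-monotonicity property is part of the contract; scikit-learn's
  solver serves as an independent oracle in the tests.
* **BRR.** Single-site Gibbs: Gaussian marker prior with common variance
  σ²_β, scaled-inverse-χ² hyper-priors on σ²_β and σ²_e with df 5 and
  scales set so the prior modes match a target marker R² of 0.5
  (S_e ∝ var(y)(1−R²), S_β ∝ var(y)R²/Σvar(x_j)).  Defaults 12,000
  iterations, 2,000 burn-in, thinning 5; posterior means and SDs of β are
  stored.  The exact chain lengths and hyper-values of the original
  analyses are unreported; these defaults are documented, not claimed to
  match.
* **BL.** Park–Casella double-exponential prior as a normal scale mixture:
  β_j | τ²_j ~ N(0, σ²_e τ²_j), 1/τ²_j inverse-Gaussian updates, λ² with a
  Gamma(1.1, rate) hyper-prior whose mode sits at λ²₀ = 2Σvar(x_j)(1−R²)/R².
  Marker-specific shrinkage gives the expected signature relative to BRR:
  harder shrinkage of null effects, less of large ones.

Fold partitions are shared across the frequentist methods of a scenario;
independent partitions for the Bayesian methods (as in the original
analysis) are available behind a flag but off by default so method
comparisons share their folds.

## 6. The cross-validation factorial

Scenarios are the Cartesian product (trait × method × MAF × LD × k ×
strategy) in that canonical order.  For k-fold strategies the engine draws
R = ⌈100/k⌉ replicate partitions (34/17/12 for k = 3/6/9, so k·R ≥ 100
tests per scenario); VP sizes are ⌊N/k⌋ with the remainder spread one per
fold (114/115 at N = 343, k = 3).  The stratified strategy partitions each
subpopulation separately so every fold holds ≈ 1/k of each; the
leave-subpopulation-out strategy is a single TP/VP split per target.
Marker selection is computed once on the full panel per marker-set
specification, matching the original study design (per-fold re-selection is
the statistically cleaner alternative and can be added at the call site by
passing fold-restricted populations).  Every (scenario, replicate, fold)
seed derives from the master seed by stable hashing, so any single cell is
reproducible in isolation.

Accuracy is r = corr(GEBV, observed BLUP) in the left-out fold; on
simulated data the correlation with the true breeding values is recorded
alongside as a diagnostic.  r is Fisher-transformed (z = ½ ln((1+r)/(1−r)),
|r| ≥ 1 clipped at 1 − 1e-12 with a warning) and analysed with three
fixed-effects OLS models under sum-to-zero coding and Type III tests:
model 1 treats the scenario as a single factor, model 2 has the five main
effects (13 DF on the main grid), model 3 adds all ten first-order
interactions (79 DF).  Following the source's reporting convention, main
effects are judged against the model-2 MSE and interactions against the
model-3 MSE.  LSMeans average model predictions over a balanced grid of
the other factors, are compared by unadjusted pairwise t tests on the model
MSE (the classical LSMeans default; the original software's behavior is
presumed, not stated), back-transformed to r for reporting, and grouped by
a compact letter display (maximal runs of mutually non-significant levels
in decreasing-mean order share a letter).

The reported total of "up to 55,296 correlations" in the source does not
follow from 540 × (100–108) under any arithmetic we could reconstruct; the
engine reports actual counts and does not target that number.

## 7. What the synthetic data does and does not show

The generator reproduces the *statistical* structure the evaluation
depends on — the U-shaped frequency spectrum, strong slowly-decaying LD,
weak four-way structure, residual heterozygosity, additive traits across a
heritability ladder, and a lattice trial with realistic error — so tests on
it validate the machinery: estimator correctness, the factorial's
arithmetic, and directional findings (leave-subpopulation-out accuracy
below random assignment; accuracy non-decreasing in heritability at fixed
architecture).  It does not reproduce the real population's absolute
accuracy values: real genotyping error and imputation, non-additive genetic
variance, genotype-by-environment interaction, selection during the
recurrent cycles and the true QTL landscape are all absent.  Absolute AA
values on synthetic data are therefore expected to differ from published
real-data values (typically upward), and no test asserts them.

## 8. Problem sizes used by the default test run

The test and acceptance runs use the full 343-line × ~8.3k-SNP population
for calibration statistics (five replicate simulations), mid-sized
populations (~160–343 lines, 0.4–1.8k SNPs) for the engine and estimator
recovery suites, and reduced MCMC settings (1.2–6k iterations) for the
Gibbs samplers — sizes chosen so the whole suite exercises every code path
at meaningful signal-to-noise in a few minutes.  The full 540-scenario
factorial at default MCMC settings is a production run, not a test, and is
driven from the CLI.
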