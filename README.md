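# ricegs

Genomic-selection evaluation for recurrent-selection rice synthetic
populations.

## The problem

Upland rice breeding programs built on recurrent selection maintain broad
synthetic populations: a few dozen founder accessions are inter-crossed,
recombined over many cycles with very mild selection, occasionally enriched
with new germplasm, and sampled as selfed (S2) lines for evaluation.  Before
committing a program to genomic selection, a breeder wants to know how the
accuracy of genomic estimated breeding values (GEBV) in such a population
depends on the choices under their control: the marker panel (minor-allele-
frequency and linkage-disequilibrium thresholds, or simply panel size), the
prediction model, the relative sizes of training and validation sets, the
trait, and the relatedness between the lines used to train and the lines to
be predicted.

`ricegs` implements that whole evaluation loop as a tested Python library
with a thin CLI:

* **`ricegs.popsim`** — forward-in-time simulator of the synthetic
  population (beta-law founder frequencies, Poisson recombination on an 18
  Morgan map, finite-pool random-mating cycles, donor-accession enrichment,
  subpopulation drift, single-seed-descent selfing) and of its 2-replicate
  alpha-lattice field trial for four additive traits with target
  heritabilities 0.86 / 0.58 / 0.29 / 0.10.
* **`ricegs.popgen`** — allele statistics (MAF, Ho, He = 2p(1−p)/4),
  within-chromosome LD r² and its distance-binned decay, pairwise
  Weir–Cockerham F_ST, effective population size from LD among unlinked loci
  (Waples–Do with the S ≥ 30 sample-size correction), and the mismatch
  kinship s = 2(1 − d) ∈ [0, 2].
* **`ricegs.markers`** — incidence matrices: MAF filtering, greedy
  per-chromosome LD pruning, random marker sets, column-centered designs.
* **`ricegs.phenotypes`** — the alpha-lattice mixed model
  Y_ijk = μ + g_i + R_j + b_k(j) + e_ijk by EM-REML on Henderson's
  mixed-model equations; genotype BLUPs and h² = σ²_g/(σ²_g + σ²_e).
* **`ricegs.predictors`** — five whole-genome regressions under one
  Model/Results interface: RR-BLUP (spectral REML for λ), G-BLUP (VanRaden
  G; exactly equivalent to RR-BLUP under matched scaling), LASSO
  (coordinate descent, inner-CV penalty), Bayesian ridge regression and the
  Bayesian LASSO (Gibbs samplers).
* **`ricegs.cvfactorial`** — the replicated cross-validation factorial:
  scenario grids (e.g. 4 traits × 5 methods × 3 MAF × 3 LD × 3 k = 540
  scenarios), fold strategies (random, stratified by subpopulation,
  leave-subpopulation-out), accuracy r and Fisher z = ½ ln((1+r)/(1−r)),
  three fixed-effects ANOVA models and LSMeans with compact letter display.

## Worked example

```python
import numpy as np
from ricegs.popsim import (SimulationConfig, simulate_population, TrialDesign,
                           default_trait_architectures, simulate_field_trial)
from ricegs.popgen import allele_stats, pairwise_ld, fst_pairwise
from ricegs.phenotypes import fit_lattice_model
from ricegs.cvfactorial import enumerate_scenarios, run_cross_validation

pop = simulate_population(SimulationConfig(), seed=1)
st = allele_stats(pop.dosage)
ld = pairwise_ld(pop.dosage, pop.gmap, max_distance_kb=25)
fst = fst_pairwise(pop.dosage, pop.subpop_labels)
print(f"mean MAF = {st.maf.mean():.3f}   mean r2 (0-25 kb) = {ld.r2.mean():.3f}"
      f"   max pairwise FST = {fst.matrix.max():.3f}")

rng = np.random.default_rng(2)
archs = default_trait_architectures(pop, rng)
trial = simulate_field_trial(pop, archs, TrialDesign(sigma2_block=2.0), seed=3)
res = fit_lattice_model(trial, trait="PH")
print(res.summary())

scenarios = enumerate_scenarios(["PH"], ["RRBLUP"], mafs=(0.05,), lds=(0.9,), ks=(3,))
records = run_cross_validation(scenarios, pop, {"PH": res.blups}, seed=4,
                               r_override=5)
print(f"AA = {records['r'].mean():.3f} (sd {records['r'].std():.3f})")
```

prints

```
mean MAF = 0.136   mean r2 (0-25 kb) = 0.525   max pairwise FST = 0.008
Alpha-lattice REML — trait PH
  plots: 686   lines: 343   blocks: 42
  sigma2_g = 111.6976
  sigma2_b = 8.2181
  sigma2_e = 108.5906
  h2 (s2g/(s2g+s2e)) = 0.507
  mu = 3.4165   converged: True (98 EM iterations)
AA = 0.671 (sd 0.044)
```

The first line is the population calibration: a U-shaped allele-frequency
spectrum (mean MAF ≈ 0.14), strong short-range LD (mean r² ≈ 0.53 within
25 kb) and weak subpopulation differentiation.  The lattice REML recovers
the plant-height trait near its simulated heritability (ĥ² = 0.51 vs. the
0.58 target), and the final line is the average accuracy (AA): the mean
Pearson correlation between cross-validated GEBVs and the observed line
BLUPs over 15 validation folds for one scenario of the factorial.

The same pipeline is scriptable from the shell:

```bash
ricegs simulate --seed 1 --out pop/
ricegs stats    --pop-dir pop/ --out stats/
ricegs blup     --trial pop/trial.csv --out blups/
ricegs cv       --pop-dir pop/ --blups blups/blups.csv \
                --methods RRBLUP,GBLUP --mafs 0.025,0.05,0.10 \
                --lds 0.75,0.9,1.0 --ks 3,6,9 --seed 1 --out records.csv
ricegs anova    --records records.csv --model 3 --lsmeans method,trait --out anova/
```

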