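# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of
`datcascade`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Differential expression model

Counts for gene g in sample j are modelled as negative binomial with
mean `mu_gj = s_j * q_gj` and variance `mu + alpha_g * mu^2`.

* **Size factors** are plain median-of-ratios: for genes with no zero
  count, `s_j = median_g(K_gj / geomean_g(K))`. No rescaling is applied
  afterwards; identical columns get unit factors automatically, and
  multiplying one column by `c` multiplies its factor *relative to every
  other column* by exactly `c` (the absolute factors each absorb a
  `c^(±1/n)` because the per-gene geometric means move too).
* **Dispersion** is a per-gene method-of-moments estimate on normalized
  counts: within-condition variances pooled with df weights, then
  `alpha = max(0, (s^2 - mean) / mean^2)`. There is no empirical-Bayes
  shrinkage, no outlier (Cook's) filtering and no independent filtering;
  the cascade only needs (baseMean, log2FC, padj) semantics, and the
  divergence from a shrinkage-based estimator is deliberate and
  documented here. Inside the GLM the dispersion is floored at 1e-8 so
  IRLS weights stay finite.
* **Testing.** The GLM (intercept + condition indicator, optional batch
  dummies, log size factor offset) is fit by IRLS with fixed dispersion:
  convergence at 1e-8 on the coefficient max-change, 100 iterations
  maximum, linear predictor clipped to ±30 to avoid overflow.
  `log2FC = beta_cond / ln 2`; the Wald statistic `beta/se(beta)` is
  referred to the standard normal, two-sided; BH adjustment across
  genes. All-zero genes report log2FC 0 and p 1; non-converged fits are
  flagged and report p 1 rather than aborting a run.
* **Small-sample behaviour.** With the plug-in dispersion and a normal
  reference, the test is anti-conservative at very small replicate
  numbers: on null simulations the nominal-0.05 rejection rate is about
  0.11 at 3 replicates per condition and reaches the nominal band
  (0.059 measured) at 10 replicates. The calibration tests therefore run
  at 10 replicates per condition; analyses at n = 3 should lean on the
  adjusted p-values (the null padj < 0.05 rate at 3 replicates is ~0.03)
  and treat raw p-values near 0.05 with caution.

## Filter cascade

Quartile indices use the 25th/50th/75th empirical percentiles with
linear interpolation; a value equal to a boundary falls in the lower
quartile (deterministic tie rule). The reference distribution for the
rank is the concordant-survivor set, not all genes, because ranking
happens at that stage of the funnel. "Fold change" in the rank is
|log2FC|: both up- and downregulated transcripts survive to selection,
so a signed quartile would confound direction with magnitude. Each pair
is ranked against its own survivor distribution and the final rank is
the minimum over pairs — selection demands strength in both pairs,
consistent with the both-pairs logic of the first two filters. A
`combine="mean"` alternative (average the statistics across pairs, rank
once) is available.

## Survival screen

The median split sends values equal to the median to the low group
(deterministic; the convention of external survival portals is
unknowable). The Kaplan–Meier estimator is the standard product limit;
the log-rank test uses the hypergeometric variance; the Cox fit is a
single-binary-covariate partial likelihood solved by Newton–Raphson
(50 iterations, 1e-10 score tolerance) with the Breslow approximation
for ties — cohorts with continuous times essentially never tie, and a
monotone likelihood (|beta| > 15) is reported as non-estimable rather
than a number. OS and PFS are combined by OR at alpha = 0.05 with no
multiplicity correction, exactly as a permissive candidate screen; with
two independent null endpoints this selects ~9.75% of null genes, and
the tests verify that rate.

## qPCR and screen quantification

Per condition, replicate Ct values are averaged before
`dCt = Ct_target - Ct_reference` (a per-replicate mode exists;
identical in expectation). `ddCt = dCt_test - dCt_control`, relative
expression `2^-ddCt`, `log2FC = -ddCt` — an algebraic identity the
tests assert exactly. Validation = sign concordance with the RNA-seq
estimate plus a configurable magnitude floor (default 0.5 in log2
units; the bundled 45-transcript panel validates in full for any floor
up to 0.9, its smallest printed magnitude). Clonogenicity is the ratio
of replicate means (not the mean of ratios), times 100; a hit loses
strictly more than the cutoff (default 50%).

## Knockdown effector analysis

Both contrasts (target-siRNA vs control-siRNA; control-siRNA vs
untreated) are called at padj < 0.01 with no fold-change gate — the
fold-change cutoff belongs to the later shortlist step (|log2FC| > 1.2
strict, padj ≤ 0.01 inclusive). Batch enters the GLM design as a
covariate; no separate batch-correction preprocessing is applied.
Off-target exclusion is a plain set difference by gene id.

## Synthetic-data generator

The generator is a pure function of its seed (independent substreams
per output, so adding one stage never perturbs another's draws).

* **Counts**: NB via gamma–Poisson with `var = mu + alpha mu^2`;
  per-sample depth factors log-uniform in [0.5, 2] (exercises
  normalization without extreme imbalance); default 3 replicates per
  condition (the replicate number of the emulated design is not
  published; 3 is the field's norm), default dispersion 0.05.
* **Planted library**: concordant genes cycle through all 16
  combinations of four base-mean strata (30/120/500/2000) and four
  |log2FC| strata (1.3/1.9/2.7/3.6) with mild jitter. The base-mean
  strata target the *cross-condition* base mean — the quantity the rank
  filter consumes — so the sensitive-condition baseline is back-computed
  as `2*level/(1 + 2^lfc)`; without this, large fold changes
  systematically inflate a gene's base-mean quartile and planted-stratum
  recovery could not hold even noise-free. One concordant-up gene in the
  (Q4, Q4) cell is the designated driver (`G000001`): hazard ratio 1.78,
  colony reduction 0.54 — the profile the end-to-end pipeline should
  single out. Other planted up-genes get sub-threshold colony
  reductions (uniform 0.05–0.40).
* **Survival**: expression standard normal per gene; event times
  exponential with the hazard multiplied by `HR^(above median)` for
  each non-unit-HR gene (log-additive across such genes; with a single
  planted gene the two-group Cox model is exactly correctly specified,
  which is what makes HR recovery a valid acceptance property). The
  configured fraction of patients is censored uniformly before their
  event time; PFS uses twice the OS baseline rate (1/12 vs 1/24 per
  month).
* **qPCR**: reference gene at 20 cycles, target at 25 − log2FC in the
  test condition, additive Gaussian per-well noise (default sd 0.2
  cycles — a standard qPCR error model), so expected 2^−ΔΔCt equals the
  planted fold change exactly.
* **Screen**: Poisson colony counts around a 200-colony baseline
  (`exact=True` replaces draws with rounded means for worked examples).
* **Knockdown**: three arms, two batches alternating across replicates
  with a shared multiplicative mean factor (default 1.0/1.15);
  off-target genes shift in both siRNA arms, specific effectors only in
  the target arm.

What the generator does *not* emulate: read-level noise, GC/length
biases, correlated gene modules, dropout structure, informative
censoring, or qPCR primer-efficiency variation. Passing recovery tests
therefore demonstrate the pipeline's correctness under its own model
assumptions, not robustness to real-data pathologies.

## Problem sizes used by the acceptance script

Null DE calibration runs 2000 genes at 10 replicates per condition;
log-rank calibration 1000 genes at 200 patients; hazard-ratio recovery
averages three independent 1656-patient cohorts (shrinking Monte-Carlo
error to ~3%); the knockdown re-enactment plants 160 off-target and
1400 specific effectors among 4000 genes at dispersion 0.02 and 4
replicates; the end-to-end run uses the default 2000-gene library.
These sizes keep each quantity's Monte-Carlo error comfortably inside
its comparison tolerance.

## Known limitations

* No dispersion shrinkage: underpowered and anti-conservative at tiny
  replicate numbers relative to empirical-Bayes DE tools (see above).
* The survival screen's OR-combination without multiplicity correction
  is intentionally permissive; it is a funnel stage, not an inference.
* The rank's min-combination and the quartile tie rule are documented
  conventions; published analyses of this design rarely state theirs,
  so cross-study rank agreement is approximate.
* The 2^−ΔΔCt model assumes perfect (100%) amplification efficiency for
  target and reference; no Pfaffl correction.
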