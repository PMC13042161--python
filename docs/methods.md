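# Methods

`tauspread` models the propagation of misfolded tau protein over weighted
brain networks and asks which network, which regional biological factor, and
which mechanistic rate best explain an observed regional tau pattern.  This
note documents the model, the estimators, the synthetic study conditions, and
the numerical choices, in that order.

## The spreading model

The engine is an extended agent-density SIR (susceptible-infectious-removed)
model.  Each region *i* of a symmetric, non-negative weighted connectome
carries two pools: normal tau `n_i(t)` and misfolded tau `m_i(t)`; each edge
*(i, j)* carries in-transit pools.  One step of duration `dt` applies, in
order:

1. **Spread.** A fraction `1 − stay_probability` of each pool exits its
   region (scaled by the regional probability `P_i` when the spread rate is
   modulated), split across incident edges proportionally to edge weight.
   Protein inside edge *(i, j)* arrives at *j* with probability
   `min(1, velocity · dt / length(i, j))`; edge lengths are Euclidean
   centroid distances when coordinates exist and 1 otherwise (similarity
   networks carry no geometry).
2. **Synthesis.** Normal protein is produced at `synthesis_rate0 · dt`
   (times `P_i` under synthesis modulation).
3. **Clearance.** The pools existing before this step's synthesis are
   multiplied by `1 − clearance_rate0 · dt` (times `P_i` under clearance
   modulation).  The same rate clears normal and misfolded protein, and
   newly synthesized protein is first exposed to clearance on the following
   step; the no-transport fixed point is therefore
   `synthesis_rate0 / clearance_rate0`.
4. **Misfolding.** A fraction `1 − exp(−m_i · transfer_rate · dt · [P_i])` of
   the normal pool converts on contact with the local misfolded density —
   bounded, linear in `m_i` for small densities.

Before seeding, normal protein is equilibrated to its steady state (max
relative per-region change below 1e-10); a misfolded seed (1 density unit by
default, split equally across bilateral epicenter regions) is then injected.
Per-step probabilities are clipped to [0, 1] with a warning, since clipping
signals an out-of-range hyperparameter.  With synthesis and clearance
disabled the step is exactly mass-conserving.

The deterministic density engine is the primary implementation; a stochastic
agent simulator applying the same rules per agent (each agent one quantum of
`1/agents_per_density`) exists purely as an independent validation oracle.
The two agree within Monte-Carlo error at 10,000 agents; the residual
O(1/K) mean-field bias is below one single-run standard error on the toy
problems tested.

**Global hyperparameters** (units per step unless noted): `stay_probability`
in [0, 1] (tau retention; default 0.5), `transfer_rate` ≥ 0 (misfolding
scale; default 1), `velocity` > 0 (length units per step; default 1), `dt`
(default 1), `n_steps` (default 30,000), `synthesis_rate0` and
`clearance_rate0` (defaults 0.1; per-step clearance must stay below 1).

**Regional modulation.** A regional factor map is z-scored and passed
through the standard-normal CDF, giving per-region probabilities in (0, 1)
that scale exactly one of the four rates; higher factor values mean higher
rates.  A constant factor maps to 0.5 everywhere.

## Tau quantification

**Load** is a per-region MinMax normalization against the reference
(tau-negative) group: reference min/max map to 0/1, pathological values may
exceed 1, sub-reference values clip to 0.  Min/max (rather than percentile)
endpoints implement the 0–1-range convention; the normalization is
equivariant under joint affine transforms of a region's values.

**Presence (TPP)** fits, per region, a two-component 1-D Gaussian mixture
across the whole cohort and reports the posterior probability of the
higher-mean component.  The EM is deterministic: components are initialized
by hard-assigning points to the nearer of the 25th/75th-percentile seeds and
moment-matching that partition (initializing both components at the sample
variance can walk EM into a spurious maximum with a narrow component glued
to the mode), variances are floored at 1e-6 of the sample variance, up to
500 iterations at 1e-8 log-likelihood tolerance, components relabelled by
ascending mean.  Regions whose component means differ by less than 0.5
pooled SD are flagged near-unimodal but still scored.  A per-region
covariate-regression hook exists for off-target-binding adjustments but is
disabled by default, as no specific correction is assumed.

Braak summaries report per-stage mean and SEM (sample SD / √n; 0 for
single-region stages by convention) plus a Spearman stage-trend diagnostic.

## Fitting and model comparison

Model fit is the maximum Pearson correlation between the simulated regional
pattern (misfolded density by default; misfolded fraction available) and the
empirical map across all timesteps, with zero-variance steps skipped rather
than zero-filled (early all-zero patterns would otherwise distort the
argmax) and ties resolved to the earliest step.  Secondary statistics:
`MSE*`, the mean squared error after linearly rescaling the simulation to
the observed min/max range (simulated scales are not intrinsically bounded);
and `EV = 1 − Var(y − ŷ)/Var(y)` with population variances.

The epicenter sweep fits one model per candidate region (bilateral pairs via
the `_L`/`_R` label convention when requested), ranking by best correlation.
Hyperparameter search is an exhaustive grid over (stay probability, transfer
rate, velocity) with deterministic grid-order tie-breaks.  The model space
crosses connectomes with factors and the four rates (`n_c + n_c·n_f·4`
models); per (connectome, factor) pair the best-performing rate is retained,
with ties broken in the fixed order synthesis, clearance, spread, misfold.
Fold-change improvement over the connectome-only baseline is
`(r_with − r_only)/r_only`, undefined for non-positive baselines.

**Surrogate nulls.** Surrogate connectomes preserve the binary degree
sequence exactly (double-edge swaps, 10 per edge) and reassign the original
weight multiset to the rewired edges by rank matching against
endpoint-strength sums.  Rank matching alone left nodal strengths far from
the originals on heavy-tailed weights, so an iterative proportional
adjustment (50 rounds of geometric-mean endpoint scaling) follows, and total
edge weight is restored exactly; in practice nodal strengths land within 10%
for essentially all nodes.  The significance gate is one-sided: a model is
significant when its observed correlation exceeds the 97.5th percentile of
the surrogate fit distribution.  Null fits reuse the observed-data
hyperparameter grid by default; per-surrogate re-tuning is available.
Spatial-autocorrelation-preserving nulls are out of scope.

## Comparators and receptor ratios

The diffusion comparator is a conservative lazy random walk,
`x(t+1) = (1−τ)x + τ W_rn^T x`, whose long-time pattern is proportional to
nodal strength; it accepts a plug-in spreading function so other
epicenter-seeded models can be substituted.  The connectivity-distance
statistic correlates a regional spreading sequence with shortest-path
distance over inverse weights (direct 1/w optional); unreachable regions are
excluded with a logged count.  Connectome similarity reports SSIM (window 7,
matrices jointly min-max scaled), cosine and Pearson on upper-triangle
entries.  The receptor module implements nine ratio maps (overall,
metabotropic, ionotropic and Glu/GABA excitatory-inhibitory ratios, the ACh
receptor-to-reuptake ratio, the transmitter/neuromodulator ratio, and the
5-HT1A/5-HT1B and DAT/NET ratios) exactly as printed formulas over 16 named
markers; all are invariant under global panel rescaling.  The panel carries
19 markers: the serotonin transporter completes the four transporters, and
CB1/MOR complete the fifteen receptors (the cannabinoid and opioid systems
the similarity network draws on).  Whether tau associations use the 66- or
62-region set is a configuration choice of the caller.

## Synthetic study conditions

The generator produces everything the pipeline consumes, with stored ground
truth (epicenter, factor, rate, per-participant pseudotimes and added
signal) in a sidecar that analysis code never reads.

* **Connectomes.** Geometric (regions uniform in the unit cube, weight
  `exp(−d/0.3)` times a symmetric log-normal jitter with σ = 1, thresholded
  to 30% density with the minimum spanning tree kept, centroids attached),
  modular, FC-like (latent-factor correlations, arctanh, top-40% positive
  edges), and dense.  The log-normal jitter emulates the heavy-tailed weight
  distribution of anatomical connectomes; without it regional connection
  profiles are too homogeneous for seed regions to be distinguishable, which
  no spreading model could overcome.
* **Cohorts.** 600 tau-positive and 200 reference participants by default —
  the scale of a large tau-PET cohort; smaller cohorts cannot identify
  low-prevalence mixture components in late-reached regions.  Reference
  values are region-specific Gaussians (means drawn once in 1.0–1.4 SUVR-like
  units, SD = `noise_sd`, default 0.1 — 10% of the signal gain).  Positive
  participants receive a latent pseudotime drawn uniformly from the end of
  burn-in (5% of peak misfolded mass) to 1.3× the last region's half-plateau
  rise: the cohort then spans clearly graded disease stages (the group map
  identifies the epicenter) while every region is reached by a
  non-negligible subpopulation (per-region mixtures are identifiable).
  Their values are baseline + gain × max-normalized misfolded density at the
  pseudotime + noise.
* **Spreading regime for cohorts.** stay 0.9, transfer rate 1.0, velocity
  0.05, 2,000 steps at dt 1, synthesis = clearance = 0.1: high retention and
  slow traversal let the epidemic unfold over hundreds of steps.
* **Latent positivity.** A participant-region is latently positive when its
  misfolded density at the pseudotime exceeds 10% of the region's trajectory
  plateau (50% in the classification benchmark, which sits in the low-density
  valley of the sigmoid rise).  The Bayes-oracle classifier uses the true
  per-region mixture (Gaussian negatives; an equal-weight Gaussian mixture
  over the reached participants' true shifts) and is the ceiling against
  which TPP thresholding is compared.

What the generator does **not** emulate: off-target tracer binding,
partial-volume and perfusion artifacts, covariance between regional noise
terms, atrophy-coupled signal loss, longitudinal within-person correlation,
and real atlas geometry.  Passing recovery tests therefore shows the
estimators are correct and well-posed under the model's own assumptions at
realistic sizes and noise — not that real tau-PET data satisfy those
assumptions.

Desk-scale problem sizes used in the validation experiments: 40-region
networks for recovery (10 cohorts for epicenter recovery; 10 seeds × 5
decoy factors × 4 rates for factor/rate recovery at 2,000 steps); 30
regions, 1,000 steps and 100 surrogates per seed for the null gate; a
5-region toy at 10,000 agents for the stochastic-oracle check; 10,000 steps
for mass conservation.

## Known limitations

* The four-process step is not a molecular kinetic model; normal and
  misfolded tau share one clearance rate, and regional factors are static.
* The TPP mixture can remain poorly identified in regions where very few
  participants carry signal; such regions are flagged, not repaired.
* Surrogate strengths are preserved approximately (to ~10%), not exactly;
  exact-strength rewiring would require accepting changes to the weight
  multiset.
* Reported hyperparameter tuples from fitted models are only meaningful
  within the grids searched; the engine warns and clips rather than
  interpreting out-of-range values (e.g. negative transfer rates).
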