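# tauspread

Connectome-based modelling of tau propagation in neurodegenerative disease.

In Alzheimer's disease, misfolded tau protein accumulates along a
stereotyped anatomical sequence. Two questions drive the analyses this
package supports: is that sequence governed by spread along brain networks,
by intrinsic regional vulnerability, or both — and which network and which
regional biological factors best explain an observed pattern?  `tauspread`
is a library for researchers who want to pose those questions against
regional tau-PET-like tables: it provides the spreading simulator, the tau
quantification pipeline, the combinatorial model search with network null
models, and a synthetic-data generator with known ground truth so every
stage is testable end to end.

## The model

An extended SIR (susceptible-infectious-removed) density model evolves
normal tau *n*ᵢ and misfolded tau *m*ᵢ on a weighted connectome. Per step of
length Δt, in order:

* **spread** — a fraction (1 − *stay probability*) of each pool exits region
  *i*, split over edges ∝ weight; protein in edge (*i*, *j*) arrives with
  probability min(1, *velocity*·Δt / lengthᵢⱼ);
* **synthesis** — normal tau is produced at α·Δt;
* **clearance** — existing pools are scaled by (1 − β·Δt), the same rate for
  both pools;
* **misfolding** — a fraction 1 − exp(−*m*ᵢ·γ·Δt) of normal tau converts by
  contact with local misfolded tau.

A regional factor map (gene expression, receptor density, blood flow, ...)
can modulate exactly one of the four rates through per-region probabilities
Φ(z-score).  Model fit is the peak Pearson correlation between the simulated
pattern and the empirical map across the simulation, with MSE* (error after
rescaling the simulation to the observed range) and explained variance
EV = 1 − Var(y − ŷ)/Var(y) as companions. Empirical maps come in two
flavours: **tau load** (reference-group MinMax-normalized values) and **tau
presence** (TPP — the posterior of the higher component of a per-region
two-Gaussian mixture). Candidate models are gated against fits on surrogate
connectomes that preserve degree and strength distributions.

## Worked example

```python
import tauspread as ts

spec = ts.SyntheticSpec(n_regions=40, seed=101, epicenter_index=7)
conn = ts.generate_connectome(spec)
table, truth = ts.generate_cohort(spec, conn)
empirical = ts.group_average_map(ts.minmax_normalize_load(table),
                                 table.group_mask("positive"))

result = ts.fit_model(conn, empirical, epicenter=7,
                      base_params=ts.DEFAULT_COHORT_SIR)
print(f"R={result.r_best:.3f} at step {result.step_best}, "
      f"MSE*={result.mse_star:.4f}, EV={result.ev:.3f}")

ranked = ts.epicenter_search(conn, ts.DEFAULT_COHORT_SIR, None, empirical)
print("best epicenter:", ranked[0][0][0])
```

prints

```
R=0.903 at step 17, MSE*=0.0646, EV=0.499
best epicenter: r007
```

The fit from the generating epicenter correlates at R = 0.903 with the
group-average load map (noise keeps it below 1), and the exhaustive sweep
over all 40 candidate seed regions ranks the true epicenter `r007` first.
The `examples/` directory holds one short script per capability —
simulation, tau quantification and Braak summaries, fitting and epicenter
search, the model-space search with surrogate nulls, and the
receptor-ratio analyses — each printing the numbers it computes and what
they mean.

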