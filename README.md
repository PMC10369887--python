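# celldensity

Continuous cell-state density estimation for single-cell genomics.

Differentiation landscapes are not uniformly populated: stable cell states
(stem compartments, committed cell types) are densely sampled while the
transitory states between them — exactly where fate decisions happen — are
rare. `celldensity` infers a *continuous density function* over a
high-dimensional cell-state space (e.g. diffusion components) so that
high- and low-density regions can be quantified at single-cell resolution,
tracked over real time in time-series experiments, and linked to the genes
and chromatin elements that drive low-density transitions.

## The model

For every cell the distance to its nearest neighbor, dₙ(xᵢ), is linked to
the local density ρ through the nearest-neighbor distribution of a Poisson
point process:

    f_NN(r | ρ) = exp(−ρ·b(r, d)) · ρ · db(r, d)/dr

with b(r, d) the volume of the d-ball of radius r. The log-density is given
a sparse Gaussian-process prior and inferred by MAP:

    f ~ GP(m, Matern52(ℓ)),  ρ(x) = exp f(x),  dₙ(xᵢ) ~ NN(ρ(xᵢ), d)

* ℓ = exp(3 + mean log dₙ) — a data-driven length-scale heuristic,
* m = P₁%[log ρ̂] − 10 — a mean implying vanishingly small density far
  from data, with ρ̂ the closed-form prior-free estimate
  (d−1)·Γ(d/2+1)/(d·dₙᵈ·π^{d/2}),
* landmarks (k-means centroids, default 5000) act as inducing points; the
  model is a full GP at or below that size,
* optimisation is L-BFGS-B on whitened coefficients with analytic
  gradients.

Extensions built on the same machinery: a product state×time Matérn kernel
for time-continuous density (with its temporal length scale fitted to the
observed between-timepoint density correlations), density-weighted gene
change scores, trajectory-marginal cell-type proportions over time, and
primed vs lineage-specific chromatin accessibility scores.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from celldensity import CellStateDensity
from celldensity.simulate import simulate_tree_gmm

states, truth = simulate_tree_gmm(seed=1)   # 5012 cells, 10 dims, 28 components
result = CellStateDensity(states).fit()
print(result.summary())
r = spearmanr(result.log_density, truth.log_density(states.coordinates)).statistic
print(f"Spearman vs exact truth: {r:.3f}")
```

prints

```
Cell-State Density MAP Results
========================================
No. cells           5012
State dims (d')     10
Density dim (d)     10
GP mode             sparse
No. landmarks       5000
Length scale        3.16913
Kernel variance     1
Mean constant (m)   -21.7071
Converged           True
Iterations          139
Neg. log posterior  -49091.5
Log-density min     -23.4467
Log-density max     24.2713
Spearman vs exact truth: 0.931
```

The fitted log-density ranks the simulated differentiation tree's states in
close agreement with the exact mixture ground truth; `result.predict(X)`
evaluates the same continuous function at any other state, and
`result.save("model.h5")` round-trips it bit-exactly.

The same workflow is available from the shell:

```bash
celldensity simulate tree --seed 1 --out sim/
celldensity fit --states sim/states.tsv --landmarks 5000 --out model.h5
celldensity predict --model model.h5 --query sim/states.tsv --out logdens.tsv
```

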