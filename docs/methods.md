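# Methods

## Model

`celldensity` treats the observed cells as a realisation of an
inhomogeneous Poisson point process on the cell-state space and infers the
(log) intensity function. Two assumptions carry the construction: Euclidean
distance in the chosen representation measures biological dissimilarity,
and density varies smoothly between similar states. Under local homogeneity
the distance from a cell to its nearest neighbor then follows

    f_NN(r | ρ) = exp(−ρ·b(r, d)) · ρ · db(r, d)/dr,
    b(r, d) = π^{d/2} r^d / Γ(d/2 + 1),

whose single-observation maximiser (with the Jeffreys-type correction that
yields a proper estimate) is the closed-form heuristic

    ρ̂(dₙ | d) = (d − 1) Γ(d/2 + 1) / (d dₙ^d π^{d/2}).

This estimate is noisy (its log has standard deviation of order 1
regardless of d); the Gaussian-process prior pools information across
similar states:

    f ~ GP(m, Matern52(ℓ)),   ρ = exp f,   dₙ(xᵢ) ~ NN(ρ(xᵢ), d).

The Matérn-5/2 kernel is exactly twice differentiable — smooth enough for a
density field, without the over-smoothing of infinitely differentiable
kernels.

### Hyperparameters

| Parameter | Default | Meaning |
|---|---|---|
| `density_dim` d | state dimensionality d′ (min 2) | dimension used in the likelihood; override for intrinsic-dimensionality studies. d = 1 is rejected: the closed-form estimate vanishes there. |
| `length_scale` ℓ | exp(3 + mean log dₙ) | radius of influence in coordinate units; the heuristic ties it to the geometric-mean nearest-neighbor spacing, so dense regions dominate. |
| mean m | P₁%[log ρ̂] − 10 | GP mean in log-density units; −10 makes far-from-data density vanishingly small. The percentile is applied on the log scale (the mean of a log-density GP lives in log space; a percentile of ρ̂ itself would make "−10" meaningless). Linear-interpolation percentile convention throughout. |
| `n_landmarks` | 5000 | k-means(++) centroids acting as inducing points; full GP at or below this size. |
| kernel variance | 1 | prior marginal variance of f; kept at 1 as the model defines no amplitude hyperparameter. |
| optimiser | L-BFGS-B, gtol 1e-6, maxiter 500 | whitened coefficients, analytic gradients. |

### Inference

The whitened parameterisation puts a standard-normal prior on coefficients
y with f = m + L y, where L is the Cholesky factor of the (jittered)
training covariance in full mode and the Nyström factor K_xz C^{-T} (C the
Cholesky factor of the landmark covariance K_zz) in sparse mode. The MAP
objective

    max_y Σᵢ [ −ρᵢ b(dₙᵢ, d) + log ρᵢ ] − ½‖y‖²,   log ρᵢ = m + (L y)ᵢ

drops the parameter-free log(db/dr) term. Initialisation solves the ridge
problem argmin ‖(log ρ̂ − m) − L y‖² + ‖y‖² in closed form. Diagonal jitter
starts at 1e-6 of the kernel variance and escalates tenfold (to at most
1e-2, logged) on factorisation failure. Prediction is the posterior mean
m + k(query, landmarks) C^{-T} y, which approaches m at distances ≫ ℓ from
all landmarks. A rank check on the landmark covariance warns when the
landmark skeleton's numerical rank falls below its size (model complexity
exhausted; more landmarks would not help).

## Time-continuous density

Measurement time becomes an extra coordinate with a product kernel
Matern52(ℓ_t)(|Δt|)·Matern52(ℓ)(‖Δx‖). The temporal length scale is not
free: per-timepoint density functions (each fitted only on its own cells)
are evaluated on the union of all cells, their pairwise Pearson
correlations form a matrix P, and ℓ_t minimises ‖P − Matern52(ℓ_t)(|t−t′|)‖_F
over [0.01, 100]× the time span (boundary hits warn). Correlations are
computed between *log*-density evaluations: exponentiated densities in ten
or more dimensions span so many orders of magnitude that a density-scale
correlation would be dominated by a handful of peak cells. P entries are
used as-is (no clipping of negative values).

Nearest-neighbor distances for the likelihood are computed within each
timepoint — the point process realised at time t consists of the cells
measured at t. Landmarks are selected by k-means in an augmented space with
time scaled by ℓ/ℓ_t so both coordinates are commensurate. The time
derivative of log-density is analytic (the Matérn factor differentiates to
−(5u/3)(1+√5u)e^{−√5u}/ℓ_t); a central finite difference with step
1e-4·ℓ_t serves as an internal consistency check.

## Trajectory analysis

Branch membership uses a running maximum over a 500-point pseudotime grid
of the 99th percentile of fate probabilities among cells at or below each
grid point; a cell belongs to the branch if its fate probability exceeds
the threshold at the next-larger grid point minus ε = 0.01 (cells beyond
the final grid point are clamped to it; leading unpopulated grid points are
backfilled and never used, since every cell populates its own prefix).
Per-dimension GP trends (Matérn-5/2, length scale 1, observation-noise
variance 0.01, mean = branch coordinate average) map pseudotime to the
state space; the time-continuous density evaluated along this curve gives
the joint pseudotime × real-time density (defaults: 200 pseudotime points,
500 time points per measured interval). Cell types are assigned to grid
points by the largest cell-type density (ties broken by label order), and
marginal proportions integrate exp(log ρ) by trapezoid with each grid
interval assigned to its left endpoint's label — exact when type boundaries
fall on grid points — then normalise per time.

## Gene change scores

Local variability d_ij is the largest |Δ expression| toward any of the
k = 15 nearest neighbors divided by the distance *to that neighbor* (the
formula's subscript is read as the contributing neighbor, matching the
construction "normalised by the distance between states"). The change score
s_j = Σ_{i∈S} d_ij / ρ(xᵢ) concentrates on genes changing rapidly in
low-density states; genes strictly above the 95th percentile are flagged.
Note a structural property: for genes with equal spatial gradients the
1/ρ weight cancels against cell counts, so the score discriminates genes
whose change is *steeper* in sparse regions — the phenomenon it is designed
to detect — not merely genes that happen to overlap them.

## Chromatin scores

TF-IDF uses term frequency (count / cell total) with smoothed IDF
log(1 + N/(1 + n_nonzero)). Gene-peak links require Pearson r ≥ 0.1 and
empirical p ≤ 0.1, with p from within-gene permutation of metacell labels
(B = 999 by default, counted two-sided on |r|, gated one-sided on r).
Openness in a reference population follows the Poisson test with
λ = total fragments / (num_peaks·5000) and a peak open iff P(X > n) < 1e-2;
linked, lineage-relevant peaks are primed if open in the reference and
lineage-specific otherwise. A naive mean-log2FC screen (thresholds > 0
vs other lineages, ≥ 0.25 vs the reference) stands in for a full
differential-accessibility test when no external peak list is supplied.
Primed/lineage scores are correlation-weighted averages of the class's
peak accessibilities; a gene with no peak of a class yields a missing
value, not zero. In-silico ChIP multiplies the expression–accessibility
correlation by a per-TF minmax (across that TF's peaks — the axis is
ambiguous in the field's usage; this reading is fixed here) of motif score
scaled by the peak's maximum accessibility, zeroing magnitudes below 0.15;
a single-peak TF has a degenerate minmax and scores 0 with a warning.

## Synthetic data

The generators are pure functions of spec and seed with exact closed-form
truth evaluators.

**Differentiation tree.** A chain of short edges (depth 12, step 0.6,
bifurcating at levels 4 and 8 → 28 components, ~5000 cells in 10
dimensions), one anisotropic Gaussian per edge aligned to its velocity
vector; child velocities are slightly perturbed copies of the parent's.
Principal axes decay exponentially away from the velocity (rate 1.0,
floored at 1e-3), giving intrinsic dimensionality ≈ 2 as real cell-state
manifolds have. Two systematic trends emulate real landscapes: component
scale grows (+0.3 in log per level) and abundance falls (−0.3 in log per
level) from stem to tips, producing the multi-order-of-magnitude density
decline from stem compartments to differentiated extremes, with lognormal
random-walk variation (sd 0.15 / 0.3) on top. These defaults were chosen so
that the ground-truth density has resolvable structure: any covariance axis
far below the sampling resolution contributes ~0.5 irreducible variance to
the truth's log-density at sampled points (the z²/2 fluctuation of an
unobservable coordinate), an information floor that binds *every*
estimator, including the 1/kNN baseline. A generator whose signal does not
clearly exceed that floor benchmarks noise, not methods.

**Discrete clusters.** Ten components in 20 dimensions, means drawn at
scale 20, Wishart-style covariances with lognormal compactness multipliers
(sd 0.5) — cell-type islands differing in abundance and tightness, mostly
isolated.

**Drifting time series.** A cluster mixture whose means translate linearly
along a fixed random drift (magnitude 2 per unit time) across 5 timepoints,
600 cells each; per-timepoint truths are exact translations, so the
held-out middle timepoint's truth is the midpoint translation.

**Omics fixture.** Cells lie exactly on a 1-D curve through 2-D space
(graph-imputed expression is a smooth function of the observed state, so
placing cells off-manifold would make expression-per-distance ratios
unbounded); pseudotime sampling leaves a sparse corridor at s ∈ (0.4, 0.6)
(5 % of cells). The driver gene ramps steeply (width 0.04) at the corridor
centre; 19 background genes ramp gently (width 0.12) inside the dense
segments; expression noise is smooth in pseudotime, as imputation leaves
it. Primed peaks are half-open from the start and rise; lineage-specific
peaks open only past the corridor. Reference fragment counts are Poisson
draws from the noiseless programmed openness at rate 600, which puts the
openness test's background λ near 0.05 — its sensitive regime.

**What passing these benchmarks does and does not show.** The generators
capture density geometry — branching manifolds, density contrast, temporal
drift — but not scRNA-seq count noise (no negative-binomial sampling, no
dropout, no doublets), batch effects, or the upstream embedding step.
Recovery on them validates the inference machinery, not robustness to raw
count data; in practice the method consumes embeddings produced by a
dedicated pipeline.

## Numerical choices and degenerate inputs

Duplicate coordinates: zero nearest-neighbor distances are replaced by the
smallest positive observed distance × 1e-3 (warned); if *every* distance is
zero (a fully duplicated dataset) each cell instead falls back to its
nearest distinct-location neighbor distance, which preserves the density
ranking of the de-duplicated data. kNN ties break by cell index. All
percentiles use linear interpolation. Exact (tree-based) neighbor search is
the default; approximate search (pynndescent) engages above 50 000 cells or
on request. The 1-D bounded search for ℓ_t uses Brent's method with
xatol 1e-8. Problem sizes in the test-suite and acceptance runs (5000-cell
fits, 3000-cell sparse/full comparison, 100 driver-gene replicates at 400
cells) were chosen as the smallest sizes at which the corresponding
statistical claims are stable.

## Known limitations

* MAP only; the log-posterior is exposed through the model objects but no
  sampler ships. MAP and posterior mean coincide closely in practice for
  this likelihood, but uncertainty is not quantified.
* The density dimension d defaults to the embedding dimension d′; when the
  data's intrinsic dimension is much lower, densities are monotonically
  distorted (rank-preserving but not calibrated in absolute units).
* The length-scale heuristic assumes most cells lie in dense, locally
  low-dimensional regions; on data with near-uniform spacing it can exceed
  the structural scale and over-smooth.
* The naive log2FC lineage-relevance screen is plumbing, not a statistical
  test; supply an externally derived peak list for real analyses.
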