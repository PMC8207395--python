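# Methods notes

This note records the models, conventions, and numerical choices behind
`nestscape`, including the places where a convention had to be fixed by the
package itself.

## Genetic distance

Allele encoding is the standard individual-PCA convention: one column per
observed allele per locus, value = copies carried / 2. Missing locus-calls
(both slots blank; one-sided missingness is rejected at parse) are imputed
with the column mean, which leaves complete columns untouched. Columns are
centered; variance scaling is off by default but exposed
(`encode_and_pca(..., scale=True)`), since sources differ on whether
allele-dosage columns should be standardized before PCA. The default of 64
retained axes balances explained variance against dimensionality for
microsatellite panels and is capped at the matrix rank, so low-rank
synthetic datasets simply keep every informative axis. Distances are
Euclidean in the retained-axis space; with all axes retained they equal
distances on the centered encoded matrix (orthogonal invariance), which the
tests assert against a dense eigendecomposition oracle.

## Mantel correlogram and semivariogram

Distance classes are equal-width over (0, max(geo)]; 30 classes by default.
The per-class statistic is minus the Pearson correlation between
off-diagonal genetic distances and the within-class 0/1 indicator — the
sign flip makes positive r read as positive spatial autocorrelation.
Significance comes from permuting individual labels (999 permutations by
default; p = (1 + #{|r*| ≥ |r|})/(n_perm + 1), two-sided in |r|). Holm
adjustment across classes is reported alongside raw p. The
genetic-neighborhood estimate uses raw p by default, matching common
empirical practice for reading single correlogram classes; the calibration
tests use the Holm-adjusted p when the claim is familywise ("no class shows
significant positive autocorrelation under the null"). Both switches are
explicit arguments.

The semivariogram uses γ(h) = Σ gd² / (2 n) per contiguous lag bin
(default 1.5 km × 52 bins); empty bins are reported with n = 0 and γ = NaN
rather than dropped.

## Resistance transformations

The nine families are fixed analytically so tests can be exact. With
x = PLAND/100, s = 2, M = 100:

- linear: g(x) = x
- monomolecular: g(x) = (1 − e^(−sx)) / (1 − e^(−s))
- Ricker: g(x) = x·e^(−sx), divided by its maximum over [0, 1]
  (peak at x = min(1, 1/s))
- "reverse": x → 1 − x (input flip); "inverse": g → 1 − g (output flip)
- resistance R = 1 + (M − 1)·g

This normalized parameterization reproduces the qualitative shapes of the
curve families commonly used for resistance-surface optimization; an exact
numeric match to any particular external implementation is not claimed.
Useful identity: the inverse variant equals (M + 1) − plain variant
pointwise, asserted in tests. 45 candidates per class = 5 windows × (8
curved families + linear).

Moving windows are squares of the nearest odd cell count to
side/cell_size; windows truncated at the raster edge are normalized by the
in-bounds cell count only, avoiding phantom-cell border bias.

## Patch metrics

Patches are connected components (queen/8-neighbor by default, rook
switchable; the neighbor rule used by common raster-metric tools varies).
Perimeter is counted in 4-neighbor cell-edge units including raster border
edges. Patch density is patches per 100 ha of landscape; cohesion follows
the standard perimeter/area form scaled by the landscape-size factor;
correlation length is the area-weighted mean radius of gyration (mean
cell-to-centroid distance per patch), in meters.

## Commute-time distances

Edge conductance between adjacent cells is the mean of the two cell
conductances divided by the hop length (1 orthogonal, √2 diagonal; 8-
neighborhood by default, 4 switchable). Commute time is
C(i,j) = vol(G)·R_eff(i,j) with vol(G) the degree sum of the connected
component containing the query points. Effective resistances come from one
sparse LU factorization of the grounded component Laplacian per query set,
solved against one unit vector per distinct query node; agreement with a
dense pseudo-inverse oracle is ~1e-12 relative on test surfaces. Points are
snapped to their containing cell center; co-located individuals share a
node (distance 0 — such pairs are excluded from models anyway).
Disconnected query points raise an error listing the components rather than
returning infinities, which MLPE could not absorb.

One property worth stating precisely: scaling every resistance by a
constant k leaves commute time *unchanged* (the walk's transition
probabilities are scale-free), while the effective resistance C/vol scales
by k. Only the volume prefactor separates commute time from
circuit-theoretic resistance distance, so standardized model predictors are
identical under either convention.

## MLPE fitting

The model is y = Xβ + Zu + ε with one random effect per individual and Z
carrying a 1 for each pair member (entries of 1, not 1/√2, so
ρ = σ_u²/(2σ_u² + σ_e²) is bounded by ½). Estimation is full ML — not REML
— because AICc comparisons span models with different fixed effects.
The likelihood is profiled over θ = σ_u²/σ_e²: given θ, β is GLS and σ_e²
closed-form. W = I + θZZᵀ is never formed; the Woodbury identity reduces
every solve to an m × m system (m = individuals), and
log|W| = log|I_m + θZᵀZ|. The 1-D profile is maximized by bounded scalar
minimization on θ ∈ [0, 50] (xatol 1e-8) with the θ = 0 endpoint (OLS)
checked explicitly. Tests pin the implementation to a dense
multivariate-normal likelihood oracle and a grid-search oracle over θ.

Parameter count k = slopes + intercept + 2 variance components; n = number
of included pairs; AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1). Since published
conventions for k and n vary, AICc *differences* are the quantities the
package tests and reports. Predictors are z-scored inside `fit_mlpe` by
default so coefficient magnitudes are comparable for rank-of-effect;
raw-scale fitting is available. Within-location pairs are excluded from
model rows (they carry no between-site landscape signal); counts both ways
are retained. Argmin-AICc ties break toward the smaller window, then a
fixed transformation-family order, and are flagged.

## Congruence classification

Similarity across the three schemes is exact categorical equality (same
rank position, same sign, same window label, same transformation label) —
the published comparisons this mirrors are exact-match, and no tolerance is
defined for "similar" windows. The code assignment is: all equal → A;
Sparse-Large = Sparse-Small → B; Dense-Small = Sparse-Small → C;
Sparse-Large = Dense-Small → D; all distinct → E. Sign is binary, so E is
impossible and reported NA if a degenerate third level (an exactly zero
coefficient) produces an all-distinct triple.

## Synthetic data: what it emulates and what it does not

The generators are stylized stand-ins chosen for testability, not
biological realism:

- **Landscape**: per-class Gaussian-smoothed white noise, argmax across
  classes. Tunable patchiness (smoothing length scale), deterministic in
  the seed. It does not emulate land-use spatial syntax (roads, field
  geometry, riparian corridors).
- **Sampling design**: rejection sampling under a minimum-spacing
  constraint with a fixed 10,000-draw budget; an infeasible packing is a
  loud error, never a silent constraint violation. Default configurations
  mirror the motivating study's geometry (19 locations / ≥7 km over
  45 × 70 km; 14 locations / ≥3 km over 16 × 16 km; ≥5 individuals per
  location), while the end-to-end experiments run a scaled-down geometry
  (below).
- **Genotypes**: location-level allele frequencies are logistic-normal with
  covariance drift_scale² · exp(−D/L̄) over commute distance D (L̄ its mean
  off-diagonal); individuals are Hardy–Weinberg draws. drift_scale = 0
  yields identical frequencies everywhere (the null used for correlogram
  calibration). There is no mutation, no forward-time drift, no linkage —
  passing tests show the *statistical machinery* behaves, not that any
  biological process is modeled.
- **Pairwise distances**: drawn directly from the MLPE generative model
  (β0 + βx + u_i + u_j + ε), which is exactly the assumption of the fitted
  model. This is deliberate for oracle tests; the genotype route above
  provides the model-mismatched counterpart.

Because the generators match the fitted model's assumptions in the direct
route, recovery rates measured here are upper bounds on what equally sized
field data would give.

## Experiment problem sizes and conditions

The end-to-end experiments use an 80 × 80 cell landscape at 50 m (4 × 4 km),
5 classes, smoothing 6 cells, 10 locations at ≥500 m with 4 individuals
each (~700 included pairs), and strong truth β = 1 per predictor SD with
σ_u = 0.2, σ_e = 0.3 — chosen once as a regime where the signal clearly
dominates pair noise, which is what the recovery properties assume. The
nested congruence experiment uses a 120 × 120 landscape, 12 sparse
locations at ≥1.2 km, a 3 × 3 km small area with 10 locations at ≥500 m,
and 3 individuals per location. The Mantel null calibration runs 100
replicates of 25 individuals with 199 permutations (p-value resolution
0.005 comfortably below α = 0.05). Under these conditions, typical measured
rates are: scale/transformation pair recovery 75–90% over 20 replicates
(failures select an adjacent window of the true family), sign recovery
100%, full-model-first 100%, null correlogram significance ~5%.

## Known limitations

- Raster I/O is ESRI ASCII grid only; no GeoTIFF, no projections —
  coordinates are planar meters.
- The genotype simulator's commute-covariance model is phenomenological;
  it produces realistic-looking isolation-by-resistance correlograms but
  has no population-genetic time scale.
- Commute distances require all query points in one graph component by
  design; landscapes with absolute barriers need nodata handling upstream.
- The ten-model comparison set is fixed to the five-class study structure;
  other class sets need a custom `model_set` mapping.
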