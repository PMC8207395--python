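# nestscape

Nested landscape-genetics analysis in Python: from individual multilocus
genotypes and a categorical land-use raster to optimized resistance
surfaces, maximum-likelihood population effects (MLPE) model rankings, and a
classification of how sampling density, study area size, and total sampling
effort change the inferences.

The package is aimed at landscape geneticists working with dispersal-limited,
continuously distributed species — the motivating case is the Mississippi
slimy salamander (*Plethodon mississippi*), sampled at microsatellite loci
across nested study designs — and at methodologists who want a fully
synthetic, ground-truth-known testbed for this class of analysis.

## The analysis

**Genetic distance.** Diploid codominant genotypes are encoded one column
per observed allele (dosage/2 ∈ {0, ½, 1}), mean-imputed, centered, and
projected onto the leading principal components; pairwise genetic distance
is the Euclidean distance between individuals in the retained-axis space
(64 axes by default, capped at rank).

**Spatial structure.** A Mantel correlogram (equal-width distance classes,
permutation p-values, Holm adjustment across classes) estimates the genetic
neighborhood size — the largest distance class with significantly positive
autocorrelation — alongside a semivariogram γ(h) of genetic distance by
geographic lag.

**Resistance surfaces.** For each land-use class, PLAND (percent of a
square moving window occupied by the class; windows of 100–1,000 m) is
mapped to resistance R ∈ [1, 100] through nine transformation families:
linear, monomolecular (saturating), and Ricker (unimodal) curves with
"reverse" (input flip) and "inverse" (output flip) modifiers, shape s = 2
and maximum resistance M = 100.

**Resistance distance.** Each surface induces a lattice graph with edge
conductance ((1/R_a + 1/R_b)/2)/w (w = 1 orthogonal, √2 diagonal); the
pairwise predictor is the commute-time distance C(i,j) = vol(G)·R_eff(i,j),
computed by sparse grounded-Laplacian solves and proportional to
circuit-theoretic resistance distance. Predictors are residualized against
the commute distance on a uniform surface to remove the straight-line
geographic-distance component, and screened for collinearity (|r| > 0.5
drops the lower-priority class).

**MLPE models.** Pairwise distances are not independent — two pairs sharing
an individual are correlated. The MLPE mixed model

&nbsp;&nbsp;&nbsp;&nbsp;y = Xβ + Zu + ε, u ~ N(0, σ<sub>u</sub>² I), ε ~ N(0, σ<sub>e</sub>² I)

puts one random effect per individual (Z the pair-incidence matrix),
inducing correlation ρ = σ<sub>u</sub>²/(2σ<sub>u</sub>² + σ<sub>e</sub>²) ≤ ½
between pairs sharing a member. Fitting is full ML via a one-dimensional
profile over θ = σ<sub>u</sub>²/σ<sub>e</sub>² with Woodbury algebra, so the
cost scales with the number of individuals, not pairs. Per class, 45
candidate predictors (5 windows × 9 transformations) are fitted one at a
time alongside the uniform-landscape distance and ranked by AICc; the
optimized predictors then enter a fixed ten-model comparison (full,
isolation-by-distance, three ecological combinations, five univariate).

**Nested comparison.** Three datasets are carved from one study —
Sparse-Large, Dense-Small, and Sparse-Small (Dense-Small pairs beyond the
sparse spacing threshold) — and each best-fit attribute (rank of effect,
sign, optimized window, optimized transformation) is compared across them:
all agree → A (insensitive); the two sparse datasets agree → B (density
drives outcomes); the two small-area datasets agree → C (area size);
Sparse-Large and Dense-Small agree → D (total effort / threshold); all
differ → E.

A synthetic-data module generates patchy categorical landscapes, nested
sampling designs, genotypes with spatially correlated allele frequencies,
and pairwise distances drawn directly from the MLPE generative model, so
every stage is testable offline with known truth.

## Worked example

Simulate a study whose response is generated from a known focal class,
window, and transformation, then let the 45-candidate AICc optimization
find them:

```python
from nestscape.pipeline import recovery_replicate

res = recovery_replicate(seed=7)
print(res["selected_window"], res["selected_transform"])
print(res["leaderboard"].head(5)[["window_side", "transform", "aicc", "coefficient"]])
```

```
500.0 monomolecular
 window_side                     transform       aicc  coefficient
       500.0                 monomolecular 449.283340     1.019429
       500.0                        linear 471.615966     0.988445
       750.0                        linear 471.822818     0.964583
       250.0                        ricker 481.301280     1.057979
       750.0 inverse-reverse monomolecular 482.121925     0.951182
```

The truth behind this replicate was a 500 m window with a monomolecular
transformation and effect size β = 1 per SD of the residualized predictor:
the winning candidate is exactly that pair (ΔAICc ≈ 22 to the runner-up),
and its standardized coefficient (1.02) recovers β. The same machinery
drives the nested congruence report:

```python
from nestscape.case_study import PUBLISHED_BEST_FITS
from nestscape.nested import comparison_report

report = comparison_report(PUBLISHED_BEST_FITS)
print(report[report["criterion"] == "sign"][["class", "outcome"]].to_string(index=False))
```

which codes, for example, hardwoods/wetlands sign as A (restriction in all
three schemes) and pine sign as C (facilitation only in the large study
area).

A thin CLI wraps the two whole-study entry points:
`nestscape simulate --seed 1 --out out/` writes a landscape (ESRI ASCII
grid), sampling design, genotype table, and ground truth;
`nestscape run --seed 1 --out out/` runs the recovery and nested
sign-congruence experiments and writes summary rates.

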