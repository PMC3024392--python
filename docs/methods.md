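# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `lipidshape`.

## Lipid panel and group statistics

Concentrations are modelled log-normal: `log c ~ N(μ_s, σ_s)` per species.
A between-group effect is an additive shift `log(fold)` of the case-group
log-mean, which makes the *generating* median ratio equal the fold exactly
(the median of a log-normal is `exp(μ)`); planting an effect on the
numerator of a ratio variable while leaving the denominator untouched
shifts the ratio's median by the same fold.

The default panel has 286 species arranged in contiguous
(class, ether-linkage, carbons, double-bond) grids chosen so exhaustive
desaturation + elongation enumeration yields exactly 267 ratios; 106 of the
species are deliberately isolated (no enzymatic neighbour), mirroring real
panels in which many identified lipids have no partner for a ratio. Species
appearing in the concordant between-study table carry that table's control
medians, and their log-scale dispersions are back-solved from the published
interquartile ranges (`σ = ln(q75/q25)/1.349`, averaged over the two
groups; species feeding a ratio get the ratio-implied σ/√2 under
independence). The remaining medians are drawn once, reproducibly, from
`U(ln 0.05, ln 20)` with σ = 0.4 — a typical biological coefficient of
variation. These constants are the package's definition of the emulated
study conditions; they are fixed, not tuning knobs.

Group comparison runs the two-sided t-test on **log** values (Welch by
default; Student's by `equal_var=True`) while folds and quartiles are
computed on the **raw** scale with type-7 (linear-interpolation) quantiles.
This split is forced by the reporting convention of concentration tables:
quartiles are printed in concentration units while the test assumes
approximate Gaussianity, which the log transform provides. No
multiple-testing correction is applied by default because the significance
counts being emulated are raw p < 0.05 tallies. The image-parameter screen
uses the two-sided Wilcoxon rank-sum test (exact null where SciPy can);
an all-tied parameter yields p = 1 with a warning rather than an error.

## Marker model

The logistic likelihood is maximised by Newton–Raphson with step-halving,
so the recorded log-likelihood trace is non-decreasing by construction;
convergence is a relative log-likelihood change below 1e-10 or 100
iterations. Standard errors come from the inverse observed information at
the optimum, z = estimate/SE, two-sided normal p. Quasi-complete separation
(coefficient magnitude > 30 or a fitted probability at machine 0/1) is
flagged; a ridge-stabilised refit (`ridge=1e-6`) is available when finite
coefficients are needed for tooling. At the emulated effect sizes roughly a
third of 11 vs 11 draws are separable — the flag is informative, not rare.

Stepwise AIC starts from the full candidate model and alternates
single-variable drops and adds, taking the strictly-best AIC move until a
local minimum; ties break deterministically by candidate order with drops
evaluated first. On well-separated problems the local minimum coincides
with the exhaustive-enumeration optimum (asserted over all 2^7 subsets in
the tests). Note AIC's entry rule is liberal: a pure-noise candidate
survives with probability P(χ²₁ > 2) ≈ 0.157, so the intercept-only model
is the *modal*, not the overwhelming, outcome on null data (≈ 0.843^k for
k candidates); the tests assert that calibrated rate.

The classification threshold is scanned over midpoints of consecutive
distinct predicted probabilities plus guard points below/above the extremes
and 0.5 itself; among misclassification minimisers the one nearest 0.5
wins. When all predictions coincide only the all-positive/all-negative
labelings exist, so the tuner returns the minority-class error count, and
0.5 when the tie is balanced. Transfer evaluation never refits: the frozen
linear predictor and threshold produce a 2×2 predicted-vs-true table tested
by a 1-df chi-square without continuity correction (flag available), and an
ROC swept over thresholds with trapezoid area.

## Dependency network

Partial correlations are computed from the Schur complement of the
conditioning block of the sub-correlation matrix — only the Q-block is
inverted, so a deterministic i–j dependence correctly returns |ρ| = 1
rather than a singularity. The test is Fisher's z with effective df
n − q − 3. The NRR draws `n_sets` conditioning subsets uniformly (without
replacement within a subset, with replacement across subsets; `n_sets=None`
enumerates all of them) and reports the non-rejection fraction at level α.
Defaults q = 3, n_sets = 100, α = 0.05 are standard for this estimator
class and feasible at n = 22; only the edge threshold (0.53) is a quoted
operating point. Edge width is `1/max(NRR, 1e-3)`; the floor keeps widths
finite. Connected components are reported descriptively.

A structural caveat quantified during development: for a truly independent
pair the subset tests all share one sample and are near-perfectly
correlated, so the pair's NRR falls below 0.5 with probability ≈ α. Exact
recovery of a p = 8 chain at per-test α = 0.05 is therefore bounded near
0.95²¹ ≈ 0.35 regardless of chain strength, and the corresponding
acceptance test is expected to fail; with α multiplicity-controlled at
0.05/28 the estimator recovers the chain exactly in ~56% of runs and
retains every true edge in 100%. The chain simulation uses neighbour
correlation 0.3, chosen by a Fisher-z power analysis (adjacent partial
correlation ≈ 0.28 → power ≈ 1 at n = 500; distance-2 induced correlation
≈ 0.09 keeps non-edges above threshold most of the time).

## Elasticnet relevance

The objective is the naive elasticnet exactly as written —
`‖y − Xβ‖² + u₁‖β‖₁ + u₂‖β‖²` — with no √(1+u₂) coefficient rescaling.
Cyclic coordinate descent soft-thresholds each coordinate
(`β_j ← S(x_jᵀr + β_j‖x_j‖², u₁/2)/(‖x_j‖² + u₂)`), converging when the
largest per-sweep coefficient change is below 1e-8; the inner loop is
numba-compiled with an identical pure-Python fallback. `u1_max = 2·max|Xᵀy|`
is the exact all-zero stationarity bound. Predictors are standardised to
unit variance and the response centred inside each training fold;
coefficients are reported back on the original scale.

Repeated cross-validation partitions the subjects into 5 blocks 100 times
by default (each partition a fresh random permutation). The per-block error
is the mean squared held-out prediction error; the grid point minimising
the block-and-repeat average wins. `e_sd,min` is the standard deviation
(ddof = 1) of the five per-block-position errors averaged over repeats —
the notation is ambiguous between this and the SD over all 500 block
errors; the averaged-report reading was chosen and is the documented
convention. The constant model (training-fold mean) is evaluated under
identical partitions, which makes the huge-u₁ grid point's error *exactly*
equal the constant model's. The decision `e_min + e_sd,min < e_cons` is
strict: equality is not explained. Default grid: 30 log-spaced u₁ from
1e-3·u1_max to u1_max × u₂ ∈ {0, 0.1, 1, 10}. Simulations in tests and the
acceptance script use scaled repeats (5) and a reduced grid for time; the
scaling leaves sensitivity at ~100% and keeps the noise false-positive rate
near the 10% boundary (more repeats tighten it).

## Heart geometry and shape association

The a-priori model uses closed ellipsoids: LV endocardium (semi-axes
25×25×38 mm), epicardium (endocardium + 9 mm wall), and a laterally
displaced, flattened RV endocardial ellipsoid — any smooth closed-at-apex
geometry satisfies the pipeline's invariants, and closed quadrics admit
analytic thickness oracles. Each surface is sampled with a Fibonacci
lattice and triangulated by its convex hull, which realises an *exact*,
arbitrary vertex budget (default 906 LV / 1516 RV / 906 epi = 3328; the
alternative 906/906/1516 reading of the point budget is a constructor
argument away). End-systole is the end-diastolic surface contracted about
its own centre (endocardium ×(0.80, 0.80, 0.93), epicardium
×(0.93, 0.93, 0.97)), so the ES cavity is smaller and wall thickening is
positive by construction.

Subjects deviate from the base geometry along its per-surface area-weighted
vertex normals: `x_ji = base_i + (a_i + b_i·l_j + ε)·n_i`, ε ~ N(0, 0.8 mm)
(a segmentation-error surrogate). The planted slope field is a smoothstep
patch on the septal (RV-facing) side of the LV endocardium, active at ES
with a negative (inward) sign and peak 3 mm per log-concentration unit, so
a 2·SD lipid decrease produces a ≈ 1 mm septal deficit — the scale of
reported regional wall-thickening differences. The intercept is centred on
the control-group lipid mean (`a_i = −b_i·l̄_ctrl`), which makes the
*empirical* control mean surface equal the base geometry; consequently the
full pipeline (mean model → deviations → per-vertex OLS) recovers the
planted slopes to < 1e-9 mm on noiseless data, with no privileged access to
the generator's internals.

Pipeline conventions: normals are computed on the mean model per phase,
per substructure (the triangulation is restricted to each closed surface so
normals never mix structures), and reused for deviations, reconstruction
and motion, with ED normals anchoring motion. Rigid alignment is Kabsch SVD
with the determinant fix (reflections disallowed), one ED-estimated
transform per subject applied to both phases. Wall thickness casts a ray
from each LV endocardial vertex along its outward normal and takes the
first epicardial triangle hit (vectorised Möller–Trumbore, 50 mm cutoff);
misses are flagged NaN and excluded from maps, never imputed. Zero-distance
hits are retained so coincident surfaces read thickness 0. Wall motion is
defined contraction-positive, `(x_ED − x_ES)·n̄_ED`, so that *negative*
difference-map values always mean reduced systolic function under the
lipid perturbation — matching the map colour convention (the raw
ES-minus-ED normal projection is the same quantity negated). Maps are
exported for the LV endocardium as legacy-VTK point scalars and CSV.

## What the synthetic data do not emulate

Species are independent log-normals: real lipidomes have strong within-class
correlation, so multivariate statistics (network edges among lipids,
elasticnet coefficient spreading among correlated species) are easier here
than in real data. Heart shapes vary only along the planted normal
directions plus isotropic normal noise — there is no population shape
variability orthogonal to the coupling, no valve/apex anatomy, and no
imaging artefact structure. Passing tests therefore demonstrate correctness
of the machinery and recoverability of planted effects at realistic sizes,
not performance on patient data; the published per-study counts (57/56
significant lipids, 19/86 image parameters, the specific network and the
septal/basal map pattern) depend on the unavailable individual-level data
and are deliberately not asserted.

## Problem sizes used in tests and acceptance

Simulations run at the study sizes (11 vs 11, 8 vs 8, n = 22 regression
subjects) with meshes at the full 3328-point budget where the quantity is
mesh-dependent (wall thickness, point bookkeeping) and at ~660 points for
pipeline-identity checks where resolution is immaterial; the relevance-rule
simulations use 100 draws with 5-repeat cross-validation and an 8×2 tuning
grid; the chain experiment uses 50 seeds at n = 500. These sizes are the
package's documented defaults for its own verification runs.
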