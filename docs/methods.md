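# Methods

## Model and estimation

O2PLS decomposes two column-centered, sample-aligned blocks X (N×p) and
Y (N×q) into joint, block-specific ("orthogonal") and noise parts:

```
X = T Wᵀ + T_Y⊥ P_Y⊥ᵀ + E,    Y = U Cᵀ + U_X⊥ P_X⊥ᵀ + F,
U = T B_T + H_UT,             T = U B_U + H_TU.
```

Estimation proceeds in five steps (`fit_o2pls`):

1. **Provisional joint part.** SVD of XᵀY; the first singular-vector pairs
   maximize the covariance wᵀXᵀYc over unit vectors (Cauchy–Schwarz on the
   singular-value expansion), so the provisional loadings are the top
   singular vectors and the scores are T₀ = XW₀, U₀ = YC₀.
2. **Orthogonal part of X.** The residual E₀ = X − T₀W₀ᵀ is searched for
   directions that still covary with the joint scores: maximizing
   ‖Tᵀ E w‖² under ‖w‖=1 yields the eigenvector of E₀ᵀT₀T₀ᵀE₀ with the
   largest eigenvalue, i.e. the first left-singular vector of E₀ᵀT₀. All
   n_x directions are taken at once as the leading left-singular vectors
   (they are exactly orthonormal, unlike one-at-a-time re-deflation).
   Orthogonal scores are computed from the residual, T_Y⊥ = E₀W_Y⊥; the
   loadings P_Y⊥ are the least-squares regression of X on T_Y⊥, and X is
   deflated by T_Y⊥P_Y⊥ᵀ.
3. **Orthogonal part of Y**, symmetrically via F₀ᵀU₀.
4. **Final joint part.** A second SVD of the deflated XᵀY re-estimates
   W, C, T, U — the joint part "corrected for" orthogonal variation. With
   n_x = n_y = 0 the fit is exactly two-block PLS from a single SVD.
5. **Inner relations.** B_T, B_U by least squares between the joint scores
   (pseudo-inverse cutoff 1e−12 × largest singular value); residuals are
   kept as H_UT, H_TU.

Sign indeterminacy of singular vectors is resolved by flipping each (w, c)
pair jointly so that the W column's largest-magnitude entry is positive;
flipping pairs (not columns independently) keeps each pair covariance equal
to +d_j. Simulation scoring instead aligns estimates to the generative
truth by the sign of the truth–estimate cross-product.

**Rank of the orthogonal extraction.** E₀ᵀT₀ has at most as many nonzero
singular values as there are provisional joint components, so by default at
most `a` orthogonal components per block can be extracted; requests beyond
that raise an explicit insufficient-rank error. Fitting more block-specific
than shared components (e.g. one joint axis but eight expression-only axes)
is supported by widening the provisional subspace via the
`provisional_components` argument. It is deliberately not the default: the
in-sample inner-R² criterion used for component selection improves slightly
for *every* extra extractable component (each one removes some
score-correlated noise), so a wide provisional subspace lets the grid
search overfit, while the rank-capped default keeps the grid honest.

**Prediction.** New samples are centered with the training means, their
block-specific variation is removed with the fitted filter
(X_corr = X_c − (X_c W_Y⊥)P_Y⊥ᵀ), and the corrected block is mapped through
the joint loadings, the inner regression and the other block's loadings:
Ŷ = X_corr W B_T Cᵀ + ȳ. Filtering is essential: without it, wherever
WᵀP_Y⊥ ≠ 0 the block-specific scores leak into the projected joint scores
and inflate prediction error — measurably enough to distort
cross-validated component selection.

## Component selection

A full 3-D cross-validation over (a, n_x, n_y) is replaced by a two-stage
heuristic (`select_components`):

1. For each candidate `a`, evaluate the criterion
   `(1 − ΣH_UT²/ΣU²) + (1 − ΣH_TU²/ΣT²)` ∈ [0, 2] on the full data over the
   grid {0..max_nx}×{0..max_ny} and take the argmax. Cells beyond the rank
   cap are infeasible (NaN, skipped); exact ties go to the smallest
   n_x + n_y, then smallest n_x.
2. Cross-validate two-way prediction at the chosen (n_x, n_y) with seeded
   near-equal folds; test folds are centered with training means only, so
   no information leaks. `a` minimizes the sum of the total-SS-relative
   MSEs of the two blocks (making blocks of different scale and size
   commensurate); both raw MSEs are reported.

## Simulation design and noise calibration

Scores and noise are i.i.d. normal with mean zero. Loading profiles are
normal-density curves over the variable index (variable i gets the density
N(i; μ, σ)), normalized to unit Euclidean norm. Normalization is what makes
the calibration below exact: with unit-norm loadings a component with score
variance v contributes expected sum of squares N·v to its block.

Given a target noise fraction α ∈ [0, 1) — the share of a block's expected
total sum of squares that is unstructured noise — the noise variances are

```
σ²_E = α/(1−α) · (a·σ²_T + n_x·σ²_{TY⊥}) / p
σ²_H = α/(1−α) · b_t²·σ²_T
σ²_F = α/(1−α) · (a·(b_t²·σ²_T + σ²_H) + n_y·σ²_{UX⊥}) / q
```

(σ²_H feeds into σ²_F because the inner-relation residual propagates into
Y through U). Two stock designs are provided, both with N=500, a=n_x=n_y=1,
b_t=2 and unit score variances:

| design | p, q | W profile | C profile | P_Y⊥ | P_X⊥ | σ²_E, σ²_F, σ²_H ÷ α/(1−α) |
|---|---|---|---|---|---|---|
| low | 100, 50 | (60, 10) | (70, 5) | (20, 20) | (15, 10) | 0.02, 0.104, 4 |
| high | 500, 250 | (300, 50) | (175, 25) | (100, 100) | (75, 50) | 0.004, 0.021, 4 |

The σ²_F coefficient depends on α through σ²_H (0.104 at α=0.05 in the low
design but 0.18 at α=0.5); the formulas are primary, not the table
constants. Note the low design's C profile peaks at index 70 of only 50
variables, so the joint Y-loading is a rising edge ramp; and the C and
P_X⊥ profiles barely overlap, which makes *detection* of the Y-orthogonal
component from F₀ᵀU₀ intrinsically marginal (its signal there is
proportional to the overlap) even though, when fitted at the true component
numbers, the Y-orthogonal loadings are still estimated usably.

`run_study` fits each replicate at the design's true component numbers,
sign-corrects all four loading factors against truth and reports per-entry
mean, median, quartiles and bias. Replicate r uses seed base_seed + r, so
studies are reproducible and trivially parallelizable.

### What the simulations do and do not show

The generator matches the estimation model exactly: Gaussian scores and
noise, homoscedastic noise, no outliers, no missing values, noise-free
inner structure apart from H, and smooth unimodal loading profiles. Real
omics data violate all of these (heavy tails, heteroscedastic measurement
error, correlated noise, batch structure). Passing recovery tests therefore
demonstrate correctness of the estimator under its own assumptions —
bias/spread behavior as dimension and noise change — not robustness on
real data.

Observed behavior under the stock designs (reproduced by the test suite and
`examples/03`): joint loadings W, C are recovered nearly unbiased at both
5% and 50% noise; orthogonal loading estimates degrade with noise, the
Y-block ones most visibly (their median interquartile range roughly doubles
from α=0.05 to α=0.5), because the orthogonal estimation uses only the
noisy leftover variation of a single block.

At zero noise the fitted model reconstructs each block exactly and the
combined joint+orthogonal subspace matches the generative one to machine
precision, but the *split* between joint and orthogonal directions carries
an O(N^−1/2) rotation from finite-sample correlations between independent
scores; tests assert subspace recovery and exact reconstruction, not
direction-wise machine precision.

Component-selection recovery on the low design at α=0.05 is ~80% over
replicates, with essentially all misses selecting (1, 1, 0) — the marginal
n_y detection discussed above.

## Preprocessing chain

Intended for concentration-like (strictly positive, right-skewed) X and
expression-like Y blocks: entrywise Box-Cox `(x^λ − 1)/λ` with a single
global λ = 1/4 by default (computed via expm1/log for stability near λ=0;
λ=0 is the log), column-mean centering with means retained for held-out
data, and a variable filter keeping variables in the top (1 − q)-fraction
both by level (mean of absolute values; median optional) and by spread
(interquartile range, linear-interpolation quartiles). Threshold cuts are
order statistics with ≥ comparisons, so ties are kept and a vanishing
quantile keeps everything. No variance scaling is offered in the default
chain: after centering only, high-variance variables dominate — scaling up
weak variables would mostly amplify noise. Pearson correlation matrices
(unit diagonal, zero-variance columns rejected by name) support
heatmap-style inspection.

## Numerical choices and edge cases

* Pseudo-inverse cutoff 1e−12 (relative) for inner relations and
  orthogonal-loading regressions.
* A residual–score cross-product with Frobenius norm < 1e−12 signals "no
  detectable orthogonal variation" rather than returning noise directions.
* Fitting refuses visibly uncentered blocks (column means above 1e−8
  relative to the data scale) instead of silently centering.
* Component bounds (a ≤ min(p,q), n_x ≤ p−a, n_y ≤ q−a, rank cap) raise
  errors; factors are never zero-padded.
* Matrix text IO writes 17 significant digits and reads with
  round-trip float parsing, so save/load cycles are bit-exact.
* Missing values ("NA" or empty fields) are handled by dropping the whole
  sample during alignment, never by imputation.

## Problem sizes used in the test suite

The replicate studies in the tests use the full stock designs (N=500) with
30–100 replicates, and component-selection recovery uses 50 replicates of
the low design with a 3×3 grid and candidates a ∈ {1, 2, 3} — enough for
the asserted properties to be stable while keeping the suite fast.
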