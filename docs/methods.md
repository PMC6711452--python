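# Methods

## Model family

All estimators operate on a demeaned age vector `Y` (N×1, years) and a
column-demeaned feature matrix `X` (N×D). The generative picture is

    YB = Y + Y²α + δ,        X ≈ f(YB) + noise,

i.e. brain age `YB` is chronological age plus an optional quadratic aging
term plus a subject-specific delta, and the imaging features are driven by
brain age (among other things). Delta is the quantity of scientific
interest; everything else is nuisance.

**Stage 1 (naive).** `β₁ = X⁺Y`, `δ₁ = Xβ₁ − Y`. Because `β₁` is
attenuated by regularisation, predictor noise and non-Gaussian age
distributions, `δ₁` contains a component proportional to `−Y`: in the limit
of a useless model `δ₁ = −Y` exactly. `δ₁` is orthogonal to the columns of
`X`, not to age.

**Stage 2 (correction).** Regress `δ₁` on `Y` and keep the residual:
`δ₂ = M_Y δ₁ = M_Y X X⁺ Y`, with `M_Y = I − YY⁺`. This removes *any*
age-linear bias, whatever its source, at the cost of also discarding any
true delta component that happens to be exactly age-linear — such a
component is unidentifiable from single-timepoint data anyway. The
quadratic variant corrects against `Y₂ = [Y, Yo²]` instead, where `Yo²` is
the demeaned square of age orthogonalised against `Y`; with no quadratic
aging in the data the extra column estimates ≈ 0 and `δ₂q ≈ δ₂`, so the
flexibility is essentially free.

**Switched model.** `X = (Y + δ₃)γ + ε` treats features as responses,
which kills regression dilution (ages are essentially noise-free) and
yields `δ₃ = M_Y X X′Y k`, `k = (Y′Y)/(Y′XX′Y)`. Each feature is modelled
independently, so the estimator is statistically weaker than multiple
regression when features carry correlated non-age structure — unless `X`
is orthonormalised first, in which case `δ₃ = k·δ₂` identically. The
quadratic form `δ₃q = M_{Y₂} X X′Y k` back-projects through the *linear*
loadings row only; the quadratic row of `γ₂ = Y₂⁺X` is retained for
inspection but carries far less variance and degrades the estimate if
used. `k` is kept identical between the linear and quadratic forms.

**Recommended pipeline.** Demean → SVD-reduce `X` to its top-`J` left
singular vectors → build the quadratic basis → stage 1 → stage 2 with
`Y₂`. `δ₂q` is the headline output; `δ₂`, `δ₃`, `δ₃q` are reported
alongside.

## SVD reduction

`X = USV′`; the top-`J` columns of `U` replace `X` (principal-component
regression). The decomposition is computed from the smaller Gram matrix
(`XX′` or `X′X`, top-`J` eigenpairs via LAPACK's subset driver), which is
algebraically identical to an economy SVD up to column signs; signs are
fixed by making each U-column's largest-magnitude element positive so runs
are deterministic. Rank detection uses the Gram eigenvalues with a 1e−12
relative cutoff (the eigenvalue noise floor is ~machine-epsilon relative
to the largest eigenvalue, i.e. much coarser than for singular values);
`J` beyond the rank truncates with a warning rather than failing.
`V` and the singular values are retained so held-out subjects can be
projected onto a training basis (`scores = X_new V S⁻¹`).

`J` is user-chosen. On the simulated cohorts the quality of delta recovery
is sharply asymmetric in `J`: undershooting the true component count is
far more damaging than overshooting (verified in the test suite with true
K=100 and J ∈ {50, 100, 1000}). A sweep helper reports recovery as a
function of `J` when the truth is known; on real data any such tuning must
be nested inside cross-validation.

## Cross-validation

10-fold by default: seeded uniform shuffle, contiguous split, fold sizes
within 1 of each other. Four stages are learned strictly on training
folds: confound regression, SVD basis, `β₁`, and the correction slopes;
all demeaning (ages, features, confounds) uses training-fold means.
Held-out features are projected onto the training SVD basis before `β₁`
is applied. Each subject therefore receives exactly one out-of-fold set
of deltas.

A caveat worth knowing: the correction slope `β₂` is learned from
*in-sample* training residuals. When the model dimension is an appreciable
fraction of the training-fold size (say J/n_train ≳ 0.2), in-sample
residuals are less age-biased than held-out residuals, so the out-of-fold
`δ₂` retains some negative age correlation and its recovery of the true
delta drops a few hundredths relative to the all-in-one fit. At large N
(J/n_train small) the two agree closely — the regime cross-validation is
intended for here.

## Multiplicative aging

`δ = δ₀(1 + λY₀)` with `Y₀` the min-max mapping of age to [0, 1]. Squaring
and taking logs gives `log|δ| ≈ D₀ + λY₀` to first order, fitted by OLS
with an intercept (the intercept absorbs the scale of `δ₀`, making the
estimate equivariant to positive rescaling of delta). The first-order
slope underestimates λ; `λ₁ = e^{λ₀} − 1` removes most of that bias
(verified on direct generative draws: mean error −0.11 for `λ₀` vs −0.03
for `λ₁` at λ=0.5). The expansion assumes λ is not large and negative; a
warning fires below λ₀ = −0.5. The p-value is a one-sided t-test on the
slope. Exact-zero deltas are excluded (log undefined) with a logged count;
more than 10% zeros is rejected as degenerate. The deltas supplied should
be stage-2-corrected: age leak in `δ₁` masquerades as a multiplicative
effect.

## Synthetic cohorts

The generator emulates a large imaging study and is the test bed for every
claim above. Defaults (the primary study conditions):

| parameter | default | meaning |
|---|---|---|
| n_subjects | 20000 | cohort size |
| n_features | 3000 | imaging variables |
| n_components | 100 | latent population modes (first = brain age) |
| age_min, age_max | 45, 75 y | hard support of the age distribution |
| delta_sd | 2 y | sd of the additive true delta |
| feature_noise_sd | 0.5 | measurement noise after column standardisation |
| alpha | 0 | quadratic aging coefficient (uses the age-orthogonal `Yo²`) |
| lambda_true | 0 | multiplicative scaling of delta, `δ·(1+λY₀)` |
| modulate_strengths | off | non-age component strengths × U(0,1) |

Ages are uniform on [45, 75] convolved with a 1-year Gaussian jitter and
clipped — a sharply truncated, hence non-Gaussian, distribution, which is
itself one of the bias drivers being studied. The brain-age component is
z-scored so all latent components have unit strength before optional
modulation; the mixing matrix is an elementwise fifth power of standard
Gaussians (sign-preserving, heavy-tailed, effectively sparse); mixed
columns are standardised to unit sd *before* measurement noise is added.
The rank-1 variant keeps only the brain-age component and raises the noise
sd to 10, the regime in which the mass-univariate `δ₃` beats unregularised
`δ₂` and `J=1` reduction recovers everything there is.

What the generator does **not** emulate: realistic covariance between
imaging features (real IDP eigenspectra fall gradually; the strength
modulation option is a gesture in that direction), site/scanner confounds,
age-correlated confounds, missing data in the features, or disease
subgroups. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not performance claims about
any particular real dataset.

Numerical footnote: the identity `true_brain_age − ages − quadratic_term =
true_delta` holds by construction and is asserted to 1e−12 (floating-point
addition is not exactly invertible).

## Evaluation

In simulations, Q is the Pearson correlation of an estimated delta with
the true one. In association mode, Q is the 99th percentile (numpy linear
interpolation; invariant to variable order) of −log₁₀(p) over per-variable
Pearson correlations between delta and external variables, with p from the
exact t-transform of r, two-sided, uncorrected. Missing values are handled
pairwise per variable; zero-variance or nearly-empty variables are
excluded with a logged count. Under a pure null, Q ≈ −log₁₀(0.01) = 2,
a useful calibration check. Variables can be residualised against supplied
confounds (including age-dependent ones) first; the delta itself is
assumed already corrected.

## Numerical choices and degeneracies

- Every pseudo-inverse / least-squares solve uses a relative singular-value
  cutoff of 1e−10.
- `β₂` assumes demeaned inputs (no intercept), which `AgeVector` enforces;
  the quadratic basis columns are mutually orthogonal by construction so
  `β₂q` solves per column.
- Constant ages, < 3 subjects, < 3 distinct ages (for the quadratic
  basis), empty feature matrices and features with no linear age signal
  (`Y′XX′Y = 0`, which makes `k` undefined) raise typed errors.
- Simulations and fold assignment consume explicit seeds through
  `numpy.random.default_rng`; there is no hidden global state. CSV output
  uses 10 significant digits so write/read round-trips are stable.

## Problem sizes used in the checks

The packaged checks run at sizes chosen to exercise the same regimes as
the full-scale conditions while staying quick on a single CPU: estimator
oracles at N ≤ 50; pipeline properties at N in the hundreds to low
thousands with proportionally reduced feature counts; the reduced-N
recovery condition at its native N=500, D=3000; the modulated-strength
dimensionality pattern at N=4000, D=1000 in the suite and at the native
N=20000, D=3000 (averaged over five cohorts) in the acceptance script; λ
recovery at N=4000 with ten repetitions. Where a scaled size is used the
assertions target orderings and patterns rather than full-scale point
values.

## Known limitations

- The stage-2 correction removes exactly-age-linear (or quadratic) true
  delta components along with the bias; this is inherent to
  single-timepoint data, not an implementation choice.
- Out-of-fold deltas from cross-validation can retain a small age
  correlation when the model dimension approaches the training-fold size
  (see the cross-validation caveat above).
- Step 1 always fits the linear age term; populations near the peak of the
  lifespan inverted-U (where the quadratic dominates) would need the
  quadratic-first variant, which is not auto-selected.
- No spline or higher-order aging models; no sparse/penalised stage-1
  regression; no voxelwise image I/O — features arrive as numeric tables.
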