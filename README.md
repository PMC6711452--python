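# agedelta

Bias-corrected estimation of **brain age delta** — the difference between the
age a subject's brain *appears* to be (predicted from imaging features) and
their chronological age. A positive delta suggests accelerated aging, a
negative one resilience, and researchers routinely correlate delta with
health outcomes, cognition and life factors. The package is aimed at
neuroimaging and epidemiology researchers who already have a subjects ×
features matrix (IDPs, voxelwise values, …) and an age vector, and want
delta estimates that are *not* confounded by age itself.

## The problem and the estimators

The common approach regresses age `Y` (demeaned) on features `X` (demeaned)
and takes the residual with its sign flipped:

    β₁ = X⁺Y,   YB₁ = Xβ₁,   δ₁ = YB₁ − Y

Shrinkage from regularisation, measurement noise in `X` (regression
dilution) and non-Gaussian age distributions all bias `β₁` towards zero, so
`δ₁` ends up negatively correlated with age — associations with `δ₁` can be
driven by age, not by brain health. The corrected estimator removes the
leak in a second stage using the residual-forming matrix `M_Y = I − YY⁺`:

    δ₂ = δ₁ − Yβ₂ = M_Y X X⁺ Y

which is orthogonal to age by construction. A "switched" model treats each
feature as a response to brain age, `X = (Y + δ₃)γ + ε`, giving the
mass-univariate estimator `δ₃ = M_Y X X′Y k` with `k = (Y′Y)/(Y′XX′Y)`;
after the features are replaced by their top-`J` left singular vectors
(principal-component regression), `δ₃ = k·δ₂`. Quadratic aging is absorbed
by correcting against the two-column basis `Y₂ = [Y, Yo²]` (`Yo²` the
demeaned, age-orthogonalised square of age), giving `δ₂q = M_{Y₂} X X⁺ Y`
and `δ₃q`. A multiplicative-aging analysis fits `δ = δ₀(1 + λY₀)` (with
`Y₀` age mapped to [0, 1]) by regressing `log|δ|` on `Y₀` and adjusting the
slope via `λ₁ = e^{λ₀} − 1`.

The package provides these estimators in closed form (`delta_core`), SVD
reduction (`reduction`), leakage-free 10-fold cross-validation in which
confound removal, SVD, the stage-1 fit and the stage-2 correction are all
learned on training folds (`crossval`), the λ analysis (`nonadditive`),
simulation generators that emulate a large imaging cohort (`simulate`), and
evaluation metrics including the association statistic Q (`evaluate`).

## Worked example

```python
import numpy as np
import agedelta as ad

cohort = ad.simulate_cohort(n_subjects=2000, n_features=600,
                            n_components=100, seed=7)
fit = ad.recommended_pipeline(cohort.X, cohort.ages, J=100)
report = ad.simulation_metrics(fit, cohort)
print(f"corr(delta1, age)        = {report.r_delta1_age:+.3f}")
print(f"corr(delta2, age)        = {np.corrcoef(fit.delta2, cohort.ages)[0,1]:+.3f}")
print(f"corr(delta1, true delta) = {report.Q_delta1:.3f}")
print(f"corr(delta2, true delta) = {report.Q_delta2:.3f}")
print(f"mean |delta2|            = {report.mean_abs_delta2:.2f} y")
```

prints

```
corr(delta1, age)        = -0.289
corr(delta2, age)        = -0.000
corr(delta1, true delta) = 0.679
corr(delta2, true delta) = 0.714
mean |delta2|            = 1.93 y
```

The naive delta carries a spurious negative age correlation of −0.29 — a
subject's "brain age gap" would partly just encode how old they are. The
corrected delta is age-orthogonal (−0.000) and tracks the true simulated
delta better (0.714 vs 0.679). The same flow works from the shell:

```bash
agedelta simulate --n 2000 --features 600 --seed 7 --out-dir cohort/
agedelta fit --features cohort/X.csv --ages cohort/ages.csv \
             --svd-components 100 --out deltas.csv
agedelta lambda --deltas deltas.csv --ages cohort/ages.csv
```

`agedelta crossval` computes out-of-fold deltas (adding a `fold_id`
column), and `agedelta evaluate` correlates a delta column with a table of
non-imaging variables and reports Q, the 99th percentile of −log₁₀(p).

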