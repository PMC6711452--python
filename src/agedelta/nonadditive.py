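"""Multiplicative (non-additive) aging: does the spread of delta grow with age?

With one timepoint per subject, a subject aging faster than the population
mean is indistinguishable from a subject with a constant offset — both land
in the delta.  At the population level, however, multiplicative aging leaves
a footprint: the dispersion of delta widens with age,

    delta = delta0 * (1 + lambda * Y0),

where ``Y0`` is age mapped linearly onto [0, 1] so ``|delta0|`` describes the
youngest subjects.  Squaring, taking logs and expanding ``log(1 + lambda Y0)``
to first order turns this into a linear regression of ``log|delta|`` on
``Y0``; the fitted slope ``lambda0`` is then corrected for the expansion
error via ``lambda1 = exp(lambda0) - 1``.  The approximation assumes lambda
is not large and negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .delta_core import DegenerateInputError, DimensionError, _as_vector

logger = logging.getLogger("agedelta.nonadditive")


@dataclass(frozen=True)
class LambdaFit:
    """Estimate of the multiplicative aging coefficient.

    ``D0`` is the model's baseline-plus-noise term ``log|delta| - lambda0*Y0``
    (NaN where a zero delta was excluded); ``lambda1 = exp(lambda0) - 1`` is
    the bias-adjusted estimate and always exceeds -1.
    """

    Y0: np.ndarray
    lambda0: float
    lambda1: float
    p_value: float       # one-sided, H1: slope > 0
    D0: np.ndarray
    n_excluded: int = 0


def map_age_unit(ages_raw) -> np.ndarray:
    """Affine map of ages onto [0, 1]: min -> 0, max -> 1."""
    ages = _as_vector(ages_raw, "ages")
    lo, hi = float(ages.min()), float(ages.max())
    if hi == lo:
        raise DegenerateInputError("ages are constant; cannot map to [0, 1]")
    return (ages - lo) / (hi - lo)


def estimate_lambda(delta, ages_raw) -> LambdaFit:
    """Fit ``log|delta| ~ D0 + lambda0 * Y0`` and bias-adjust the slope.

    ``delta`` should be a stage-2-corrected (age-orthogonal) delta vector;
    the naive delta's age leak would masquerade as a multiplicative effect.
    Exact zeros (log undefined) are excluded with a logged count; more than
    10% zeros is treated as a degenerate input.
    """
    delta = _as_vector(delta, "delta")
    ages = _as_vector(ages_raw, "ages")
    if delta.size != ages.size:
        raise DimensionError(
            f"delta has {delta.size} entries but ages has {ages.size}")
    Y0 = map_age_unit(ages)

    nonzero = delta != 0.0
    n_excluded = int((~nonzero).sum())
    if n_excluded > 0.1 * delta.size:
        raise DegenerateInputError(
            f"{n_excluded}/{delta.size} deltas are exactly zero (> 10%); "
            "log|delta| is undefined for these")
    if n_excluded:
        logger.info("excluding %d exactly-zero deltas from the lambda fit",
                    n_excluded)

    logabs = np.log(np.abs(delta[nonzero]))
    res = scipy.stats.linregress(Y0[nonzero], logabs)
    lambda0 = float(res.slope)
    # linregress reports the two-sided slope t-test; fold to one-sided H1: slope > 0
    p_one_sided = res.pvalue / 2.0 if lambda0 > 0 else 1.0 - res.pvalue / 2.0
    if lambda0 < -0.5:
        warnings.warn(
            f"lambda0={lambda0:.3f} is large and negative; the log-expansion "
            "behind the bias adjustment may not be valid", stacklevel=2)

    D0 = np.full(delta.size, np.nan)
    D0[nonzero] = logabs - lambda0 * Y0[nonzero]
    return LambdaFit(Y0=Y0, lambda0=lambda0, lambda1=float(np.expm1(lambda0)),
                     p_value=float(p_one_sided), D0=D0, n_excluded=n_excluded)
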