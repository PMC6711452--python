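"""Evaluation metrics for delta estimators.

Two modes.  On simulated cohorts the truth is known, so the headline
quality measure Q is simply the Pearson correlation between an estimated
and the true delta, alongside correlations with age (the bias signature)
and mean absolute deltas.  On real data, where truth is unavailable, Q is
a surrogate built from mass-univariate association tests: correlate the
delta with each of many non-imaging variables, convert the (two-sided)
p-values to -log10, and take the 99th percentile across variables —
emphasising the strong tail of associations rather than the null bulk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import scipy.stats

from .delta_core import DeltaFit, DimensionError, PINV_RCOND, _as_vector
from .simulate import SimulatedCohort

logger = logging.getLogger("agedelta.evaluate")


@dataclass
class EvaluationReport:
    """One row of metrics for a fitted cohort (means/sds across repeats via
    :func:`summarize_reports`)."""

    r_delta1_age: float = np.nan
    r_age_YB1: float = np.nan
    r_age_YB2: float = np.nan
    mean_abs_delta1: float = np.nan
    mean_abs_delta2: float = np.nan
    mean_abs_delta3: float = np.nan
    Q_delta1: float = np.nan
    Q_delta2: float = np.nan
    Q_delta3: float = np.nan
    Q_delta2q: float = np.nan
    Q_delta3q: float = np.nan
    n_repeats: int = 1

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _corr(a, b) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def simulation_metrics(fit: DeltaFit, truth: SimulatedCohort) -> EvaluationReport:
    """Correlations with age and true delta, and mean |delta|, for one fit."""
    td = truth.true_delta
    ages = truth.ages
    rep = EvaluationReport()
    if fit.delta1 is not None:
        if fit.delta1.size != td.size:
            raise DimensionError(
                f"fit has {fit.delta1.size} subjects but cohort has {td.size}")
        rep.r_delta1_age = _corr(fit.delta1, ages)
        rep.mean_abs_delta1 = float(np.abs(fit.delta1).mean())
        rep.Q_delta1 = _corr(fit.delta1, td)
    if fit.YB1 is not None:
        rep.r_age_YB1 = _corr(fit.YB1, ages)
    if fit.YB2 is not None:
        rep.r_age_YB2 = _corr(fit.YB2, ages)
    if fit.delta2 is not None:
        rep.mean_abs_delta2 = float(np.abs(fit.delta2).mean())
        rep.Q_delta2 = _corr(fit.delta2, td)
    if fit.delta3 is not None:
        rep.mean_abs_delta3 = float(np.abs(fit.delta3).mean())
        rep.Q_delta3 = _corr(fit.delta3, td)
    if fit.delta2q is not None:
        rep.Q_delta2q = _corr(fit.delta2q, td)
    if fit.delta3q is not None:
        rep.Q_delta3q = _corr(fit.delta3q, td)
    return rep


def summarize_reports(reports: list[EvaluationReport]
                      ) -> tuple[EvaluationReport, EvaluationReport]:
    """Mean and sd of each metric across repeated simulations."""
    mean, sd = EvaluationReport(), EvaluationReport()
    for f in fields(EvaluationReport):
        if f.name == "n_repeats":
            continue
        vals = np.array([getattr(r, f.name) for r in reports], dtype=float)
        setattr(mean, f.name, float(np.nanmean(vals)) if not np.isnan(vals).all() else np.nan)
        setattr(sd, f.name, float(np.nanstd(vals, ddof=1)) if len(reports) > 1 else 0.0)
    mean.n_repeats = sd.n_repeats = len(reports)
    return mean, sd


def deconfound(data, confounds) -> np.ndarray:
    """Residualise each data column against the confounds (plus intercept).

    Redundant (rank-deficient) confound columns are tolerated: the solve uses
    a rank-revealing least squares, and a warning reports the deficiency.
    """
    data = np.asarray(data, dtype=float)
    squeeze = data.ndim == 1
    if squeeze:
        data = data[:, None]
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != data.shape[0]:
        raise DimensionError(
            f"data has {data.shape[0]} rows but confounds has {C.shape[0]}")
    design = np.column_stack([np.ones(C.shape[0]), C])
    beta, _, rank, _ = np.linalg.lstsq(design, data, rcond=PINV_RCOND)
    if rank < design.shape[1]:
        warnings.warn(
            f"confound design is rank-deficient ({rank} < {design.shape[1]}); "
            "redundant columns contribute nothing", stacklevel=2)
    resid = data - design @ beta
    return resid.ravel() if squeeze else resid


def association_q(delta, variables, confounds=None, percentile: float = 99.0
                  ) -> tuple[float, np.ndarray]:
    """Surrogate quality metric for real data.

    Pearson-correlates the delta with every column of ``variables`` (pairwise
    complete over missing values), converts two-sided p-values (exact
    t-distribution transform of r) to -log10, and returns the requested
    percentile across variables (linear interpolation) plus the per-variable
    -log10(p) vector (NaN where a variable was excluded for zero variance or
    too few complete pairs).

    If ``confounds`` is given, the variables are residualised against them
    first; the delta is assumed already deconfounded/corrected.
    """
    delta = _as_vector(delta, "delta")
    V = np.asarray(variables, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    if V.shape[0] != delta.size:
        raise DimensionError(
            f"delta has {delta.size} entries but variables has {V.shape[0]} rows")
    if confounds is not None:
        # column-wise deconfounding on complete rows only, preserving NaNs
        C = np.asarray(confounds, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        V = V.copy()
        for j in range(V.shape[1]):
            ok = ~np.isnan(V[:, j])
            if ok.sum() > C.shape[1] + 1:
                V[ok, j] = deconfound(V[ok, j], C[ok])

    neglogp = np.full(V.shape[1], np.nan)
    n_excluded = 0
    for j in range(V.shape[1]):
        ok = ~np.isnan(V[:, j]) & ~np.isnan(delta)
        v = V[ok, j]
        if ok.sum() < 3 or np.ptp(v) == 0 or np.ptp(delta[ok]) == 0:
            n_excluded += 1
            continue
        r, p = scipy.stats.pearsonr(delta[ok], v)
        neglogp[j] = -np.log10(max(p, np.finfo(float).tiny))
    if n_excluded:
        logger.info("excluded %d variables with zero variance or too few "
                    "complete pairs", n_excluded)
    valid = neglogp[~np.isnan(neglogp)]
    if valid.size == 0:
        raise DimensionError("no variable had enough complete, varying data")
    Q = float(np.percentile(valid, percentile))
    return Q, neglogp
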