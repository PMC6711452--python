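"""Closed-form estimators of brain age delta.

The brain age delta of a subject is the difference between the apparent
("brain") age predicted from imaging features and the chronological age:
``delta = YB - Y``.  The naive estimator fits ages from features by least
squares and takes the residual with its sign flipped,

    delta1 = X beta1 - Y,   beta1 = X+ Y,

which is orthogonal to the feature matrix ``X`` but *not* to age: shrinkage,
non-Gaussian age distributions and measurement noise in ``X`` all attenuate
``beta1``, leaking age into ``delta1``.  The corrected estimator regresses
that leak out in a second stage,

    delta2 = delta1 - Y beta2 = MY X X+ Y,

where ``MY = I - Y Y+`` is the residual-forming projection for (demeaned)
age, so ``delta2`` is orthogonal to age by construction.  A "switched" model
treats the features as the response, ``X = (Y + delta3) gamma + eps``, giving
the mass-univariate estimator ``delta3 = MY X X' Y k`` with
``k = (Y'Y)/(Y'X X'Y)``; after orthonormal SVD reduction of ``X`` it
coincides with ``k * delta2``.  Quadratic variants replace the single age
regressor with the two-column basis ``Y2 = [Y, Yo2]`` (``Yo2`` the demeaned
square of age orthogonalised against ``Y``), absorbing accelerating aging
into the correction.

All estimators operate on *demeaned* quantities; :func:`recommended_pipeline`
wires the full sequence (demean, SVD-reduce, quadratic basis, stage-1 fit,
stage-2 correction) together for raw inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

logger = logging.getLogger("agedelta.delta_core")

#: Relative singular-value cutoff used by every pseudo-inverse / least-squares
#: solve in the package (relative to the largest singular value).
PINV_RCOND = 1e-10


class DimensionError(ValueError):
    """Input shapes are inconsistent (e.g. subject counts differ)."""


class DegenerateInputError(ValueError):
    """An input is degenerate: constant ages, empty feature matrix, rank-deficient basis."""


class EstimationError(RuntimeError):
    """An estimator's defining quantity is undefined for these inputs."""


def _as_vector(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim == 2 and 1 in v.shape:
        v = v.ravel()
    if v.ndim != 1:
        raise DimensionError(f"{name} must be a 1-d vector, got shape {v.shape}")
    return v


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeVector:
    """Chronological ages with their demeaned form.

    The residual-forming projection ``MY = I - Y Y+`` is exposed as
    :meth:`residualize` and never materialised as an N x N matrix.
    """

    raw: np.ndarray   #: ages in years, shape (N,)
    Y: np.ndarray     #: demeaned ages, shape (N,)
    mean: float       #: sample mean used for demeaning

    @classmethod
    def from_raw(cls, ages) -> "AgeVector":
        ages = _as_vector(ages, "ages")
        if ages.size < 3:
            raise DegenerateInputError(f"need at least 3 subjects, got {ages.size}")
        mean = float(ages.mean())
        Y = ages - mean
        if not np.any(np.abs(Y) > 0):
            raise DegenerateInputError("ages are constant; age effects cannot be estimated")
        return cls(raw=ages, Y=Y, mean=mean)

    @property
    def n(self) -> int:
        return self.Y.size

    def residualize(self, v: np.ndarray) -> np.ndarray:
        """Apply ``MY = I - Y Y+`` to a vector or to each column of a matrix."""
        Y = self.Y
        coef = (Y @ v) / (Y @ Y)
        return v - np.multiply.outer(Y, coef) if np.ndim(v) == 2 else v - Y * coef


@dataclass(frozen=True)
class QuadraticAgeBasis:
    """Two-column age basis ``Y2 = [Y, Yo2]``.

    ``Yo2`` is the demeaned square of age orthogonalised against ``Y``, so the
    two columns are mutually orthogonal and the projection ``MY2 = I - Y2 Y2+``
    factors into two rank-1 subtractions.
    """

    Y: np.ndarray
    Yo2: np.ndarray

    @property
    def Y2(self) -> np.ndarray:
        return np.column_stack([self.Y, self.Yo2])

    def residualize(self, v: np.ndarray) -> np.ndarray:
        """Apply ``MY2 = I - Y2 Y2+`` to a vector or to matrix columns."""
        out = v
        for col in (self.Y, self.Yo2):
            coef = (col @ out) / (col @ col)
            out = out - (np.multiply.outer(col, coef) if np.ndim(v) == 2 else col * coef)
        return out


@dataclass
class FeatureMatrix:
    """Subjects x features data with explicit demeaning/orthonormality state."""

    X: np.ndarray
    column_means: Optional[np.ndarray] = None
    column_scales: Optional[np.ndarray] = None
    is_demeaned: bool = False
    is_orthonormal: bool = False

    @classmethod
    def from_raw(cls, X, standardize: bool = False) -> "FeatureMatrix":
        """Demean (and optionally unit-scale) the columns of a raw matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DimensionError(f"feature matrix must be 2-d, got shape {X.shape}")
        if np.isnan(X).any():
            raise DegenerateInputError("feature matrix contains missing values")
        means = X.mean(axis=0)
        Xd = X - means
        scales = None
        if standardize:
            scales = Xd.std(axis=0, ddof=0)
            scales[scales == 0] = 1.0
            Xd = Xd / scales
        return cls(X=Xd, column_means=means, column_scales=scales, is_demeaned=True)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class DeltaFit:
    """Container for every estimator output produced along the pipeline.

    Fields are filled in as the corresponding stages run; entries that a
    given call does not compute stay ``None``.  All delta vectors are in
    years.  ``YB1``/``YB2`` are predicted brain ages on the raw age scale.
    """

    beta1: Optional[np.ndarray] = None      # (D,) stage-1 coefficients
    delta1: Optional[np.ndarray] = None     # (N,) naive delta
    YB1: Optional[np.ndarray] = None        # (N,) initial predicted brain age
    beta2: Optional[float] = None           # stage-2 slope (linear correction)
    delta2: Optional[np.ndarray] = None     # (N,) age-orthogonal delta
    beta2q: Optional[np.ndarray] = None     # (2,) stage-2 coefficients, quadratic basis
    delta2q: Optional[np.ndarray] = None    # (N,)
    YB2: Optional[np.ndarray] = None        # (N,) corrected predicted brain age
    gamma: Optional[np.ndarray] = None      # (D,) switched-model loadings
    k: Optional[float] = None               # switched-model scaling
    delta3: Optional[np.ndarray] = None     # (N,)
    gamma2: Optional[np.ndarray] = None     # (2, D) switched-model loadings, quadratic
    delta3q: Optional[np.ndarray] = None    # (N,)
    epsilon: Optional[np.ndarray] = None    # (N, D) switched-model residuals
    fold_ids: Optional[np.ndarray] = None   # (N,) set by cross-validation only


# ---------------------------------------------------------------------------
# Stage-1 fit and stage-2 corrections
# ---------------------------------------------------------------------------

def fit_delta1(X: FeatureMatrix, Y: AgeVector, keep_epsilon: bool = False) -> DeltaFit:
    """Naive delta: least-squares age prediction residual, ``delta1 = X X+ Y - Y``."""
    if not X.is_demeaned:
        raise DegenerateInputError("feature matrix must be demeaned (FeatureMatrix.from_raw)")
    if X.n_subjects != Y.n:
        raise DimensionError(
            f"feature matrix has {X.n_subjects} rows but ages has {Y.n} entries")
    if X.n_features == 0:
        raise DegenerateInputError("feature matrix has zero columns")
    beta1, *_ = np.linalg.lstsq(X.X, Y.Y, rcond=PINV_RCOND)
    pred = X.X @ beta1
    delta1 = pred - Y.Y
    return DeltaFit(beta1=beta1, delta1=delta1, YB1=Y.raw + delta1)


def correct_delta2(delta1, Y: AgeVector) -> tuple[float, np.ndarray]:
    """Stage-2 linear correction: regress delta1 on age, keep the residual.

    Returns ``(beta2, delta2)`` with ``delta2 = delta1 - Y beta2 = MY delta1``.
    """
    delta1 = _as_vector(delta1, "delta1")
    if delta1.size != Y.n:
        raise DimensionError(f"delta1 has {delta1.size} entries but ages has {Y.n}")
    beta2 = float((Y.Y @ delta1) / (Y.Y @ Y.Y))
    return beta2, delta1 - Y.Y * beta2


def fit_delta3(X: FeatureMatrix, Y: AgeVector, keep_epsilon: bool = False
               ) -> tuple[np.ndarray, float, np.ndarray]:
    """Switched-model delta: ``delta3 = MY X X' Y k``, ``k = (Y'Y)/(Y'X X'Y)``.

    Models each feature column as a response to brain age, so the delta sits
    in the residuals and is age-orthogonal by construction.  Returns
    ``(gamma, k, delta3)``; with ``keep_epsilon`` the (N, D) residual matrix
    ``MY X`` is attached as a fourth element.
    """
    if not X.is_demeaned:
        raise DegenerateInputError("feature matrix must be demeaned")
    if X.n_subjects != Y.n:
        raise DimensionError(
            f"feature matrix has {X.n_subjects} rows but ages has {Y.n} entries")
    yty = float(Y.Y @ Y.Y)
    XtY = X.X.T @ Y.Y
    denom = float(XtY @ XtY)
    if denom <= PINV_RCOND * yty * max(1.0, float(np.abs(X.X).max()) ** 2):
        raise EstimationError(
            "Y'XX'Y is zero: the feature matrix carries no linear age signal, "
            "so the switched-model scaling k is undefined")
    gamma = XtY / yty  # = Y+ X
    k = yty / denom
    delta3 = Y.residualize(X.X @ XtY) * k
    if keep_epsilon:
        return gamma, k, delta3, Y.residualize(X.X)
    return gamma, k, delta3


# ---------------------------------------------------------------------------
# Quadratic-aging variants
# ---------------------------------------------------------------------------

def build_quadratic_basis(Y: AgeVector) -> QuadraticAgeBasis:
    """Demean age squared and orthogonalise it against age, giving ``[Y, Yo2]``."""
    if np.unique(Y.raw).size < 3:
        raise DegenerateInputError(
            "quadratic age basis needs at least 3 distinct ages")
    q = Y.Y ** 2
    q = q - q.mean()
    Yo2 = Y.residualize(q)
    if np.linalg.norm(Yo2) <= PINV_RCOND * max(1.0, np.linalg.norm(q)):
        raise DegenerateInputError(
            "quadratic term is collinear with age; basis would be rank-deficient")
    return QuadraticAgeBasis(Y=Y.Y, Yo2=Yo2)


def correct_delta2q(delta1, basis: QuadraticAgeBasis) -> tuple[np.ndarray, np.ndarray]:
    """Stage-2 correction with the two-column basis: ``delta2q = MY2 delta1``.

    ``beta2q`` holds the linear-bias slope and the quadratic-aging coefficient.
    """
    delta1 = _as_vector(delta1, "delta1")
    if delta1.size != basis.Y.size:
        raise DimensionError(
            f"delta1 has {delta1.size} entries but basis has {basis.Y.size}")
    # columns of Y2 are orthogonal by construction, so solve per column
    beta2q = np.array([
        (basis.Y @ delta1) / (basis.Y @ basis.Y),
        (basis.Yo2 @ delta1) / (basis.Yo2 @ basis.Yo2),
    ])
    return beta2q, delta1 - basis.Y2 @ beta2q


def fit_delta3q(X: FeatureMatrix, basis: QuadraticAgeBasis, Y: AgeVector
                ) -> tuple[np.ndarray, float, np.ndarray]:
    """Switched model with quadratic basis: ``delta3q = MY2 X X' Y k``.

    The loadings ``gamma2 = Y2+ X`` carry a linear and a quadratic row, but the
    back-projection onto subjects uses only the linear row (the quadratic row
    is weakly determined in practice), with the same ``k`` as :func:`fit_delta3`.
    """
    if X.n_subjects != Y.n:
        raise DimensionError(
            f"feature matrix has {X.n_subjects} rows but ages has {Y.n} entries")
    yty = float(Y.Y @ Y.Y)
    XtY = X.X.T @ Y.Y
    denom = float(XtY @ XtY)
    if denom <= PINV_RCOND * yty * max(1.0, float(np.abs(X.X).max()) ** 2):
        raise EstimationError(
            "Y'XX'Y is zero: the feature matrix carries no linear age signal")
    gamma2 = np.vstack([
        XtY / yty,
        (basis.Yo2 @ X.X) / (basis.Yo2 @ basis.Yo2),
    ])
    k = yty / denom
    delta3q = basis.residualize(X.X @ XtY) * k
    return gamma2, k, delta3q


# ---------------------------------------------------------------------------
# Recommended end-to-end pipeline
# ---------------------------------------------------------------------------

def recommended_pipeline(X_raw, ages_raw, J: int) -> DeltaFit:
    """Run the full recommended sequence on raw inputs.

    Demeans ages and features, SVD-reduces the features to ``J`` orthonormal
    subject-eigenvectors (``J=0`` skips reduction), builds the quadratic age
    basis, fits the naive delta, then applies both the linear and the
    two-column stage-2 corrections plus the switched-model estimators.  The
    headline output is ``delta2q``; ``delta2`` is its linear-only sibling.
    """
    from .reduction import svd_reduce  # deferred: reduction depends on this module's types

    Y = AgeVector.from_raw(ages_raw)
    X = FeatureMatrix.from_raw(X_raw)
    if X.n_subjects != Y.n:
        raise DimensionError(
            f"feature matrix has {X.n_subjects} rows but ages has {Y.n} entries")
    if J:
        red = svd_reduce(X, J)
        X = FeatureMatrix(X=red.U, is_demeaned=True, is_orthonormal=True)
    basis = build_quadratic_basis(Y)
    fit = fit_delta1(X, Y)
    fit.beta2, fit.delta2 = correct_delta2(fit.delta1, Y)
    fit.beta2q, fit.delta2q = correct_delta2q(fit.delta1, basis)
    fit.gamma, fit.k, fit.delta3 = fit_delta3(X, Y)
    fit.gamma2, _, fit.delta3q = fit_delta3q(X, basis, Y)
    fit.YB2 = Y.raw + fit.delta2
    return fit
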