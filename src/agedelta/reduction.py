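"""SVD-based principal-component reduction of the feature matrix.

Writing the demeaned feature matrix as ``X = U S V'``, the top-``J``
subject-eigenvectors ``U_J`` replace ``X`` in the delta estimators
(principal-component regression).  Because ``U_J`` is orthonormal, the
stage-2-corrected and switched-model deltas coincide up to the scaling
``k`` after reduction, and the truncation acts as regularisation.

The decomposition is computed from the smaller Gram matrix (``X X'`` when
subjects are fewer than features, ``X'X`` otherwise); the result is
identical to an economy SVD up to column sign, which is then fixed
deterministically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .delta_core import (AgeVector, DegenerateInputError, FeatureMatrix,
                         PINV_RCOND, correct_delta2, fit_delta1)

logger = logging.getLogger("agedelta.reduction")


@dataclass(frozen=True)
class SVDReduction:
    """Top-J left singular vectors of a demeaned feature matrix.

    ``V`` (feature loadings) is retained so held-out subjects can be
    projected onto the same basis: ``scores = X_new @ V / singular_values``.
    """

    U: np.ndarray                 # (N, J), orthonormal columns
    singular_values: np.ndarray   # (J,), descending, positive
    J: int
    V: np.ndarray                 # (D, J)

    def project(self, X_new: np.ndarray) -> np.ndarray:
        """Coordinates of new (already demeaned) rows in this basis."""
        return (X_new @ self.V) / self.singular_values


def svd_reduce(X, J: int) -> SVDReduction:
    """Top-``J`` subject-eigenvectors of a demeaned feature matrix.

    ``X`` may be a :class:`FeatureMatrix` or a plain demeaned array.  If ``J``
    exceeds the numerical rank (or ``min(N, D)``), the reduction truncates to
    rank with a warning instead of erroring.  Column signs are fixed so each
    column's largest-magnitude element is positive.
    """
    if isinstance(X, FeatureMatrix):
        if not X.is_demeaned:
            raise DegenerateInputError("feature matrix must be demeaned before SVD")
        A = X.X
    else:
        A = np.asarray(X, dtype=float)
    n, d = A.shape
    if J < 1:
        raise ValueError(f"J must be >= 1, got {J}")
    m = min(n, d)
    if J > m:
        warnings.warn(f"J={J} exceeds min(N, D)={m}; truncating", stacklevel=2)
        J = m

    # eigendecomposition of the smaller Gram matrix; top-J eigenpairs only
    if n <= d:
        G = A @ A.T
    else:
        G = A.T @ A
    w, Q = scipy.linalg.eigh(G, subset_by_index=[m - J, m - 1])
    order = np.argsort(w)[::-1]
    w, Q = w[order], Q[:, order]
    s = np.sqrt(np.clip(w, 0.0, None))

    # rank detection happens on the Gram eigenvalues, whose floating-point
    # noise floor is ~eps * w_max — much coarser than for singular values
    keep = w > w[0] * 1e-12 if w[0] > 0 else np.zeros(J, dtype=bool)
    if not keep.all():
        rank = int(keep.sum())
        warnings.warn(f"J={J} exceeds numerical rank {rank}; truncating", stacklevel=2)
        s, Q = s[:rank], Q[:, :rank]
        J = rank
    if J == 0:
        raise DegenerateInputError("feature matrix is numerically zero")

    if n <= d:
        U = Q
        V = (A.T @ U) / s
    else:
        V = Q
        U = (A @ V) / s

    # deterministic sign: largest-|.| element of each U column made positive
    flip = U[np.abs(U).argmax(axis=0), np.arange(J)] < 0
    U[:, flip] *= -1.0
    V[:, flip] *= -1.0
    return SVDReduction(U=U, singular_values=s, J=J, V=V)


def reduce_feature_matrix(X: FeatureMatrix, J: int) -> FeatureMatrix:
    """Convenience: wrap the reduced basis as an orthonormal FeatureMatrix."""
    red = svd_reduce(X, J)
    return FeatureMatrix(X=red.U, is_demeaned=True, is_orthonormal=True)


def sweep_components(X_raw, ages_raw, true_delta, J_values) -> dict[int, float]:
    """Correlation of the corrected delta with a known truth for several ``J``.

    Diagnostic helper for simulated cohorts where the true delta is known.
    The top-``max(J)`` basis is computed once and truncated per ``J`` (the
    leading columns of a larger reduction are exactly the smaller reduction).
    Tuning ``J`` on real data must instead happen inside cross-validation.
    """
    Y = AgeVector.from_raw(ages_raw)
    Xd = FeatureMatrix.from_raw(X_raw)
    true_delta = np.asarray(true_delta, dtype=float)
    J_values = sorted(int(j) for j in J_values)
    red = svd_reduce(Xd, max(J_values))
    out: dict[int, float] = {}
    for J in J_values:
        J_eff = min(J, red.J)
        XJ = FeatureMatrix(X=red.U[:, :J_eff], is_demeaned=True, is_orthonormal=True)
        fit = fit_delta1(XJ, Y)
        _, delta2 = correct_delta2(fit.delta1, Y)
        out[J] = float(np.corrcoef(delta2, true_delta)[0, 1])
    return out
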