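"""Leakage-free k-fold cross-validated delta estimation.

All four trainable stages — confound removal, SVD reduction, the stage-1
age fit, and the stage-2 correction — are learned on training folds only
and applied to the held-out fold: demeaning uses training-fold means,
held-out features are projected onto the training SVD basis, and the
correction slopes come from training-fold (delta1, age) pairs.  At large
sample sizes the results barely differ from an all-in-one fit, but the
out-of-fold deltas are honest when they would not be.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .delta_core import (AgeVector, DeltaFit, DimensionError, FeatureMatrix,
                         PINV_RCOND, _as_vector)
from .reduction import svd_reduce

logger = logging.getLogger("agedelta.crossval")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings.

    The stage flags switch individual training stages off (a disabled
    deconfound/svd/correction stage is simply skipped; the stage-1 fit
    always runs).
    """

    n_folds: int = 10
    seed: int = 0
    deconfound: bool = True
    svd: bool = True
    correction: bool = True


@dataclass
class _QuadTransform:
    """Quadratic age basis learned on a training fold, applicable to any ages."""

    age_mean: float
    q_mean: float
    slope: float  # regression of demeaned age^2 on demeaned age (training fold)

    @classmethod
    def fit(cls, ages_train: np.ndarray) -> "_QuadTransform":
        mean = float(ages_train.mean())
        y = ages_train - mean
        q = y ** 2
        q_mean = float(q.mean())
        qc = q - q_mean
        return cls(age_mean=mean, q_mean=q_mean,
                   slope=float((y @ qc) / (y @ y)))

    def transform(self, ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        y = ages - self.age_mean
        yo2 = y ** 2 - self.q_mean - self.slope * y
        return y, yo2


def assign_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded uniform shuffle then contiguous split; sizes differ by <= 1."""
    if not 2 <= n_folds <= n:
        raise ValueError(f"need 2 <= n_folds <= N, got n_folds={n_folds}, N={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.empty(n, dtype=int)
    for i, chunk in enumerate(np.array_split(perm, n_folds)):
        fold_ids[chunk] = i
    return fold_ids


def crossval_deltas(X_raw, ages_raw, confounds=None, J: int = 0,
                    cfg: Optional[CVConfig] = None) -> DeltaFit:
    """Out-of-fold deltas for every subject.

    ``J=0`` (or ``cfg.svd=False``) disables SVD reduction.  Returns a
    :class:`DeltaFit` whose vectors hold each subject's estimates computed
    with that subject held out, plus ``fold_ids``.
    """
    cfg = cfg or CVConfig()
    X = np.asarray(X_raw, dtype=float)
    ages = _as_vector(ages_raw, "ages")
    n = ages.size
    if X.shape[0] != n:
        raise DimensionError(f"feature matrix has {X.shape[0]} rows but ages has {n}")
    C = None
    if confounds is not None and cfg.deconfound:
        C = np.asarray(confounds, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise DimensionError(
                f"confounds has {C.shape[0]} rows but ages has {n}")
    use_svd = cfg.svd and J > 0

    fold_ids = assign_folds(n, cfg.n_folds, cfg.seed)
    out = DeltaFit(fold_ids=fold_ids)
    out.delta1 = np.empty(n)
    out.delta2 = np.empty(n)
    out.delta2q = np.empty(n)
    out.delta3 = np.empty(n)
    out.delta3q = np.empty(n)
    out.YB1 = np.empty(n)
    out.YB2 = np.empty(n)

    for f in range(cfg.n_folds):
        test = fold_ids == f
        train = ~test
        n_train = int(train.sum())
        model_dim = J if use_svd else X.shape[1]
        if n_train <= model_dim:
            raise ValueError(
                f"training folds have {n_train} subjects but the model needs more "
                f"than {model_dim}; use larger folds (fewer of them) or a smaller J")

        # stage a) confound removal, learned on the training fold
        Xtr = X[train] - X[train].mean(axis=0)
        Xte = X[test] - X[train].mean(axis=0)
        if C is not None:
            c_mean = C[train].mean(axis=0)
            Ctr, Cte = C[train] - c_mean, C[test] - c_mean
            beta_c, *_ = np.linalg.lstsq(Ctr, Xtr, rcond=PINV_RCOND)
            Xtr = Xtr - Ctr @ beta_c
            Xte = Xte - Cte @ beta_c

        # stage b) SVD basis from the training fold; project the test fold
        if use_svd:
            red = svd_reduce(Xtr, J)
            Str, Ste = red.U, red.project(Xte)
        else:
            Str, Ste = Xtr, Xte

        # stage c) initial age fit
        quad = _QuadTransform.fit(ages[train])
        ytr, yo2tr = quad.transform(ages[train])
        yte, yo2te = quad.transform(ages[test])
        beta1, *_ = np.linalg.lstsq(Str, ytr, rcond=PINV_RCOND)
        d1_tr = Str @ beta1 - ytr
        d1_te = Ste @ beta1 - yte
        out.delta1[test] = d1_te
        out.YB1[test] = ages[test] + d1_te

        # stage d) correction slopes from training pairs, applied out of fold
        if cfg.correction:
            b2 = (ytr @ d1_tr) / (ytr @ ytr)
            b2q_quad = (yo2tr @ d1_tr) / (yo2tr @ yo2tr)
            out.delta2[test] = d1_te - yte * b2
            out.delta2q[test] = d1_te - yte * b2 - yo2te * b2q_quad
        else:
            out.delta2[test] = d1_te
            out.delta2q[test] = d1_te
        out.YB2[test] = ages[test] + out.delta2[test]

        # switched-model deltas: project, scale by training k, correct with
        # training slopes
        xty = Str.T @ ytr
        denom = float(xty @ xty)
        k = float(ytr @ ytr) / denom
        p_tr = Str @ xty * k
        p_te = Ste @ xty * k
        b3 = (ytr @ p_tr) / (ytr @ ytr)
        b3q = (yo2tr @ p_tr) / (yo2tr @ yo2tr)
        out.delta3[test] = p_te - yte * b3
        out.delta3q[test] = p_te - yte * b3 - yo2te * b3q
    return out
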