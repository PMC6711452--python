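"""Synthetic cohort generators for validating delta estimators.

The primary generator emulates a large imaging study: ages drawn from a
sharply truncated (hence non-Gaussian) distribution over roughly 45-75
years, an additive Gaussian delta (sd 2 y) forming the true brain age, and
a set of latent population components — the first being brain age, the rest
age-independent noise processes — mixed into thousands of features by a
heavy-tailed (effectively sparse) mixing matrix, with feature-level
measurement noise on top.  Optional switches add a quadratic aging term,
multiplicative (age-dependent) scaling of the delta, and random modulation
of the non-age component strengths.

The second generator strips the cohort down to a single latent component
(brain age) buried in strong noise — an idealised rank-1 world in which the
mass-univariate switched estimator shines and unregularised multiple
regression struggles.

Both generators are fully seeded: the same config and seed reproduce the
cohort bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

from .delta_core import AgeVector, build_quadratic_basis
from .nonadditive import map_age_unit

logger = logging.getLogger("agedelta.simulate")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic cohort.

    Defaults are the primary study conditions: 20000 subjects, 3000
    features mixed from 100 latent components, ages truncated to 45-75 y,
    additive delta sd 2 y, feature measurement noise sd 0.5.
    """

    n_subjects: int = 20000
    n_features: int = 3000
    n_components: int = 100
    age_min: float = 45.0
    age_max: float = 75.0
    delta_sd: float = 2.0          # years
    feature_noise_sd: float = 0.5
    alpha: float = 0.0             # quadratic aging coefficient (y per y^2)
    lambda_true: float = 0.0       # multiplicative aging coefficient
    modulate_strengths: bool = False  # scale non-age components by U(0,1) draws
    age_jitter_sd: float = 1.0     # smoothing of the truncated age distribution
    n_repeats: int = 20
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 3:
            problems.append(f"n_subjects={self.n_subjects} (need >= 3)")
        if self.n_features < 1:
            problems.append(f"n_features={self.n_features} (need >= 1)")
        if not 1 <= self.n_components <= self.n_features:
            problems.append(
                f"n_components={self.n_components} (need 1 <= n_components <= n_features)")
        if not self.age_min < self.age_max:
            problems.append(f"age_min={self.age_min} not below age_max={self.age_max}")
        if self.delta_sd <= 0:
            problems.append(f"delta_sd={self.delta_sd} (need > 0)")
        if self.feature_noise_sd < 0:
            problems.append(f"feature_noise_sd={self.feature_noise_sd} (need >= 0)")
        if self.n_repeats < 1:
            problems.append(f"n_repeats={self.n_repeats} (need >= 1)")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


@dataclass(frozen=True)
class SimulatedCohort:
    """A generated (features, ages, true delta) triple plus diagnostics."""

    X: np.ndarray               # (N, D) features
    ages: np.ndarray            # (N,) years
    true_delta: np.ndarray      # (N,) years
    true_brain_age: np.ndarray  # (N,) ages + quadratic term + true_delta
    quadratic_term: np.ndarray  # (N,) alpha * Yo2
    components: np.ndarray      # (N, K) latent components (first = brain age, z-scored)
    mixing: np.ndarray          # (K, D)
    config: SimulationConfig


def _draw_ages(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Sharply truncated age distribution: uniform convolved with a small
    Gaussian (sd ``age_jitter_sd``) then clipped to the support limits."""
    ages = rng.uniform(cfg.age_min, cfg.age_max, size=cfg.n_subjects)
    if cfg.age_jitter_sd > 0:
        ages = ages + rng.normal(0.0, cfg.age_jitter_sd, size=cfg.n_subjects)
    return np.clip(ages, cfg.age_min, cfg.age_max)


def simulate_cohort(cfg: Optional[SimulationConfig] = None,
                    **overrides) -> SimulatedCohort:
    """Generate the full multi-component cohort.

    Keyword overrides are applied on top of ``cfg`` (or the defaults), e.g.
    ``simulate_cohort(n_subjects=500, seed=7)``.
    """
    cfg = replace(cfg or SimulationConfig(), **overrides)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    ages = _draw_ages(cfg, rng)
    true_delta = rng.normal(0.0, cfg.delta_sd, size=cfg.n_subjects)
    if cfg.lambda_true != 0.0:
        true_delta = true_delta * (1.0 + cfg.lambda_true * map_age_unit(ages))

    # quadratic aging uses the age-orthogonalised squared term so that alpha
    # adds curvature without aliasing the linear age effect
    if cfg.alpha != 0.0:
        Y = AgeVector.from_raw(ages)
        quad = cfg.alpha * build_quadratic_basis(Y).Yo2
    else:
        quad = np.zeros(cfg.n_subjects)
    brain_age = ages + quad + true_delta

    # latent components: unit-strength brain age plus independent noise modes
    components = np.empty((cfg.n_subjects, cfg.n_components))
    ba = brain_age - brain_age.mean()
    components[:, 0] = ba / ba.std(ddof=0)
    if cfg.n_components > 1:
        components[:, 1:] = rng.standard_normal(
            (cfg.n_subjects, cfg.n_components - 1))

    strengths = np.ones(cfg.n_components)
    if cfg.modulate_strengths and cfg.n_components > 1:
        strengths[1:] = rng.uniform(0.0, 1.0, size=cfg.n_components - 1)

    # heavy-tailed, sign-preserving mixing: elementwise fifth power of N(0,1)
    mixing = rng.standard_normal((cfg.n_components, cfg.n_features)) ** 5

    X = (components * strengths) @ mixing
    X -= X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X /= sd
    if cfg.feature_noise_sd > 0:
        X += rng.normal(0.0, cfg.feature_noise_sd, size=X.shape)

    return SimulatedCohort(X=X, ages=ages, true_delta=true_delta,
                           true_brain_age=brain_age, quadratic_term=quad,
                           components=components, mixing=mixing, config=cfg)


#: Fields a caller most often overrides for the rank-1 cohort.
SIM2_DEFAULTS = dict(n_components=1, feature_noise_sd=10.0)


def simulate_sim2(cfg: Optional[SimulationConfig] = None,
                  **overrides) -> SimulatedCohort:
    """Rank-1 cohort: brain age is the only structured component.

    Noise sd defaults to 10 (a much harsher regime than the full cohort);
    any explicit ``feature_noise_sd`` in ``cfg``/overrides wins.
    """
    if cfg is None:
        cfg = SimulationConfig(**SIM2_DEFAULTS)
    else:
        cfg = replace(cfg, n_components=1)
    cfg = replace(cfg, **overrides)
    if cfg.n_components != 1:
        raise ValueError("the rank-1 cohort has exactly one latent component")
    return simulate_cohort(cfg)
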