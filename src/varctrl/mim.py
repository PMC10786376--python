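"""Plausibility-based test of treatment variances against a control variance.

Tests ``H0: sigma_i^2 = sigma_0^2 for all i`` against the tree-ordered
alternative ``H1: sigma_i^2 <= sigma_0^2`` with at least one strict
inequality, for ``k`` treatment groups and one control, all normal.  The
hypothesis is reparameterised through

    theta = min(sigma_1^2, ..., sigma_k^2) / sigma_0^2,

so H0 becomes ``theta = 1`` versus ``theta < 1``.  With ``T`` the observed
control-to-minimum sample-variance ratio ``S0^2 / min_i S_i^2`` and ``F``
the data-free null distribution from :mod:`varctrl.ratiodist`, the
plausibility of ``{theta}`` is ``1 - F(T * theta)``; H0 is rejected at level
``alpha`` when the plausibility at ``theta = 1`` is <= ``alpha``, and
``{theta : pl(theta) > alpha}`` is a one-sided confidence region whose upper
limit is ``F^{-1}(1 - alpha) / T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ratiodist import DfVector, RatioDistribution

__all__ = [
    "GroupSummary",
    "StudySummary",
    "TestResult",
    "PlausibilityCurve",
    "observed_statistic",
    "mim_plausibility",
    "mim_test",
    "plausibility_curve",
    "default_theta_grid",
    "mim_upper_bound",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size and sample variance (divisor ``n - 1``) of one group."""

    label: str
    n: int
    s2: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"group {self.label!r}: sample size must be an integer >= 2, got {self.n}")
        if not math.isfinite(self.s2) or self.s2 < 0:
            raise ValueError(f"group {self.label!r}: sample variance must be finite and >= 0, got {self.s2}")


@dataclass(frozen=True)
class StudySummary:
    """One control group plus ``k >= 1`` treatment groups."""

    control: GroupSummary
    treatments: tuple[GroupSummary, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(self.treatments))
        if len(self.treatments) < 1:
            raise ValueError("at least one treatment group is required")
        labels = [self.control.label] + [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ValueError(f"group labels must be unique, got {labels}")

    @property
    def k(self) -> int:
        return len(self.treatments)

    @property
    def sizes(self) -> tuple[int, ...]:
        """Group sample sizes, control first."""
        return (self.control.n,) + tuple(t.n for t in self.treatments)

    def df_vector(self) -> DfVector:
        return DfVector.from_sizes(self.sizes)

    def _require_positive_variances(self) -> None:
        for g in (self.control, *self.treatments):
            if g.s2 <= 0:
                raise ValueError(
                    f"group {g.label!r} has zero sample variance; the normal "
                    "scale model is degenerate and no inference is possible"
                )


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    plausibility: float
    alpha: float
    reject: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.plausibility <= 1.0:
            raise ValueError(f"plausibility must lie in [0, 1], got {self.plausibility}")
        if self.reject != (self.plausibility <= self.alpha):
            raise ValueError("decision inconsistent with plausibility and alpha")


@dataclass(frozen=True)
class PlausibilityCurve:
    """Plausibility evaluated on a grid of variance-ratio values theta."""

    thetas: np.ndarray
    pl_values: np.ndarray

    def __post_init__(self) -> None:
        thetas = np.asarray(self.thetas, dtype=float)
        pl = np.asarray(self.pl_values, dtype=float)
        object.__setattr__(self, "thetas", thetas)
        object.__setattr__(self, "pl_values", pl)
        if thetas.shape != pl.shape or thetas.ndim != 1:
            raise ValueError("thetas and pl_values must be 1-d arrays of equal length")
        if np.any(np.diff(pl) > 1e-9):
            raise ValueError("plausibility must be nonincreasing along the theta grid")


def observed_statistic(study: StudySummary) -> float:
    """Control-to-minimum variance ratio ``T = S0^2 / min_i S_i^2``."""
    study._require_positive_variances()
    return study.control.s2 / min(t.s2 for t in study.treatments)


def mim_plausibility(
    study: StudySummary,
    theta: float = 1.0,
    *,
    dist: RatioDistribution | None = None,
) -> float:
    """Plausibility ``1 - F(T * theta)`` of the point ``{theta}``.

    At ``theta = 1`` this is the evidence against variance homogeneity; small
    values favour the alternative that some treatment variance is below the
    control's.  Pass ``dist`` to reuse a prepared null distribution.
    """
    theta = float(theta)
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    t_obs = observed_statistic(study)
    if dist is None:
        dist = RatioDistribution(study.df_vector())
    return 1.0 - dist.cdf(t_obs * theta)


def mim_test(study: StudySummary, alpha: float = 0.05) -> TestResult:
    """Level-``alpha`` decision: reject H0 when the plausibility is <= alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    pl = mim_plausibility(study, 1.0)
    return TestResult(
        method="MIM",
        statistic=observed_statistic(study),
        plausibility=pl,
        alpha=float(alpha),
        reject=pl <= alpha,
    )


def default_theta_grid(study: StudySummary, n_points: int = 400) -> np.ndarray:
    """Log-spaced grid covering plausibilities from ~0.999 down to ~0.001."""
    dist = RatioDistribution(study.df_vector())
    t_obs = observed_statistic(study)
    lo = dist.ppf(0.001) / t_obs
    hi = dist.ppf(0.999) / t_obs
    return np.geomspace(lo, hi, int(n_points))


def plausibility_curve(
    study: StudySummary,
    theta_grid: Sequence[float] | np.ndarray | None = None,
) -> PlausibilityCurve:
    """Plausibility along a strictly increasing positive grid of theta."""
    if theta_grid is None:
        theta_grid = default_theta_grid(study)
    thetas = np.asarray(theta_grid, dtype=float)
    if thetas.size == 0:
        raise ValueError("theta grid must be non-empty")
    if np.any(thetas <= 0) or np.any(np.diff(thetas) <= 0):
        raise ValueError("theta grid must be strictly increasing and positive")
    t_obs = observed_statistic(study)
    dist = RatioDistribution(study.df_vector())
    pl = 1.0 - dist.cdf_many(t_obs * thetas)
    # clamp tiny quadrature wiggle so the monotone invariant holds exactly
    pl = np.minimum.accumulate(pl)
    return PlausibilityCurve(thetas=thetas, pl_values=pl)


def mim_upper_bound(study: StudySummary, alpha: float = 0.05) -> float:
    """Upper limit of the one-sided 100(1-alpha)% confidence region for theta.

    Returns ``F^{-1}(1 - alpha) / T``, the supremum of
    ``{theta : pl(theta) > alpha}``; by duality the bound is below 1 exactly
    when the level-``alpha`` test rejects.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    t_obs = observed_statistic(study)
    dist = RatioDistribution(study.df_vector())
    return dist.ppf(1.0 - alpha) / t_obs
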