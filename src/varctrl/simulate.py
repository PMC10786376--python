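"""Synthetic normal studies and Monte-Carlo rejection-rate experiments.

A :class:`SimulationSpec` describes one scenario (group sizes, variances,
optional means, replicate count, level, seed, methods).  :func:`run_study`
estimates type-I-error / power by repeated sampling; within one scenario the
null ratio distribution is set up once, so the per-replicate cost is a single
batched CDF evaluation for the plausibility test and a comparison against a
precomputed critical constant for Spurrier's test.

Per-replicate randomness is derived from ``(seed, rep_index)`` through
``numpy.random.default_rng([seed, rep_index])``, so replicates are
order-independent and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .mim import GroupSummary, StudySummary
from .ratiodist import DfVector, RatioDistribution
from .spurrier import spurrier_critical_ratio

__all__ = [
    "SimulationSpec",
    "SimulationResult",
    "PlNullDistribution",
    "generate_study",
    "run_study",
    "pl_null_distribution",
    "load_scenarios",
    "run_scenarios",
]

METHODS = ("MIM", "Spurrier")


@dataclass(frozen=True)
class SimulationSpec:
    """One Monte-Carlo scenario; all per-group vectors are control-first."""

    sizes: tuple[int, ...]
    variances: tuple[float, ...]
    means: tuple[float, ...] | None = None
    reps: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    methods: tuple[str, ...] = ("MIM",)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(int(n) for n in self.sizes))
        object.__setattr__(self, "variances", tuple(float(v) for v in self.variances))
        if len(self.sizes) < 2:
            raise ValueError("need a control group and at least one treatment group")
        if any(n < 2 for n in self.sizes):
            raise ValueError(f"every group size must be >= 2, got {self.sizes}")
        if len(self.variances) != len(self.sizes):
            raise ValueError("variances must have one entry per group")
        if any(not math.isfinite(v) or v <= 0 for v in self.variances):
            raise ValueError(f"variances must be positive and finite, got {self.variances}")
        if self.means is None:
            object.__setattr__(self, "means", (0.0,) * len(self.sizes))
        else:
            object.__setattr__(self, "means", tuple(float(m) for m in self.means))
        if len(self.means) != len(self.sizes):
            raise ValueError("means must have one entry per group")
        if int(self.reps) < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        object.__setattr__(self, "reps", int(self.reps))
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if int(self.seed) < 0:
            raise ValueError("seed must be a nonnegative integer")
        object.__setattr__(self, "seed", int(self.seed))
        norm = tuple(self._canonical_method(m) for m in self.methods)
        if not norm:
            raise ValueError("at least one method must be requested")
        object.__setattr__(self, "methods", norm)
        if "Spurrier" in norm and len(set(self.sizes[1:])) != 1:
            raise ValueError(
                "Spurrier's test requires equal treatment sample sizes; "
                f"got {self.sizes[1:]} (request only MIM for this scenario)"
            )

    @staticmethod
    def _canonical_method(name: str) -> str:
        for m in METHODS:
            if name.lower() == m.lower():
                return m
        raise ValueError(f"unknown method {name!r}; choose from {METHODS}")

    @property
    def k(self) -> int:
        return len(self.sizes) - 1

    def df_vector(self) -> DfVector:
        return DfVector.from_sizes(self.sizes)


@dataclass(frozen=True)
class SimulationResult:
    """Estimated rejection rates with binomial Monte-Carlo standard errors."""

    rejection_rate: Mapping[str, float]
    mc_stderr: Mapping[str, float]
    reps_used: int
    spec: SimulationSpec


@dataclass(frozen=True)
class PlNullDistribution:
    """Null plausibility sample with a Kolmogorov-Smirnov uniformity check."""

    pl_values: np.ndarray
    ks_statistic: float | None
    ks_pvalue: float | None


def _rep_rng(seed: int, rep_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, int(rep_index)])


def generate_study(
    spec: SimulationSpec, rep_index: int
) -> tuple[StudySummary, dict[str, np.ndarray]]:
    """Draw one replicate study: independent normal samples per group.

    Returns the variance summary plus the raw samples keyed by group label
    (``control``, ``treatment1``, ...).  Deterministic in
    ``(spec.seed, rep_index)``.
    """
    rng = _rep_rng(spec.seed, rep_index)
    samples: dict[str, np.ndarray] = {}
    groups: list[GroupSummary] = []
    for i, (n, var, mu) in enumerate(zip(spec.sizes, spec.variances, spec.means)):
        label = "control" if i == 0 else f"treatment{i}"
        x = rng.normal(mu, math.sqrt(var), n)
        samples[label] = x
        groups.append(GroupSummary(label=label, n=n, s2=float(np.var(x, ddof=1))))
    return StudySummary(control=groups[0], treatments=tuple(groups[1:])), samples


def _statistics(spec: SimulationSpec) -> np.ndarray:
    """Observed control-to-minimum variance ratios, one per replicate."""
    t = np.empty(spec.reps)
    for r in range(spec.reps):
        study, _ = generate_study(spec, r)
        t[r] = study.control.s2 / min(g.s2 for g in study.treatments)
    return t


def run_study(spec: SimulationSpec) -> SimulationResult:
    """Estimate the rejection rate of each requested method at ``spec.alpha``."""
    t_obs = _statistics(spec)
    rates: dict[str, float] = {}
    stderr: dict[str, float] = {}
    if "MIM" in spec.methods:
        dist = RatioDistribution(spec.df_vector())
        pl = 1.0 - dist.cdf_many(t_obs)
        rates["MIM"] = float(np.mean(pl <= spec.alpha))
    if "Spurrier" in spec.methods:
        n0 = spec.sizes[0]
        m = spec.sizes[1]
        c_crit = spurrier_critical_ratio(n0, m, spec.k, spec.alpha)
        rates["Spurrier"] = float(np.mean(1.0 / t_obs <= c_crit))
    for name, r in rates.items():
        stderr[name] = math.sqrt(r * (1.0 - r) / spec.reps)
    return SimulationResult(
        rejection_rate=rates, mc_stderr=stderr, reps_used=spec.reps, spec=spec
    )


def pl_null_distribution(spec: SimulationSpec) -> PlNullDistribution:
    """Sample the null distribution of the plausibility at ``theta = 1``.

    Only meaningful under the null, so the spec must have all variances
    equal.  With more than one replicate a one-sample Kolmogorov-Smirnov
    statistic against Unif(0, 1) is attached.
    """
    if len(set(spec.variances)) != 1:
        raise ValueError(
            "the uniformity diagnostic requires a null configuration "
            f"(all variances equal); got {spec.variances}"
        )
    t_obs = _statistics(spec)
    dist = RatioDistribution(spec.df_vector())
    pl = 1.0 - dist.cdf_many(t_obs)
    if spec.reps > 1:
        ks = stats.kstest(pl, "uniform")
        return PlNullDistribution(pl, float(ks.statistic), float(ks.pvalue))
    return PlNullDistribution(pl, None, None)


# -- scenario files ----------------------------------------------------------

def load_scenarios(path: str) -> list[SimulationSpec]:
    """Read scenarios from a YAML file.

    Layout: optional top-level defaults (``reps``, ``alpha``, ``seed``,
    ``methods``) and a ``scenarios`` list whose entries give ``sizes`` and
    ``variances`` (control first) plus any per-scenario overrides.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "scenarios" not in doc:
        raise ValueError(f"{path}: expected a mapping with a 'scenarios' list")
    defaults = {k: v for k, v in doc.items() if k != "scenarios"}
    specs = []
    for i, entry in enumerate(doc["scenarios"]):
        if not isinstance(entry, dict):
            raise ValueError(f"{path}: scenario {i} is not a mapping")
        merged = {**defaults, **entry}
        if "methods" in merged:
            merged["methods"] = tuple(merged["methods"])
        try:
            specs.append(SimulationSpec(**merged))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: scenario {i}: {exc}") from exc
    return specs


def run_scenarios(specs: Iterable[SimulationSpec]) -> pd.DataFrame:
    """Run every scenario; one row per scenario, rate/stderr columns per method."""
    rows = []
    for spec in specs:
        res = run_study(spec)
        row: dict[str, object] = {
            "sizes": ",".join(map(str, spec.sizes)),
            "variances": ",".join(f"{v:g}" for v in spec.variances),
            "reps": spec.reps,
            "alpha": spec.alpha,
            "seed": spec.seed,
        }
        for m in METHODS:
            if m in res.rejection_rate:
                row[f"{m.lower()}_rate"] = res.rejection_rate[m]
                row[f"{m.lower()}_stderr"] = res.mc_stderr[m]
        rows.append(row)
    return pd.DataFrame(rows)
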