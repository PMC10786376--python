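"""Spurrier's exact test for the equal-treatment-sample-size design.

With ``k`` treatment groups of common size ``m`` and a control of size ``n``,
the vector ``F_i = (S_i^2/sigma_i^2) / (S_0^2/sigma_0^2)`` follows a
multivariate F distribution, and the lower one-sided p-value is

    p = P(min_i F_i <= c)
      = 1 - \\int_0^inf [1 - H(x c (m-1)/(n-1))]^k g(x) dx,

where ``c = min_i s_i^2 / s_0^2`` is the observed minimum variance ratio,
``H`` the chi-square(m-1) distribution function and ``g`` the chi-square(n-1)
density.  The integral is evaluated by adaptive quadrature to ~1e-8.

The test is undefined when the treatment sample sizes differ; callers are
directed to the plausibility test in :mod:`varctrl.mim`, which has no such
restriction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from .mim import StudySummary, TestResult, observed_statistic

__all__ = [
    "UnequalSampleSizesError",
    "SpurrierInput",
    "spurrier_pvalue",
    "spurrier_critical_ratio",
    "spurrier_from_study",
]

_SPLIT_QUANTILES = (0.005, 0.1, 0.5, 0.9, 0.995)


class UnequalSampleSizesError(ValueError):
    """Raised when Spurrier's test is requested for an unsupported design."""


@dataclass(frozen=True)
class SpurrierInput:
    """Summary of an equal-treatment-size study.

    Fields: control size ``n``, common treatment size ``m``, number of
    treatment groups ``k``, and the observed statistic
    ``c = min_i s_i^2 / s_0^2``.
    """

    n: int
    m: int
    k: int
    c: float

    def __post_init__(self) -> None:
        if self.n < 2 or self.m < 2:
            raise ValueError(f"sample sizes must be >= 2, got n={self.n}, m={self.m}")
        if self.k < 1:
            raise ValueError(f"need at least one treatment group, got k={self.k}")
        if not math.isfinite(self.c) or self.c <= 0:
            raise ValueError(f"observed minimum variance ratio must be positive, got c={self.c}")


def _integrand(x: float, inp: SpurrierInput) -> float:
    scale = inp.c * (inp.m - 1) / (inp.n - 1)
    return stats.chi2.sf(x * scale, inp.m - 1) ** inp.k * stats.chi2.pdf(x, inp.n - 1)


def spurrier_pvalue(inp: SpurrierInput, *, epsabs: float = 1e-10) -> float:
    """Exact lower one-sided p-value ``P(min_i F_i <= c)``."""
    d0 = inp.n - 1
    splits = [stats.chi2.ppf(q, d0) for q in _SPLIT_QUANTILES]
    total, err, lo = 0.0, 0.0, 0.0
    for hi in splits:
        val, e = integrate.quad(_integrand, lo, hi, args=(inp,), epsabs=epsabs, limit=200)
        total += val
        err += e
        lo = hi
    val, e = integrate.quad(_integrand, lo, np.inf, args=(inp,), epsabs=epsabs, limit=200)
    total += val
    err += e
    if err > 1e-6:
        raise RuntimeError(f"quadrature did not converge for {inp}: estimated error {err:.3e}")
    return float(min(max(1.0 - total, 0.0), 1.0))


def spurrier_critical_ratio(n: int, m: int, k: int, alpha: float) -> float:
    """Critical constant ``c_alpha`` with ``p(c_alpha) = alpha``.

    The test rejects exactly when the observed ``c`` is <= this value; useful
    in simulations where thousands of replicates share one design.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    # k = 1 reduces to the one-sided F test, whose critical value brackets
    # the k > 1 root from above (the minimum only gets smaller)
    hi = stats.f.ppf(alpha, m - 1, n - 1) * 1.001
    lo = stats.f.ppf(alpha / (10.0 * k), m - 1, n - 1)
    f = lambda c: spurrier_pvalue(SpurrierInput(n=n, m=m, k=k, c=c)) - alpha
    for _ in range(100):
        if f(lo) <= 0:
            break
        lo /= 4.0
    for _ in range(100):
        if f(hi) >= 0:
            break
        hi *= 2.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-13))


def spurrier_from_study(study: StudySummary, alpha: float = 0.05) -> TestResult:
    """Run Spurrier's test on a study summary (equal treatment sizes only)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    sizes = {t.n for t in study.treatments}
    if len(sizes) != 1:
        raise UnequalSampleSizesError(
            "Spurrier's test requires equal sample sizes among the treatment "
            f"groups, but got sizes {[t.n for t in study.treatments]}; "
            "use the MIM test, which supports unequal sizes"
        )
    t_obs = observed_statistic(study)
    inp = SpurrierInput(
        n=study.control.n,
        m=sizes.pop(),
        k=study.k,
        c=1.0 / t_obs,
    )
    p = spurrier_pvalue(inp)
    return TestResult(
        method="Spurrier",
        statistic=t_obs,
        plausibility=p,
        alpha=float(alpha),
        reject=p <= alpha,
    )
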