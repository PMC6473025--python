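"""Maximal-lifespan (MLS) estimators and lifespan-extension statistics.

"Maximal lifespan" here is the mean lifespan of the longest-lived 10% of a
cohort — not the single oldest animal.  Three estimators are provided:

* :func:`mls_direct` — the arithmetic mean of the top decile of observed
  death ages (k = max(1, floor(fraction*n)) animals).
* :func:`mls_model_tail` — the conditional mean age over [t10, inf) of a
  fitted Gompertz curve, with the survival function itself as the integral
  weight: value = int t*f(t) dt / int f(t) dt, where t10 is the age at which
  10% of the model population remains.
* :func:`combine_weighted` — an inverse-uncertainty weighted average of the
  two, (d2*v1 + d1*v2)/(d1 + d2): the estimate with the smaller half-width
  gets the larger weight.

Uncertainties: :func:`student_ci` gives the standard Student-t half-width at
P = 0.05.  Published half-widths for this kind of estimate are sometimes
obtained by other (unstated) means; an :class:`MLSEstimate` therefore tags
where its ``delta`` came from (``student``, ``printed``, ``heuristic`` or
``none``) so recorded and computed uncertainties are never conflated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats

from .gompertz import GompertzParams, quantile_time, survival_fraction

__all__ = [
    "MLSEstimate",
    "mls_direct",
    "mls_model_tail",
    "combine_weighted",
    "student_ci",
    "extension_percent",
    "survival_fold",
]


@dataclass(frozen=True)
class MLSEstimate:
    """An MLS value (months) with half-width delta, tail count and method tag."""

    value: float
    delta: float | None
    n_tail: int
    method: str  # direct | model_tail | combined
    delta_source: str = "student"  # student | printed | heuristic | none

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("MLS value must be > 0")
        if self.delta is not None and self.delta < 0:
            raise ValueError("delta must be >= 0")

    def with_delta(self, delta: float, source: str = "printed") -> "MLSEstimate":
        return MLSEstimate(self.value, delta, self.n_tail, self.method, source)


def student_ci(ages, alpha: float = 0.05) -> float:
    """Student-t confidence half-width t_{n-1,1-a/2} * s / sqrt(n)."""
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    if n < 2:
        raise ValueError("CI undefined for fewer than 2 observations")
    s = ages.std(ddof=1)
    return float(stats.t.ppf(1 - alpha / 2, n - 1) * s / math.sqrt(n))


def mls_direct(
    death_ages,
    n_cohort: int | None = None,
    fraction: float = 0.1,
) -> MLSEstimate:
    """Mean lifespan of the top ``fraction`` of a cohort, from observed ages.

    ``death_ages`` may be the full set of death ages or just the tail, as
    long as it contains the top k = max(1, floor(fraction*n_cohort)) ages;
    ``n_cohort`` defaults to len(death_ages).
    """
    ages = np.sort(np.asarray(death_ages, dtype=float))
    if ages.size == 0:
        raise ValueError("no death ages supplied")
    n = int(n_cohort) if n_cohort is not None else ages.size
    if n < 10:
        warnings.warn(
            f"top-decile estimate from a cohort of only {n} animals", stacklevel=2
        )
    k = max(1, math.floor(fraction * n))
    if k > ages.size:
        raise ValueError(f"need the top {k} ages but only {ages.size} supplied")
    tail = ages[-k:]
    delta = student_ci(tail) if k >= 2 else None
    return MLSEstimate(
        value=float(tail.mean()),
        delta=delta,
        n_tail=k,
        method="direct",
        delta_source="student" if k >= 2 else "none",
    )


def mls_model_tail(params: GompertzParams, fraction: float = 0.1) -> MLSEstimate:
    """Conditional mean age over [t10, inf) of the Gompertz survival curve.

    value = int_{t10}^{inf} t*f(t) dt / int_{t10}^{inf} f(t) dt with f the
    survival fraction and t10 the age where ``fraction`` of the population
    remains.  Adaptive quadrature at relative tolerance 1e-8; the upper
    limit is truncated where f drops below 1e-12.  Always exceeds t10.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    t_lo = quantile_time(params, fraction)
    t_hi = quantile_time(params, 1e-12)

    def f(t):
        return survival_fraction(params, t)

    num, num_err = integrate.quad(lambda t: t * f(t), t_lo, t_hi, epsrel=1e-10, limit=200)
    den, den_err = integrate.quad(f, t_lo, t_hi, epsrel=1e-10, limit=200)
    if den <= 0 or num_err > 1e-8 * abs(num) + 1e-12 or den_err > 1e-8 * abs(den) + 1e-12:
        raise RuntimeError(
            f"tail quadrature failed: residuals {num_err:.3g}, {den_err:.3g}"
        )
    return MLSEstimate(
        value=float(num / den), delta=None, n_tail=0, method="model_tail", delta_source="none"
    )


def combine_weighted(e1: MLSEstimate, e2: MLSEstimate) -> MLSEstimate:
    """Inverse-uncertainty weighted combination (d2*v1 + d1*v2)/(d1 + d2).

    A convex combination of the two values; the estimate with the smaller
    half-width receives the larger weight.  No published rule exists for the
    combined half-width, so it is propagated as min(d1, d2) and flagged
    ``heuristic``; callers comparing against a recorded value should
    override it via :meth:`MLSEstimate.with_delta`.
    """
    d1, d2 = e1.delta, e2.delta
    if d1 is None or d2 is None:
        raise ValueError("both estimates need a delta to combine")
    if d1 == 0 and d2 == 0:
        if e1.value != e2.value:
            raise ValueError("both deltas zero with unequal values: weights undefined")
        value = e1.value
    else:
        value = (d2 * e1.value + d1 * e2.value) / (d1 + d2)
    return MLSEstimate(
        value=float(value),
        delta=float(min(d1, d2)),
        n_tail=e1.n_tail + e2.n_tail,
        method="combined",
        delta_source="heuristic",
    )


def extension_percent(mls_exp: float, mls_ctrl: float) -> float:
    """Relative MLS increase, 100*(exp - ctrl)/ctrl, in percent."""
    if not mls_ctrl > 0:
        raise ValueError("control MLS must be > 0")
    return 100.0 * (mls_exp - mls_ctrl) / mls_ctrl


def survival_fold(mls_exp: float, mls_ctrl: float, t0: float) -> float:
    """Fold change in survival time past the intervention age t0."""
    if mls_ctrl <= t0:
        raise ValueError("fold undefined: control MLS does not exceed t0")
    if mls_exp <= t0:
        raise ValueError("fold undefined: experimental MLS does not exceed t0")
    return (mls_exp - t0) / (mls_ctrl - t0)
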