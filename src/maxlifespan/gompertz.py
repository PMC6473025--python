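"""The Gompertz mortality law: survival, quantiles, fitting, sampling.

The hazard is log-linear in age, h(t) = exp(mu0 + mu1*t), with mu0 the log
baseline hazard (per month) and mu1 > 0 the slope (1/month).  Two
normalizations of the survival curve are supported:

``proper``
    S(t) = exp(-(e^(mu0 + mu1*t) - e^(mu0)) / mu1), the exact survival
    function of the hazard above; S(0) = 1 identically.  Default.
``paper_literal``
    S(t) = exp(-e^(mu0 + mu1*t) / mu1), the bare exponential shape as it is
    often printed with the normalization constant folded into the 100% unit.
    It misses S(0) = 1 by exactly e^(mu0)/mu1 in log-survival (about 1.6e-5
    in the reference regime mu0 = -11.4, mu1 = 0.7) — numerically
    indistinguishable for cohort work, kept for exact comparability with
    printed curves.

Time is months everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import optimize

from .cohort import StepCurve

__all__ = [
    "GompertzParams",
    "survival_fraction",
    "hazard",
    "quantile_time",
    "fit_least_squares",
    "sample_lifespans",
]

_NORMALIZATIONS = ("proper", "paper_literal")


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the Gompertz law: log baseline hazard and slope."""

    mu0: float
    mu1: float
    normalization: str = "proper"

    def __post_init__(self) -> None:
        if not self.mu1 > 0:
            raise ValueError(f"mu1 must be > 0, got {self.mu1}")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {_NORMALIZATIONS}, got {self.normalization!r}"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"mu0": self.mu0, "mu1": self.mu1, "normalization": self.normalization}
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "GompertzParams":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        d = json.loads(text)
        return cls(mu0=d["mu0"], mu1=d["mu1"], normalization=d.get("normalization", "proper"))


def hazard(params: GompertzParams, t) -> np.ndarray | float:
    """Instantaneous mortality rate exp(mu0 + mu1*t), per month."""
    t = np.asarray(t, dtype=float)
    out = np.exp(params.mu0 + params.mu1 * t)
    return out if out.ndim else float(out)


def survival_fraction(params: GompertzParams, t) -> np.ndarray | float:
    """Fraction surviving to age ``t`` months, in (0, 1]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be >= 0")
    with np.errstate(over="ignore"):
        cum = np.exp(params.mu0 + params.mu1 * t) / params.mu1
        if params.normalization == "proper":
            cum = cum - np.exp(params.mu0) / params.mu1
        out = np.exp(-cum)
    return out if out.ndim else float(out)


def quantile_time(params: GompertzParams, q) -> np.ndarray | float:
    """Age at which the surviving fraction equals ``q`` (inverse of survival).

    Closed form; under ``proper`` normalization
    t = (ln(e^mu0 - mu1*ln q) - mu0)/mu1, with t -> 0 as q -> 1.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q must lie in (0, 1)")
    arg = -params.mu1 * np.log(q)
    if params.normalization == "proper":
        arg = arg + np.exp(params.mu0)
    else:
        ceiling = np.exp(-np.exp(params.mu0) / params.mu1)
        if np.any(q >= ceiling):
            raise ValueError(
                "q exceeds the paper_literal curve's value at age 0 "
                f"({ceiling:.8f}); no nonnegative solution"
            )
    out = (np.log(arg) - params.mu0) / params.mu1
    return out if out.ndim else float(out)


def _fit_targets(curve: StepCurve) -> tuple[np.ndarray, np.ndarray]:
    # evaluation points: the step's lower value just after each death age
    return curve.ages, curve.fractions


def fit_least_squares(
    curve: StepCurve,
    normalization: str = "proper",
    mu0_grid: np.ndarray | None = None,
    mu1_grid: np.ndarray | None = None,
) -> GompertzParams:
    """Least-squares Gompertz fit to an empirical survival step curve.

    Minimizes the sum of squared deviations between the model survival
    fraction and the empirical fraction immediately after each distinct
    death age.  Deterministic multistart: a fixed grid of starting points
    (mu0 in [-20, -5], mu1 in [0.1, 2] by default), each refined by
    trust-region least squares; the best local optimum wins.
    """
    t, frac = _fit_targets(curve)
    if t.size < 3:
        raise ValueError("need at least 3 distinct death ages to fit")
    if mu0_grid is None:
        mu0_grid = np.linspace(-20.0, -5.0, 5)
    if mu1_grid is None:
        mu1_grid = np.geomspace(0.1, 2.0, 5)

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = GompertzParams(theta[0], theta[1], normalization=normalization)
        return survival_fraction(p, t) - frac

    best = None
    for m0 in mu0_grid:
        for m1 in mu1_grid:
            sol = optimize.least_squares(
                residuals,
                x0=[m0, m1],
                bounds=([-40.0, 1e-8], [5.0, 20.0]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        resid = float("nan") if best is None else 2 * best.cost
        raise RuntimeError(f"Gompertz fit failed to converge; best residual {resid}")
    return GompertzParams(float(best.x[0]), float(best.x[1]), normalization=normalization)


def sample_lifespans(params: GompertzParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` lifespans by inverse-CDF sampling of the Gompertz law.

    Always inverts the proper normalization (the exact distribution of the
    log-linear hazard); ``seed`` may be an int or a numpy Generator.
    Reproducible: a fixed seed yields identical draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    proper = replace(params, normalization="proper")
    return np.asarray(quantile_time(proper, u), dtype=float)
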