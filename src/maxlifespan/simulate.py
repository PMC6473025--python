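"""Forward simulation of a complete lifespan-intervention study.

Generates everything the analysis pipeline consumes — lifespans for a
control and an experimental arm, per-injection embolic deaths, scheduled
sacrifices, and binomial per-image GFP counts — with the statistical
structure the estimators assume, so every stage is testable without the
original animal data.

The treatment is modelled as a change of Gompertz parameters after the
intervention age: experimental animals follow the control law up to T0 and,
if they survive it, a (typically milder) treated law conditional on having
reached T0 (piecewise-hazard construction).  This is a minimal forward
model, not a biological claim about mechanism.

All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chimerism import ChimerismImage, ChimerismSample
from .cohort import Cohort, Event, Group, LifeRecord, StepCurve, empirical_survival
from .gompertz import GompertzParams, fit_least_squares, sample_lifespans, survival_fraction, quantile_time

__all__ = ["StudyDesign", "simulate_study", "parameter_recovery_experiment", "RecoveryResult"]

DAYS_PER_MONTH = 30.44


@dataclass(frozen=True)
class StudyDesign:
    """Design of a synthetic study.  Defaults emulate the reference study:

    20 control and 56 experimental animals; control mortality (mu0=-11.4,
    mu1=0.7 per month); intervention at 15 months; 6 injections at uniform
    10-20 day intervals with a 0.06 embolic risk each (9 deaths in ~150
    injections); 5 animals sacrificed at 21 months (when chimerism was
    assayed); true chimerism 0.28 read out through a 0.25 donor-positive
    fraction over 15 images of ~1000 nucleated cells.
    """

    n_control: int = 20
    n_experimental: int = 56
    control_params: GompertzParams = GompertzParams(-11.4, 0.7)
    treated_params: GompertzParams = GompertzParams(-15.3, 0.7)
    t_intervention: float = 15.0
    n_injections: int = 6
    injection_interval_days: tuple[float, float] = (10.0, 20.0)
    embolic_prob_per_injection: float = 0.06
    sacrifice_schedule: tuple[tuple[float, int], ...] = ((21.0, 5),)
    chimerism_truth: float = 0.28
    donor_positive_fraction: float = 0.25
    n_chimerism_samples: int = 5
    images_per_sample: int = 15
    cells_per_image: int = 1000
    age_weighted_embolism: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_experimental < 0:
            raise ValueError("group sizes must be >= 0")
        for name in ("embolic_prob_per_injection", "chimerism_truth"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.donor_positive_fraction <= 1:
            raise ValueError("donor_positive_fraction must lie in (0, 1]")
        lo, hi = self.injection_interval_days
        if not 0 <= lo <= hi:
            raise ValueError("injection_interval_days must be an ordered nonnegative range")
        for age, count in self.sacrifice_schedule:
            if age < self.t_intervention or count < 0:
                raise ValueError("sacrifice ages must be >= t_intervention, counts >= 0")


def _injection_ages(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    """First injection at T0, later ones at uniform draws from the stated interval."""
    if design.n_injections == 0:
        return np.empty(0)
    lo, hi = design.injection_interval_days
    gaps = rng.uniform(lo, hi, size=design.n_injections - 1) / DAYS_PER_MONTH
    return design.t_intervention + np.concatenate([[0.0], np.cumsum(gaps)])


def _conditional_treated_lifespans(
    design: StudyDesign, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Treated-law lifespans conditional on survival to the intervention age."""
    p = replace(design.treated_params, normalization="proper")
    s0 = survival_fraction(p, design.t_intervention)
    u = rng.uniform(size=n)
    return np.asarray(quantile_time(p, u * s0), dtype=float)


def simulate_study(design: StudyDesign) -> tuple[Cohort, list[ChimerismSample]]:
    """Simulate one full study; reproducible under the design's seed.

    Returns the raw cohort (before the mortality policy: embolic and
    sacrificed events still labelled as such) and the chimerism count
    samples.  Every animal carries exactly one terminal event.
    """
    rng = np.random.default_rng(design.seed)

    records: list[LifeRecord] = []
    for i, age in enumerate(sample_lifespans(design.control_params, max(design.n_control, 1), rng)[: design.n_control]):
        records.append(LifeRecord(f"c{i + 1:03d}", Group.CONTROL, round(float(age), 3), Event.NATURAL))

    # experimental arm: control law to T0, treated law after
    n_exp = design.n_experimental
    base = sample_lifespans(design.control_params, max(n_exp, 1), rng)[:n_exp]
    death_age = np.where(
        base < design.t_intervention,
        base,
        _conditional_treated_lifespans(design, n_exp, rng),
    )
    event = np.full(n_exp, "natural", dtype=object)

    # per-injection embolic risk for animals alive on the injection day
    inj_ages = _injection_ages(design, rng)
    risk = np.full(n_exp, design.embolic_prob_per_injection)
    if design.age_weighted_embolism and n_exp > 1:
        # frailer (shorter latent lifespan) animals carry up to twice the risk
        rank = np.argsort(np.argsort(death_age)) / (n_exp - 1)
        risk = np.clip(risk * 2.0 * (1.0 - rank), 0.0, 1.0)
    for a in inj_ages:
        alive = (death_age > a) & (event == "natural")
        hit = alive & (rng.uniform(size=n_exp) < risk)
        death_age[hit] = a
        event[hit] = "embolic"

    # scheduled sacrifices among animals still alive
    for age, count in design.sacrifice_schedule:
        candidates = np.flatnonzero((death_age > age) & (event == "natural"))
        if candidates.size < count:
            raise ValueError(
                f"infeasible sacrifice: {count} requested at {age} months, "
                f"only {candidates.size} alive"
            )
        chosen = rng.choice(candidates, size=count, replace=False)
        death_age[chosen] = age
        event[chosen] = "sacrificed"

    for i in range(n_exp):
        records.append(
            LifeRecord(f"e{i + 1:03d}", Group.EXPERIMENTAL, round(float(death_age[i]), 3), Event(event[i]))
        )

    samples = []
    p_cell = design.chimerism_truth * design.donor_positive_fraction
    for s in range(design.n_chimerism_samples):
        counts = rng.binomial(design.cells_per_image, p_cell, size=design.images_per_sample)
        images = tuple(
            ChimerismImage(f"img{j + 1:02d}", int(c), design.cells_per_image)
            for j, c in enumerate(counts)
        )
        samples.append(
            ChimerismSample(f"s{s + 1:02d}", images, design.donor_positive_fraction)
        )

    return Cohort(tuple(records), t_intervention=design.t_intervention), samples


@dataclass(frozen=True)
class RecoveryResult:
    true_params: GompertzParams
    recovered: GompertzParams
    err_mu0: float
    err_mu1: float
    curve: StepCurve


def parameter_recovery_experiment(
    true_params: GompertzParams, n: int, seed
) -> RecoveryResult:
    """Sample n lifespans, build the step curve, refit, report absolute errors."""
    if n < 100:
        raise ValueError("recovery experiment needs n >= 100")
    ages = sample_lifespans(true_params, n, seed)
    records = tuple(
        LifeRecord(f"r{i:05d}", Group.CONTROL, float(a), Event.NATURAL)
        for i, a in enumerate(ages)
    )
    curve = empirical_survival(Cohort(records))
    fit = fit_least_squares(curve)
    return RecoveryResult(
        true_params=true_params,
        recovered=fit,
        err_mu0=abs(fit.mu0 - true_params.mu0),
        err_mu1=abs(fit.mu1 - true_params.mu1),
        curve=curve,
    )
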