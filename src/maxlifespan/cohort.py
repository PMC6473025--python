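"""Cohort lifespan records, inclusion policy and empirical survival curves.

A study cohort is a flat table of animals: an opaque id, a group label
(control or experimental), the age in months at which the terminal event was
recorded, and the event type.  Four event types occur in this kind of
intervention study:

``natural``
    death from old age; always counted in survival statistics.
``embolic``
    death on the operating table during an intravenous injection; the
    analysis convention is to count these as natural deaths.
``sacrificed``
    animal removed for tissue sampling; excluded from all statistics.
``alive``
    animal still alive at its last observation (right-censored).

:func:`apply_mortality_policy` encodes the inclusion convention;
:func:`empirical_survival` builds the non-increasing step curve of the
fraction surviving versus age.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Event",
    "LifeRecord",
    "Cohort",
    "StepCurve",
    "apply_mortality_policy",
    "empirical_survival",
    "read_cohort_csv",
    "write_cohort_csv",
]


class Group(str, enum.Enum):
    CONTROL = "control"
    EXPERIMENTAL = "experimental"


class Event(str, enum.Enum):
    NATURAL = "natural"
    EMBOLIC = "embolic"
    SACRIFICED = "sacrificed"
    ALIVE = "alive"


@dataclass(frozen=True)
class LifeRecord:
    """One animal: id, group, age in months at the terminal event, event type."""

    animal_id: str
    group: Group
    age_months: float
    event: Event

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "event", Event(self.event))
        if not np.isfinite(self.age_months) or self.age_months < 0:
            raise ValueError(
                f"record {self.animal_id!r}: age_months must be finite and >= 0, "
                f"got {self.age_months!r}"
            )


@dataclass(frozen=True)
class Cohort:
    """A collection of :class:`LifeRecord` plus the intervention age T0 (months)."""

    records: tuple[LifeRecord, ...]
    t_intervention: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.animal_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate animal_id: {dupes}")
        if self.t_intervention < 0:
            raise ValueError("t_intervention must be >= 0")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, group: Group | str) -> "Cohort":
        g = Group(group)
        return replace(self, records=tuple(r for r in self.records if r.group == g))

    def death_ages(self) -> np.ndarray:
        """Sorted ages of all death events (natural or embolic)."""
        return np.sort(
            [r.age_months for r in self.records if r.event in (Event.NATURAL, Event.EMBOLIC)]
        )


@dataclass(frozen=True)
class StepCurve:
    """Fraction surviving as a right-continuous, non-increasing step function.

    ``ages``/``fractions`` are the breakpoints *after* each drop; the curve
    starts at (0, 1.0).  ``n`` is the number of animals at risk (deaths plus
    censored), kept so that fitted models can be compared on the same footing.
    """

    ages: np.ndarray
    fractions: np.ndarray
    n: int

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        fractions = np.asarray(self.fractions, dtype=float)
        if ages.shape != fractions.shape or ages.ndim != 1:
            raise ValueError("ages and fractions must be 1-d arrays of equal length")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(np.diff(fractions) > 0):
            raise ValueError("fractions must be non-increasing")
        if fractions.size and (fractions[0] > 1.0 + 1e-12 or fractions[-1] < -1e-12):
            raise ValueError("fractions must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "fractions", fractions)

    def __call__(self, t):
        """Fraction surviving at age ``t`` (vectorized, right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.ages, t, side="right")
        out = np.where(idx == 0, 1.0, self.fractions[np.clip(idx - 1, 0, None)])
        return out if out.ndim else float(out)

    def breakpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints including the (0, 1.0) start."""
        return (
            np.concatenate([[0.0], self.ages]),
            np.concatenate([[1.0], self.fractions]),
        )

    def to_frame(self) -> pd.DataFrame:
        ages, fractions = self.breakpoints()
        return pd.DataFrame({"age_months": ages, "fraction_surviving": fractions})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def apply_mortality_policy(cohort: Cohort) -> Cohort:
    """Apply the study's inclusion convention to a cohort.

    Sacrificed animals are removed entirely; embolic deaths are relabelled as
    natural deaths at the recorded (injection-day) age.  Everything else is
    untouched.  Idempotent; the input cohort is not mutated.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    out = []
    for r in cohort.records:
        if r.event == Event.SACRIFICED:
            continue
        if r.event == Event.EMBOLIC:
            r = replace(r, event=Event.NATURAL)
        out.append(r)
    return replace(cohort, records=tuple(out))


def empirical_survival(cohort: Cohort) -> StepCurve:
    """Empirical fraction-surviving step curve.

    Each death drops the curve by 1/n (ties drop k/n).  ``alive`` records are
    right-censored: they contribute to n but never produce a drop, so the
    curve ends above zero when censored animals outlive every death.  The
    mortality policy must already have been applied (sacrificed records are
    rejected rather than silently guessed at).
    """
    if any(r.event == Event.SACRIFICED for r in cohort.records):
        raise ValueError("cohort contains sacrificed records; apply_mortality_policy first")
    deaths = cohort.death_ages()
    if deaths.size == 0:
        raise ValueError("no events")
    n = len(cohort)
    ages, counts = np.unique(deaths, return_counts=True)
    fractions = 1.0 - np.cumsum(counts) / n
    # guard against float accumulation at the final drop
    fractions = np.clip(fractions, 0.0, 1.0)
    return StepCurve(ages=ages, fractions=fractions, n=n)


_COLUMNS = ["animal_id", "group", "age_months", "event"]


def read_cohort_csv(path: str | Path, t_intervention: float = 0.0) -> Cohort:
    """Read a cohort table (columns animal_id, group, age_months, event).

    Errors name the offending data row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype={"animal_id": str}, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                LifeRecord(
                    animal_id=str(row.animal_id),
                    group=Group(row.group),
                    age_months=float(row.age_months),
                    event=Event(row.event),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    try:
        return Cohort(records=tuple(records), t_intervention=t_intervention)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "group": r.group.value,
                "age_months": r.age_months,
                "event": r.event.value,
            }
            for r in cohort.records
        ],
        columns=_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")
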