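"""Cohort records, the inclusion policy, and the empirical survival curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maxlifespan import (
    Cohort,
    Event,
    GompertzParams,
    Group,
    LifeRecord,
    StepCurve,
    apply_mortality_policy,
    empirical_survival,
    read_cohort_csv,
    sample_lifespans,
    survival_fraction,
    write_cohort_csv,
)


def _cohort(ages_events, group=Group.CONTROL):
    return Cohort(
        tuple(
            LifeRecord(f"m{i}", group, a, e) for i, (a, e) in enumerate(ages_events)
        )
    )


class TestMortalityPolicy:
    def test_sacrificed_removed_embolic_relabelled(self, mixed_cohort):
        out = apply_mortality_policy(mixed_cohort)
        assert len(out) == 2
        assert all(r.event == Event.NATURAL for r in out.records)
        assert sorted(r.age_months for r in out.records) == [10.0, 16.0]
        # input untouched
        assert len(mixed_cohort) == 3
        assert mixed_cohort.records[2].event == Event.SACRIFICED

    def test_study_bookkeeping_56_enrolled_5_sacrificed(self):
        """56 experimental animals minus 5 sacrificed leaves 51 analyzable."""
        ages = np.linspace(5, 24, 56)
        events = [Event.NATURAL] * 42 + [Event.EMBOLIC] * 9 + [Event.SACRIFICED] * 5
        cohort = _cohort(zip(ages, events), group=Group.EXPERIMENTAL)
        out = apply_mortality_policy(cohort)
        assert len(out) == 51
        assert sum(r.event == Event.NATURAL for r in out.records) == 51

    def test_identity_when_nothing_to_do(self, control_cohort):
        assert apply_mortality_policy(control_cohort) == control_cohort

    def test_idempotent(self, mixed_cohort):
        once = apply_mortality_policy(mixed_cohort)
        assert apply_mortality_policy(once) == once

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            apply_mortality_policy(Cohort(()))


class TestEmpiricalSurvival:
    def test_tail_fractions_for_20_animal_cohort(self, control_cohort):
        curve = empirical_survival(control_cohort)
        assert curve(17.6) == pytest.approx(1 / 20)
        assert curve(19.3) == 0.0

    def test_single_death(self):
        curve = empirical_survival(_cohort([(10.0, Event.NATURAL)]))
        assert curve(9.999) == 1.0
        assert curve(10.0) == 0.0

    def test_tied_deaths_drop_together(self):
        curve = empirical_survival(
            _cohort([(1.0, Event.NATURAL)] * 2 + [(2.0, Event.NATURAL), (3.0, Event.NATURAL)])
        )
        assert curve(0.5) == 1.0
        assert curve(1.0) == 0.5
        assert curve(2.0) == 0.25
        assert curve(3.0) == 0.0

    def test_censored_animals_widen_n_but_never_drop(self):
        curve = empirical_survival(
            _cohort([(10.0, Event.NATURAL), (12.0, Event.ALIVE), (14.0, Event.ALIVE), (11.0, Event.NATURAL)])
        )
        assert curve.n == 4
        assert curve(11.0) == pytest.approx(0.5)  # two deaths out of four
        assert curve(30.0) == pytest.approx(0.5)  # censored tails keep the curve up

    def test_total_drop_equals_death_fraction(self, rng):
        events = [Event.NATURAL] * 30 + [Event.ALIVE] * 10
        ages = rng.uniform(1, 20, size=40)
        curve = empirical_survival(_cohort(zip(ages, events)))
        assert 1.0 - curve.fractions[-1] == pytest.approx(30 / 40)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            empirical_survival(_cohort([(5.0, Event.ALIVE)]))

    def test_sacrificed_records_rejected(self, mixed_cohort):
        with pytest.raises(ValueError, match="policy"):
            empirical_survival(mixed_cohort)

    def test_matches_kaplan_meier_without_censoring(self, rng):
        """With no censoring, the step curve equals the Kaplan-Meier estimate."""
        lifelines = pytest.importorskip("lifelines")
        ages = rng.uniform(2, 25, size=60)
        curve = empirical_survival(_cohort((a, Event.NATURAL) for a in ages))
        km = lifelines.KaplanMeierFitter().fit(ages)
        grid = np.linspace(0, 26, 200)
        np.testing.assert_allclose(
            curve(grid), km.survival_function_at_times(grid).to_numpy(), atol=1e-12
        )

    def test_glivenko_cantelli_convergence(self, fitted_params):
        """At n = 10^4 the empirical curve tracks the generating survival within 0.03."""
        ages = sample_lifespans(fitted_params, 10_000, seed=7)
        curve = empirical_survival(_cohort((a, Event.NATURAL) for a in ages))
        grid = np.linspace(0.0, 30.0, 2000)
        gap = np.max(np.abs(curve(grid) - survival_fraction(fitted_params, grid)))
        assert gap < 0.03


class TestStepCurveValidation:
    def test_rejects_increasing_fractions(self):
        with pytest.raises(ValueError, match="non-increasing"):
            StepCurve(ages=np.array([1.0, 2.0]), fractions=np.array([0.5, 0.8]), n=2)

    def test_rejects_unsorted_ages(self):
        with pytest.raises(ValueError, match="increasing"):
            StepCurve(ages=np.array([2.0, 1.0]), fractions=np.array([0.5, 0.2]), n=2)


class TestCsvRoundTrip:
    def test_single_row(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("animal_id,group,age_months,event\nm1,control,17.6,natural\n")
        cohort = read_cohort_csv(p)
        assert len(cohort) == 1
        assert cohort.records[0].age_months == 17.6

    def test_round_trip_identity(self, tmp_path, control_cohort):
        p = tmp_path / "cohort.csv"
        write_cohort_csv(control_cohort, p)
        assert read_cohort_csv(p) == control_cohort

    def test_unknown_event_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "animal_id,group,age_months,event\nm1,control,17.6,natural\nm2,control,3.0,dead\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_cohort_csv(p)

    def test_negative_age_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("animal_id,group,age_months,event\nm1,control,-1.0,natural\n")
        with pytest.raises(ValueError, match="row 1"):
            read_cohort_csv(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "animal_id,group,age_months,event\nm1,control,5.0,natural\nm1,control,6.0,natural\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort_csv(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "cols.csv"
        p.write_text("animal_id,group,age_months\nm1,control,5.0\n")
        with pytest.raises(ValueError, match="event"):
            read_cohort_csv(p)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    ages=st.lists(
        st.floats(min_value=0.1, max_value=40.0, allow_nan=False), min_size=1, max_size=40
    )
)
def test_survival_curve_invariants(ages):
    """Any all-deaths cohort yields a curve that is non-increasing, in [0,1], ending at 0."""
    curve = empirical_survival(
        Cohort(
            tuple(
                LifeRecord(f"m{i}", Group.CONTROL, a, Event.NATURAL)
                for i, a in enumerate(ages)
            )
        )
    )
    assert np.all(np.diff(curve.fractions) <= 0)
    assert np.all((curve.fractions >= 0) & (curve.fractions <= 1))
    assert curve.fractions[-1] == pytest.approx(0.0, abs=1e-12)
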