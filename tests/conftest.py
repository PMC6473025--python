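import numpy as np
import pytest

from maxlifespan import Cohort, Event, GompertzParams, Group, LifeRecord


@pytest.fixture(scope="session")
def fitted_params() -> GompertzParams:
    """The study's published Gompertz fit to pre-intervention mortality."""
    return GompertzParams(mu0=-11.4, mu1=0.7)


@pytest.fixture
def control_cohort() -> Cohort:
    """A 20-animal control cohort whose top decile dies at 17.6 and 19.3 months."""
    ages = [8.1, 9.4, 10.2, 11.0, 11.7, 12.3, 12.9, 13.4, 13.8, 14.2,
            14.6, 15.0, 15.3, 15.9, 16.1, 16.4, 16.8, 17.1, 17.6, 19.3]
    return Cohort(
        tuple(
            LifeRecord(f"c{i:02d}", Group.CONTROL, a, Event.NATURAL)
            for i, a in enumerate(ages)
        )
    )


@pytest.fixture
def mixed_cohort() -> Cohort:
    return Cohort(
        (
            LifeRecord("a1", Group.EXPERIMENTAL, 10.0, Event.NATURAL),
            LifeRecord("a2", Group.EXPERIMENTAL, 16.0, Event.EMBOLIC),
            LifeRecord("a3", Group.EXPERIMENTAL, 17.0, Event.SACRIFICED),
        ),
        t_intervention=15.0,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
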