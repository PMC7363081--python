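import numpy as np
import pytest

from ovimodel import (
    FemaleRecord,
    SynthConfig,
    default_parameters,
    generate_cohort,
)
from ovimodel.reference import adult_summary, oviposition_summary


@pytest.fixture(scope="session")
def params():
    """Packaged published parameter estimates."""
    return default_parameters()


@pytest.fixture(scope="session")
def adult_table():
    """Published per-temperature longevity/fecundity means."""
    return adult_summary()


@pytest.fixture(scope="session")
def ovi_table():
    """Published per-temperature APOP/AOP/TPOP means."""
    return oviposition_summary()


@pytest.fixture(scope="session")
def small_cohort(params):
    """Small multi-temperature synthetic cohort for pipeline tests."""
    cfg = SynthConfig(n_per_temperature=60, seed=11)
    return generate_cohort(params, cfg)


def make_record(
    eggs=(), temperature=23.5, longevity=None, rid="f1", apop=None, aop=None
):
    eggs = np.asarray(eggs, dtype=float)
    if longevity is None:
        longevity = max(eggs.size, 1)
    return FemaleRecord(
        id=rid,
        temperature=temperature,
        longevity=longevity,
        eggs=eggs,
        apop=apop,
        aop=aop,
    )
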