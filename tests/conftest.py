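import numpy as np
import pytest

from petcohort.curves import ded_schedule, pe2i_schedule
from petcohort.synthetic import (
    CohortSpec,
    ReferenceShape,
    generate_cohort,
    make_reference_tac,
)


@pytest.fixture(scope="session")
def ded_sched():
    return ded_schedule()


@pytest.fixture(scope="session")
def pe2i_sched():
    return pe2i_schedule()


@pytest.fixture(scope="session")
def pe2i_shape():
    return ReferenceShape(30.0, 0.03, 0.5)


@pytest.fixture(scope="session")
def ded_shape():
    return ReferenceShape(100.0, 0.05, 1.0)


@pytest.fixture(scope="session")
def pe2i_ref(pe2i_sched, pe2i_shape):
    return make_reference_tac(pe2i_sched, pe2i_shape)


@pytest.fixture(scope="session")
def ded_ref(ded_sched, ded_shape):
    return make_reference_tac(ded_sched, ded_shape, region="reference_corrected")


@pytest.fixture(scope="session")
def big_cohort():
    """n=10,000 cohort without TACs, shared across statistical checks."""
    return generate_cohort(CohortSpec(n_subjects=10_000, seed=42, simulate_tacs=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
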