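import pytest
from hypothesis import settings

from numlearn.experiments import (
    Sim2Config,
    run_sim1,
    run_sim2,
    run_sim3,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


# The headline simulation runs are deterministic and moderately sized, so a
# single session-scoped run of each is shared by all tests that read it.


@pytest.fixture(scope="session")
def sim1_result():
    return run_sim1()


@pytest.fixture(scope="session")
def sim2_result():
    return run_sim2()


@pytest.fixture(scope="session")
def sim2_equal8_result():
    return run_sim2(Sim2Config(arm="equal8", eval_sizes=tuple(range(1, 9))))


@pytest.fixture(scope="session")
def sim2_weighted8_result():
    return run_sim2(Sim2Config(eval_sizes=tuple(range(1, 9))))


@pytest.fixture(scope="session")
def sim3_result():
    return run_sim3()
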