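import numpy as np
import pytest

from cspc_lba import reference
from cspc_lba.fitting import prepare_fit_data
from cspc_lba.model_space import build_condition_params
from cspc_lba.synth import DesignSpec, GeneratingModel, simulate_participants


@pytest.fixture(scope="session")
def b2_theta():
    """Group-average threshold-model (B2) parameters for data set I."""
    return reference.reference_theta("B2", "I")


@pytest.fixture(scope="session")
def b2_mapping(b2_theta):
    return build_condition_params(b2_theta)


@pytest.fixture(scope="session")
def small_cohort():
    """Two simulated participants (full 448-trial design) from B2 truth."""
    gen = GeneratingModel.from_reference("B2", "I")
    cohort, truth = simulate_participants(DesignSpec(), gen, 2, seed=42)
    return cohort, truth


@pytest.fixture(scope="session")
def prepared_participant(small_cohort):
    cohort, _ = small_cohort
    return prepare_fit_data(cohort[0])


def random_accumulator(rng: np.random.Generator):
    """A random valid accumulator on the empirically relevant scale."""
    A = rng.uniform(0.02, 0.3)
    return dict(
        b=A + rng.uniform(0.05, 0.5),
        A=A,
        v=rng.uniform(0.4, 1.2),
        s=rng.uniform(0.1, 0.3),
    )
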