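import numpy as np
import pytest

from eegdep.synth import CohortSpec, generate_cohort

# 16-channel montage fully covering several regions of the association table,
# including the frontal discriminative trio.
SMALL_MONTAGE = (
    "FC2", "AFz", "F2",
    "PO3", "Pz", "POz", "O1", "O2", "Oz",
    "C1", "C2", "Cz", "Cpz",
    "FC3", "FC4", "FC6",
)


@pytest.fixture(scope="session")
def separated_cohort():
    """12 subjects, strong beta separation at FC2/AFz/F2, 19 s after trigger."""
    spec = CohortSpec(
        n_ctl=6,
        n_dep=6,
        channels=SMALL_MONTAGE,
        duration=20.0,
        beta_ctl=1.0,
        beta_dep=1.5,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """12 subjects with identical class parameters (no injected effect)."""
    spec = CohortSpec(
        n_ctl=6,
        n_dep=6,
        channels=SMALL_MONTAGE,
        duration=20.0,
        beta_ctl=1.0,
        beta_dep=1.0,
        seed=13,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
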