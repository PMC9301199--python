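import numpy as np
import pytest

import nasalpbpk as npk
from nasalpbpk import reference as ref


@pytest.fixture(scope="session")
def phys():
    return npk.build_physiology()


@pytest.fixture(scope="session")
def us():
    return ref.US_SYSTEMIC


@pytest.fixture(scope="session")
def cn():
    return ref.CN_SYSTEMIC


@pytest.fixture(scope="session")
def nasal_frac():
    return ref.NASAL_DEPOSITION


@pytest.fixture(scope="session")
def oral_frac():
    return ref.ORAL_DEPOSITION


@pytest.fixture(scope="session")
def bid_regimen():
    return ref.labelled_bid_regimen()


@pytest.fixture(scope="session")
def oral_1mg_sim(phys, us, oral_frac):
    """Typical-subject single oral 1 mg simulation on the default grid."""
    return npk.simulate(phys, us, oral_frac,
                        npk.Regimen.single_dose(ref.ORAL_DOSE_NG, route="oral"))


@pytest.fixture(scope="session")
def bid_sim(phys, us, nasal_frac, bid_regimen):
    """Typical-subject 0.06 mg intranasal BID x 7 d simulation."""
    return npk.simulate(phys, us, nasal_frac, bid_regimen)


def rng_state(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
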