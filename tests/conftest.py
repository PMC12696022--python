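import pytest

from vfaopt import TreatmentKey, simulate_study, study_domain


@pytest.fixture(scope="session")
def best_key():
    return TreatmentKey("PS", 14.0, 10.5)


@pytest.fixture(scope="session")
def study_obs():
    """One full synthetic study at the default replicate noise (516 mg COD/L)."""
    return simulate_study(seed=0)


@pytest.fixture(scope="session")
def zero_noise_obs():
    """Same design skeleton, zero replicate noise: rows equal the truth surface."""
    return simulate_study(seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def sampled_domain():
    """Sweep domain clipped to the sampled day span (no day < 3 extrapolation)."""
    return study_domain(day_range=(3.0, 12.0))
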