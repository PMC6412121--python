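import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def u1():
    from silnas.simulate import U1_LIKE

    return U1_LIKE


@pytest.fixture(scope="session")
def u2():
    from silnas.simulate import U2_LIKE

    return U2_LIKE


@pytest.fixture(scope="session")
def noise_free_default():
    """Default benchmark scenario with every noise source switched off."""
    from silnas.simulate import default_scenario, simulate

    scenario = default_scenario(
        intensity_cv=0.0, mass_error_ppm=0.0, rt_jitter_sd=0.0,
        stoichiometry_jitter_sd=0.0, n_replicates=1,
        conditions=("control", "knockdown-1"),
    )
    return scenario, simulate(scenario)
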