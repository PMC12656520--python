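import numpy as np
import pytest

from seedhtt import (
    PercentileTimes,
    SyntheticTrialConfig,
    Treatment,
    exact_percentiles,
)

TRUE = dict(theta_HT=500.0, Tb=10.0, psi_b50=-0.6, sigma_psib=0.2)
TEMPS = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0)
PSIS = (0.0, -0.2, -0.4, -0.6, -0.8)


@pytest.fixture(scope="session")
def noiseless_percentiles():
    """Exact model quantile curves over the full design grid (no censoring)."""
    return exact_percentiles(
        TRUE["theta_HT"], TRUE["Tb"], TRUE["psi_b50"], TRUE["sigma_psib"],
        temperatures=TEMPS, water_potentials=PSIS,
    )


@pytest.fixture(scope="session")
def trial_config():
    """Standard full-design trial at the usable water potentials."""
    return SyntheticTrialConfig(water_potentials=PSIS, rng_seed=11)


def make_percentiles(treatment_kwargs, g_levels, t_g):
    return PercentileTimes(
        treatment=Treatment(**treatment_kwargs),
        g_levels=np.asarray(g_levels, dtype=float),
        t_g=np.asarray(t_g, dtype=float),
    )
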