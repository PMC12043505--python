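import warnings

import numpy as np
import pytest

import phasecal as pc

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def identity():
    """Identity curve: mu_c(theta) = theta, negligible curve error."""
    return pc.identity_curve((12000, 2000))


@pytest.fixture(scope="session")
def wiggly():
    """Mildly wiggly terrestrial curve used across MCMC tests."""
    return pc.simulate_calibration_curve((11000, 5000), wiggle_amplitude=15,
                                         wiggle_period=600, sigma=8, seed=3)


@pytest.fixture(scope="session")
def single_phase_site(wiggly):
    """One uniform phase, true span 8500-7500 cal BP, 30 dates, sigma 40."""
    cfg = pc.SiteSimConfig(phase_truths=((8500.0, 7500.0),),
                           dates_per_phase=30, lab_sigma=40.0, seed=11)
    table, truth = pc.simulate_phased_site(cfg, wiggly)
    return table, truth


@pytest.fixture
def quick_mcmc():
    return pc.McmcSettings(chains=2, iterations=3000, burn_in=1000,
                           thin=2, seed=5)
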