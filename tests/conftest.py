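import math

import numpy as np
import pytest

import serumpk as sp


@pytest.fixture(scope="session")
def typical_params() -> sp.PKParameters:
    """Typical-subject one-compartment parameters of the simulated study."""
    return sp.PKParameters(ka=2.6, kel=math.log(2) / 3.93, vd_over_f=1500.0,
                           tlag=0.15, dose=100.0)


@pytest.fixture(scope="session")
def spec_params() -> sp.PKParameters:
    """Simple lag-free parameter set used for closed-form oracle checks."""
    return sp.PKParameters(ka=2.0, kel=0.1764, vd_over_f=1500.0,
                           tlag=0.0, dose=100.0)


@pytest.fixture(scope="session")
def dense_schedule() -> np.ndarray:
    """Quarter-hour sampling out to 48 h (~12 terminal half-lives)."""
    return np.round(np.arange(0.0, 48.0 + 1e-9, 0.25), 6)


@pytest.fixture(scope="session")
def dense_profile(typical_params, dense_schedule) -> sp.ConcentrationTimeProfile:
    return sp.simulate_profile(typical_params, dense_schedule)


@pytest.fixture(scope="session")
def printed_fit() -> sp.CalibrationFit:
    """1/x-weighted fit of a noise-free batch on the reference line."""
    batch = sp.simulate_calibration_batch(noise_cv=0.0)
    return sp.fit_weighted_line(batch, "1/x")
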