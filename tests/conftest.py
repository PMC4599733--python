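import pytest

import debstar as d
from debstar.calibration import calibrate


@pytest.fixture(scope="session")
def params_arr():
    """Packaged parameter set (uncalibrated) with its thermal response."""
    return d.default_params()


@pytest.fixture(scope="session")
def calibrated(params_arr):
    """Parameter set with wet coupler, maturity thresholds and s_M filled."""
    p, arr = params_arr
    return calibrate(p, arr), arr


@pytest.fixture(scope="session")
def env_lab():
    """Ad-libitum laboratory conditions at habitat temperature."""
    return d.Environment(T=271.5, f=1.0)


@pytest.fixture(scope="session")
def env_field(calibrated):
    p, _ = calibrated
    return d.Environment(T=271.5, f=p.f_f)


@pytest.fixture(scope="session")
def lab_lifecycle(calibrated, env_lab):
    """Fifty-year ad-libitum trajectory used by several slow checks."""
    p, arr = calibrated
    return d.simulate_lifecycle(p, arr, env_lab, t_end=50 * 365.0,
                                record_interval=10.0)


@pytest.fixture(scope="session")
def field_lifecycle(calibrated, env_field):
    """Field-food trajectory long enough to include puberty."""
    p, arr = calibrated
    return d.simulate_lifecycle(p, arr, env_field, t_end=12 * 365.0,
                                record_interval=10.0)


@pytest.fixture(scope="session")
def gonad_cycle_run(calibrated, env_lab):
    """Stationary gonad cycle of a maximum-size adult under lab food."""
    p, arr = calibrated
    L_i, _ = d.ultimate_size(p, arr, f=1.0)
    return d.simulate_gonad_cycle(p, arr, env_lab, length_cm=L_i, years=5)
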