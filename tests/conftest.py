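import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def consts():
    from mprfit.params import FixedConstants

    return FixedConstants()


@pytest.fixture(scope="session")
def fast_zap():
    """ZAP protocol at the accuracy-verified fast integration step."""
    from mprfit.stimulus import ZapConfig

    return ZapConfig(dt=0.5)


@pytest.fixture(scope="session")
def target():
    from mprfit.impedance import reference_target

    return reference_target()


@pytest.fixture(scope="session")
def evaluator(target, fast_zap):
    """Shared evaluator against the biological reference target."""
    from mprfit.evaluator import AttributeEvaluator

    return AttributeEvaluator(target, zap=fast_zap)


@pytest.fixture(scope="session")
def passive_params():
    """Leak-only model: the analytic RC oracle applies."""
    from mprfit.params import ModelParams

    return ModelParams(
        g_L=0.096, g_H=0.0, g_Ca=0.0, tau_mH_max=1000.0,
        V_half_mCa=-51.0, tau_mCa=70.0, V_half_hCa=-67.0, tau_hCa=458.0,
    )


@pytest.fixture(scope="session")
def median_params():
    from mprfit.params import MEDIAN_PARAMS

    return MEDIAN_PARAMS


def rc_impedance(f_hz, g_l, c_m=1.0):
    """Closed-form RC impedance (MOhm) and phase (rad) in mV/ms/uS/nF units."""
    w = 2.0 * np.pi * f_hz / 1000.0  # rad/ms
    Z = 1.0 / np.hypot(g_l, w * c_m)
    phi = -np.arctan2(w * c_m, g_l)
    return Z, phi
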