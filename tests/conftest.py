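import numpy as np
import pytest

from burstkin.fitting import ProgressCurve
from burstkin.models import BurstParams, RateConstants, burst_product


def biphasic_grid(lam: float, n_burst: int = 10, n_linear: int = 6) -> np.ndarray:
    """Time grid resolving both the burst (rate lam) and the linear phase."""
    return np.unique(np.concatenate([
        [0.0],
        np.geomspace(0.05 / lam, 5.0 / lam, n_burst),
        np.linspace(6.0 / lam, 60.0 / lam, n_linear),
    ]))


def noiseless_curve(e_active: float, k2: float, k3: float, s_total: float = 1e9) -> ProgressCurve:
    truth = BurstParams(e_active, RateConstants(k2, k3))
    t = biphasic_grid(k2 + k3)
    return ProgressCurve(t, burst_product(t, truth), e_active, s_total)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
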