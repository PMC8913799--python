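import numpy as np
import pytest

from nitiwave import AngleScan, NITIParameters, rayleigh_curve


@pytest.fixture(scope="session")
def skin_like_params() -> NITIParameters:
    """Forearm-dermis-like fast-axis parameter set (mu=2, G=6, delta=8 kPa)."""
    return NITIParameters(mu=2e3, G=6e3, delta=8e3, rho=1000.0)


@pytest.fixture(scope="session")
def noiseless_scan(skin_like_params) -> AngleScan:
    """13-angle noiseless synthetic scan with the symmetry axis at +10 deg."""
    curve = rayleigh_curve(skin_like_params, alpha=10.0)
    return AngleScan(curve.angles, curve.speeds)


def make_noisy_scan(base: AngleScan, rel_sd: float, seed: int) -> AngleScan:
    """Multiplicative Gaussian speed noise on an existing scan."""
    rng = np.random.default_rng(seed)
    speeds = base.speeds * (1.0 + rng.normal(0.0, rel_sd, size=base.speeds.shape))
    return AngleScan(base.angles, speeds, np.full_like(speeds, rel_sd * base.speeds.mean()))
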