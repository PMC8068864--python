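import numpy as np
import pytest

from condyn.frap import RoiSpec
from condyn.simulate import FrapSimConfig, simulate_frap_movie


@pytest.fixture(scope="session")
def small_diffusion_movie():
    """A compact pure-diffusion movie shared by conservation/IO tests."""
    cfg = FrapSimConfig(grid_size=64, pixel_size=0.08, n_post=60,
                        diffusion_coeff=0.147,
                        bleach_roi=RoiSpec(kind="circle", center=(31.5, 31.5),
                                           radius=0.5),
                        seed=7)
    movie, gt = simulate_frap_movie(cfg)
    return cfg, movie, gt


def exp_recovery(times, amplitudes, half_times):
    """Reference (bi)exponential recovery used to build noiseless curves."""
    times = np.asarray(times, float)
    out = np.zeros_like(times)
    for a, th in zip(amplitudes, half_times):
        out += a * (1.0 - np.exp(-times * np.log(2) / th))
    return out
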