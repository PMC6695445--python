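import numpy as np
import pytest

import leapmea as lm
from leapmea.model import AnalysisConfig

FS_NATIVE = 12500.0   # acquisition-platform rate
FS_DESK = 5000.0      # desk-scale rate for synthesis-heavy tests
FS_FAST = 2000.0      # long-recording tests

# band edges clamped for the reduced rates (band_for also clamps at runtime)
DESK_CONFIG = AnalysisConfig(leap_band_hz=(0.01, 2000.0), fp_band_hz=(1.0, 2000.0))


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def desk_config():
    return DESK_CONFIG


def make_leap_trace(
    fs=FS_DESK,
    bp_ms=1200.0,
    duration_s=12.0,
    amplitude_uV=1000.0,
    theta_ms=300.0,
    h=4.0,
    rise_ms=5.0,
    sigma_uV=0.0,
    seed=0,
    **kwargs,
):
    """One spontaneous high-coupling AP electrode trace plus its truth rows."""
    shape = lm.APShapeParams(
        family="hill", rise_time_ms=rise_ms, theta_ms=theta_ms, h=h, diastolic_ms=150.0
    )
    sched = lm.BeatSchedule(mean_bp_ms=bp_ms, cov_percent=kwargs.pop("cov_percent", 0.0))
    coup = lm.CouplingParams(mode="leap", amplitude_uV=amplitude_uV)
    noise = lm.NoiseParams(white_sigma_uV=sigma_uV, seed=seed)
    return lm.synthesize_electrode_trace(
        shape, sched, coup, noise=noise, sampling_rate_hz=fs, duration_s=duration_s,
        rng=seed, **kwargs,
    )


def shelf_beat_uV(fs=FS_NATIVE, amplitude_uV=1000.0, shelf_frac=0.6, shelf_ms=300.0):
    """Synthetic beat with a flat mid-repolarization shelf.

    Upstroke to ``amplitude``, fast drop to ``shelf_frac``·amplitude, a flat
    shelf, then linear decay to zero: a bump added on the shelf has
    topographic prominence exactly equal to its height.
    """
    dt = 1000.0 / fs
    up = np.array([0.0, amplitude_uV])
    drop = np.linspace(amplitude_uV, shelf_frac * amplitude_uV, int(10 / dt))
    shelf = np.full(int(shelf_ms / dt), shelf_frac * amplitude_uV)
    decay = np.linspace(shelf_frac * amplitude_uV, 0.0, int(200 / dt))
    rest = np.zeros(int(100 / dt))
    return np.concatenate([up, drop, shelf, decay, rest])


def raised_cosine_bump(n, center, half_width):
    k = np.arange(n)
    b = 0.5 * (1 + np.cos(np.pi * (k - center) / half_width))
    b[np.abs(k - center) > half_width] = 0.0
    return b
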