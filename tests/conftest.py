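import numpy as np
import pytest

from chrophys import synth
from chrophys.synth.mea import RateLevelSigmoid


@pytest.fixture(scope="session")
def pulse_mea_recording():
    """Small single-pulse recording with planted sigmoid rate-level."""
    params = synth.MEAParams(
        n_electrodes=4,
        intensities=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0),
        n_reps=30,
        rate_level=RateLevelSigmoid(floor=5.0, ceiling=150.0, midpoint=4.0, slope=1.2),
        best_depth_um=75.0,
        spatial_sigma_um=500.0,
        noise_sd_uv=5.0,
        post_ms=40.0,
    )
    return params, synth.gen_mea_recording(params, 11)


@pytest.fixture(scope="session")
def small_image_stack():
    """Ten-cell stack with all cells expressing, membrane gain 2."""
    params = synth.ImageSimParams(
        n_cells=10,
        frac_positive=1.0,
        membrane_gain=2.0,
        background_sd=0.5,
        image_shape=(5, 450, 450),
    )
    return params, synth.gen_image_stack(params, 21)


def match_fraction(truth_times, detected_times, tol_ms):
    """Fraction of planted spikes with a detection within tol_ms."""
    truth_times = np.asarray(truth_times)
    detected_times = np.asarray(detected_times)
    if truth_times.size == 0:
        return np.nan
    if detected_times.size == 0:
        return 0.0
    d = np.abs(truth_times[:, None] - detected_times[None, :]).min(axis=1)
    return float((d <= tol_ms).mean())
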