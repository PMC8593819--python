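import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import somnoflow as sf
from somnoflow import synthetic as syn
from somnoflow.position import PositionSegment


@pytest.fixture(scope="session")
def small_subject():
    """A 10-minute single-position night with moderate apnea burden."""
    trace, truth = sf.generate_subject(600.0, 30.0, "single_position", seed=3)
    return trace, truth


@pytest.fixture(scope="session")
def rolling_subject():
    """A 30-minute night with position changes and events in both positions."""
    trace, truth = sf.generate_subject(1800.0, 40.0, "positional", seed=5)
    return trace, truth


@pytest.fixture(scope="session")
def small_trajectories(small_subject):
    trace, truth = small_subject
    return syn.exact_point_trajectories(trace, truth.positions, 48, 64, rate=2.0)


@pytest.fixture(scope="session")
def textured_image():
    """A smooth random texture suitable for optical-flow estimation."""
    rng = np.random.default_rng(1)
    img = gaussian_filter(rng.random((80, 100)), 3.0)
    return (img - img.min()) / np.ptp(img)


@pytest.fixture()
def sinusoid_trace():
    t = np.arange(600) / 10.0
    return syn.BreathingTrace(
        sample_rate=10.0,
        amplitude_series=2.0 * np.sin(2 * np.pi * 0.3 * t),
        base_rate=0.3,
        noise_sd=0.0,
    )


@pytest.fixture()
def supine_segment():
    return [PositionSegment(0.0, 60.0, "supine")]
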