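import numpy as np
import pytest

from oirdkit import BreathModelSpec, SegmentationConfig


@pytest.fixture
def noiseless_config() -> SegmentationConfig:
    """Segmentation without smoothing, for exact noiseless checks."""
    return SegmentationConfig(smoothing_window_s=0.0)


@pytest.fixture
def periodic_spec() -> BreathModelSpec:
    """Exactly periodic 2 Hz breathing at PIF −3 mL/s."""
    return BreathModelSpec(mean_frequency=2.0, mean_pif=-3.0)


@pytest.fixture
def sine_recording():
    """flow(t) = −sin(2π·2t) over 5 s at 1 kHz: 2 Hz breathing starting
    with inspiration at t = 0."""
    from oirdkit import AirflowRecording
    t = np.arange(0, 5, 0.001)
    return AirflowRecording(-np.sin(2 * np.pi * 2 * t), 1000.0)
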