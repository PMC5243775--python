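import numpy as np
import pytest
from hypothesis import settings

from gobypass import AssayRecording, FishRecord, ThresholdSet, \
    worked_example_profile

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def reference_profile():
    """The shipped reference barrier (max bottom flow 0.5 m/s, max pool
    spacing 4.54 m)."""
    return worked_example_profile()


@pytest.fixture
def reference_thresholds():
    """Published a-priori thresholds: front trait means plus barrier limits."""
    return ThresholdSet(boldness_mean=1.13, activity_mean=1.17,
                        asociability_mean=0.95, flow_limit_m_s=0.5,
                        distance_limit_m=4.54)


@pytest.fixture
def example_individual():
    """The published worked-example fish: 12.2 cm, bold and active but
    social."""
    return FishRecord(fish_id="example", tl_cm=12.2, boldness=1.71,
                      activity=1.76, asociability=0.47)


def make_recording(frames, latency_s=60.0, px_per_cm=2.0,
                   stimuli_point=(0.0, 0.0), fish_id="f0", t_max=3600.0):
    """Build an AssayRecording from a plain list of (t, x, y) rows."""
    return AssayRecording(fish_id=fish_id, latency_s=latency_s,
                          frames=np.asarray(frames, dtype=float),
                          px_per_cm=px_per_cm, stimuli_point=stimuli_point,
                          t_max=t_max)
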