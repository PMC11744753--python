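import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20081114)


def make_recording(values, start_s=7 * 3600, **kwargs):
    """Small recording with a window exactly covering the given samples."""
    from luxsleep.light import TimeWindow, clean_samples

    values = np.asarray(values, dtype=float)
    win = TimeWindow(start_s, start_s + len(values))
    times = np.arange(start_s, start_s + len(values))
    return clean_samples(times, values, analysis_window=win, **kwargs)


def random_hypnogram(rng, n_min=40, n_max=400, p_w=0.15):
    """Unstructured random stage sequence (may lack a valid onset)."""
    from luxsleep.sleep import STAGES, Hypnogram

    n = int(rng.integers(n_min, n_max))
    probs = [p_w, 0.1, 0.4, 0.2, 0.3 - p_w + 0.05]
    probs = np.array(probs) / np.sum(probs)
    stages = rng.choice(STAGES, size=n, p=probs)
    return Hypnogram(23 * 3600, stages)
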