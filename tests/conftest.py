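import numpy as np
import pytest

from critstate.io import SpikeRecording
from critstate.popstats import PopulationTrain


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def poisson_recording():
    """Two-electrode homogeneous Poisson recording, 200 s at 30 Hz pooled."""
    rng = np.random.default_rng(7)
    duration = 200.0
    times, elecs = [], []
    for e, rate in ((0, 10.0), (1, 20.0)):
        n = rng.poisson(rate * duration)
        times.append(rng.random(n) * duration)
        elecs.append(np.full(n, e))
    return SpikeRecording(
        np.concatenate(elecs), np.concatenate(times), duration=duration
    )


@pytest.fixture(scope="session")
def synth_recording():
    """Default five-state synthetic recording (shared across tests)."""
    from critstate.synth import SynthStateParams, generate_labeled_recording

    return generate_labeled_recording(SynthStateParams(), duration=400.0, seed=11)


def train_from_counts(counts, delta_t_ms=10.0):
    """Build a PopulationTrain whose binned counts equal ``counts`` exactly."""
    counts = np.asarray(counts, dtype=int)
    b = delta_t_ms / 1000.0
    times = []
    for i, c in enumerate(counts):
        # spread spikes strictly inside bin i
        times.extend(i * b + (np.arange(c) + 0.5) / max(c, 1) * b * 0.999)
    duration = counts.size * b
    return PopulationTrain(np.asarray(times), [(0.0, duration)])
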