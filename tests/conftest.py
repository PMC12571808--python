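import numpy as np
import pytest

from stanflow.spike_data import EnsembleRecording
from stanflow.synthetic_data import default_benchmark_config, simulate_population


@pytest.fixture
def tiny_rec() -> EnsembleRecording:
    """Two units, one odor + control, two trials, hand-placed spikes."""
    spikes = {
        ("a", "odorA", 0): np.array([0.10, 0.25, 0.45]),
        ("b", "odorA", 0): np.array([0.12, 0.30, 0.31]),
        ("a", "odorA", 1): np.array([0.20, 0.50]),
        ("b", "odorA", 1): np.array([0.05]),
        ("a", "ctrl", 0): np.array([0.40]),
        ("b", "ctrl", 1): np.array([0.15, 0.90]),
    }
    return EnsembleRecording(
        unit_ids=["a", "b"],
        stimuli=[("odorA", "behavioral"), ("ctrl", "control")],
        trials_per_stimulus=2,
        spikes=spikes,
        stim_onset_s=0.3,
        stim_duration_s=0.4,
        trial_duration_s=1.0,
    )


@pytest.fixture(scope="session")
def benchmark_rec() -> EnsembleRecording:
    """The 12-unit planted-synchrony benchmark ensemble (fixed seed)."""
    return simulate_population(default_benchmark_config(seed=1))
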