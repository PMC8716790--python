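import numpy as np
import pytest

from cldbs.sensing import Band, SenseConfig
from cldbs.synthetic import (
    BiomarkerSpec,
    SymptomDynamics,
    SymptomTrace,
    generate_lfp,
    generate_symptom_trace,
)

THETA = Band(label="theta", low=4.0, high=8.0)
BETA = Band(label="beta", low=13.0, high=30.0)


def make_trace(score: np.ndarray, dt: float = 1.0, cutoff: float = 5.0) -> SymptomTrace:
    """Build a SymptomTrace directly from a score array."""
    score = np.asarray(score, float)
    times = np.arange(len(score)) * dt
    return SymptomTrace(times, score, (score >= cutoff).astype(int), cutoff)


@pytest.fixture(scope="session")
def block_trace():
    """300 s low-pain block followed by 300 s high-pain block."""
    return make_trace(np.r_[np.full(300, 3.0), np.full(300, 7.0)])


@pytest.fixture(scope="session")
def theta_biomarker():
    return BiomarkerSpec(channel=0, band=(4.0, 8.0), power_low=1.0, power_high=4.0)


@pytest.fixture(scope="session")
def theta_recording(block_trace, theta_biomarker):
    """Recording with a clean state-gated theta biomarker, low background."""
    return generate_lfp(
        block_trace, [theta_biomarker], fs=250.0, seed=11, background_rms=0.3
    )


@pytest.fixture(scope="session")
def theta_sense_cfg():
    return SenseConfig(
        window_length=256, update_interval=0.5, bands=[THETA], channels=["ch1"]
    )


@pytest.fixture(scope="session")
def episodic_trace():
    dyn = SymptomDynamics(
        baseline=4.0,
        diurnal_amplitude=0.0,
        transition_rate=1.0 / 100.0,
        transition_amplitude=3.0,
        noise_sd=0.2,
    )
    return generate_symptom_trace(
        600.0, dyn, cutoff=5.0, seed=21, require_both_states=True
    )
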