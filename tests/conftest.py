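import numpy as np
import pytest

from ictalscope.io import EEGRecord, SeizureAnnotation
from ictalscope.synth import SynthConfig, assemble_record


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig(total_duration_s=2500.0, n_events=2, seed=42)


@pytest.fixture(scope="session")
def synth_record(synth_config):
    """One synthetic annotated record shared across tests (read-only)."""
    return assemble_record(synth_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def flat_record():
    """A constant-plus-noise record handy for window arithmetic tests."""
    fs = 1000.0
    rng = np.random.default_rng(0)
    x = rng.standard_normal(int(60 * fs))
    return EEGRecord(samples=x, fs=fs, record_id="flat")


def make_record(duration_s, fs=1000.0, seed=0, amp=1.0):
    rng = np.random.default_rng(seed)
    return EEGRecord(samples=amp * rng.standard_normal(int(duration_s * fs)), fs=fs, record_id=f"r{seed}")


def make_annotation(events):
    return SeizureAnnotation(list(events))
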