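import numpy as np
import pytest

from aad.containers import Envelope, EEGRecording, Part
from aad.synthetic import SimulationConfig, generate_session

# a small montage used where the physics under test is channel-count
# independent and a full cap would only cost time
SMALL_LABELS = ("Fz", "Cz", "Pz", "F3", "F4", "C3", "C4", "Oz")


def small_config(**kwargs) -> SimulationConfig:
    defaults = dict(montage="custom", custom_labels=SMALL_LABELS,
                    n_parts=4, part_duration_s=(30.0, 30.0), snr_db=10.0,
                    seed=0)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def make_part(eeg_data: np.ndarray, env_att: np.ndarray,
              env_unatt: np.ndarray, part_id: str = "p0") -> Part:
    labels = [f"ch{i}" for i in range(eeg_data.shape[0])]
    return Part(
        part_id=part_id,
        subject_id="test",
        eeg=EEGRecording(data=eeg_data, fs=100.0, channel_labels=labels),
        env_attended=Envelope(env_att, talker_id="A"),
        env_unattended=Envelope(env_unatt, talker_id="B"),
        attended_talker_id="A",
    )


@pytest.fixture(scope="session")
def small_session():
    """High-SNR 4-part session on the 8-channel montage (shared, read-only)."""
    return generate_session(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
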