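import numpy as np
import pytest

from microstates import reference
from microstates.montage import ElectrodeMontage, standard_64_montage
from microstates.preprocess import epoch_and_reference
from microstates.synth import render_eeg, sample_state_sequence
from microstates.templates import make_canonical_templates

# classic 10-20 subset: cheap but still separates the four template classes
SMALL_NAMES = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
]


@pytest.fixture(scope="session")
def montage64():
    return standard_64_montage()


@pytest.fixture(scope="session")
def templates64(montage64):
    return make_canonical_templates(montage64)


@pytest.fixture(scope="session")
def montage20(montage64):
    idx = [montage64.channel_names.index(n) for n in SMALL_NAMES]
    return ElectrodeMontage(tuple(SMALL_NAMES), montage64.positions[idx])


@pytest.fixture(scope="session")
def templates20(montage20):
    return make_canonical_templates(montage20)


@pytest.fixture(scope="session")
def mwoa_spec():
    return reference.semimarkov_from_group(reference.MWOA)


@pytest.fixture(scope="session")
def hc_spec():
    return reference.semimarkov_from_group(reference.HC)


@pytest.fixture(scope="session")
def short_recording(mwoa_spec, templates20, montage20):
    """60 s, 20-channel, snr-5 recording with ground truth."""
    labels = sample_state_sequence(mwoa_spec, 60.0, 500.0, seed=11)
    return render_eeg(labels, templates20, 500.0, 5.0, seed=12, montage=montage20)


@pytest.fixture(scope="session")
def short_epochs(short_recording):
    return epoch_and_reference(short_recording, 2.0, 30)


def make_epochs(data: np.ndarray, fs: float, epoch_length_s: float):
    """Wrap a channels-by-samples matrix as a single referenced epoch set."""
    from microstates.synth import SyntheticRecording

    rec = SyntheticRecording(np.asarray(data, float), fs=fs)
    n = int(round(epoch_length_s * fs))
    return epoch_and_reference(rec, epoch_length_s, data.shape[1] // n)
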