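import numpy as np
import pytest

from plastometrics import io, synthetic


@pytest.fixture(scope="session")
def study_table():
    """The bundled 24-subject clinical table (13 guided, 11 sham)."""
    return io.load_bundled_clinical()


@pytest.fixture(scope="session")
def erd_epochs():
    """Synthetic EEG with 20% mu power drop on the affected channels."""
    return synthetic.generate_eeg(synthetic.EEGGenSpec(n_trials=12, seed=7))


@pytest.fixture(scope="session")
def bold_dataset():
    """One state-switching BOLD draw with its ground-truth flexible set."""
    ts, flexible, states = synthetic.generate_bold(synthetic.BOLDGenSpec(seed=11))
    return ts, np.asarray(flexible), states
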