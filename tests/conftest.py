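import numpy as np
import pytest

from sleepfbn import CouplingModel, FunctionalBrainNetwork, simulate_eeg
from sleepfbn.io import write_edf
from sleepfbn.pipeline import planted_coupling

LABELS8 = tuple("ABCDEFGH")


@pytest.fixture
def k8_net():
    """Binary complete graph on 8 nodes (joint analytic fixture)."""
    w = np.ones((8, 8))
    np.fill_diagonal(w, 0.0)
    return FunctionalBrainNetwork(w, LABELS8)


@pytest.fixture
def empty_net():
    return FunctionalBrainNetwork(np.zeros((8, 8)), LABELS8)


@pytest.fixture
def ring_net():
    w = np.zeros((8, 8))
    for i in range(8):
        w[i, (i + 1) % 8] = w[(i + 1) % 8, i] = 1.0
    return FunctionalBrainNetwork(w, LABELS8)


@pytest.fixture(scope="session")
def edf_file(tmp_path_factory):
    """A 160-s simulated 8-channel recording written as EDF."""
    model = CouplingModel(coupling=planted_coupling(), noise_sd=1.0, seed=2024)
    rec = simulate_eeg(model, duration=160.0, subject_id="S01", timepoint="baseline")
    path = tmp_path_factory.mktemp("edf") / "s01_baseline.edf"
    write_edf(rec, path)
    return path, rec
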