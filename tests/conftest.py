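import numpy as np
import pytest

import eegfp
from eegfp.montage import Montage


@pytest.fixture(scope="session")
def montage():
    return eegfp.default_montage()


@pytest.fixture(scope="session")
def toy_montage():
    """Three fully adjacent electrodes; hand-checkable Laplacian."""
    return Montage(
        name="toy3",
        names=("A", "B", "C"),
        positions={"A": (0.0, 1.0), "B": (-1.0, -1.0), "C": (1.0, -1.0)},
        region={"A": "frontal", "B": "central", "C": "parietal"},
        neighbors={
            "A": frozenset({"B", "C"}),
            "B": frozenset({"A", "C"}),
            "C": frozenset({"A", "B"}),
        },
    )


@pytest.fixture(scope="session")
def noise_epoch():
    """One 32-channel epoch of independent white noise (500 samples)."""
    rng = np.random.default_rng(11)
    return eegfp.Epoch(
        data=rng.standard_normal((32, 500)),
        fs=250.0,
        subject_id="S01",
        session_id="A",
        index=0,
    )


@pytest.fixture(scope="session")
def small_cohort_features():
    """GC features of a 4-subject single-session desk-scale cohort."""
    recs = eegfp.make_cohort(
        n_subjects=4,
        sessions=[eegfp.SessionSpec("A", 1, 0.0)],
        duration_s=60.0,
        fs=125.0,
        seed=5,
    )
    epochs = []
    for rec in recs:
        epochs.extend(eegfp.preprocess_recording(rec))
    return eegfp.connectivity_dataset(epochs, "GC", order=8)
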