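import numpy as np
import pytest

from indelfx import GeneratorConfig, ProteinRecord, generate_dataset
from indelfx.features import PropertyTrack


@pytest.fixture
def toy_protein():
    return ProteinRecord(protein_id="TOY", sequence="MAKLG")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study shared across tests."""
    config = GeneratorConfig(n_proteins=40, n_pathogenic=120, n_neutral=200,
                             seed=7)
    proteins, variants, truth = generate_dataset(config)
    return config, proteins, variants, truth


def make_track(scores, threshold=0.5, mechanism="m", alpha=None):
    return PropertyTrack(mechanism=mechanism, scores=np.asarray(scores, float),
                         confident_threshold=threshold, alpha=alpha)
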