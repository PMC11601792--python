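import numpy as np
import pytest

from jointms.chem import FeatureConfig, parse_molecule
from jointms.encoders import EncoderConfig
from jointms.simdata import SimConfig, generate_dataset
from jointms.training import LossConfig


@pytest.fixture(scope="session")
def small_molecules():
    """A handful of parsed everyday molecules."""
    return {
        name: parse_molecule(smi, mol_id=name)
        for name, smi in {
            "ethanol": "CCO",
            "dimethyl_ether": "COC",
            "benzene": "c1ccccc1",
            "acetic_acid": "CC(=O)O",
            "methane": "C",
            "ethylamine": "CCN",
        }.items()
    }


@pytest.fixture(scope="session")
def tiny_encoder_config():
    """Small encoder for fast unit tests."""
    return EncoderConfig(gcn_layers=2, hidden_dim=16, embed_dim=8, dropout=0.0)


@pytest.fixture(scope="session")
def tiny_sim():
    """A miniature synthetic study used by training/model/cli tests."""
    return generate_dataset(SimConfig(n_molecules=12, library_multiplier=10, seed=11))


@pytest.fixture(scope="session")
def tiny_loss_config():
    return LossConfig(epochs=3, batch_size=8, kaug=2, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
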