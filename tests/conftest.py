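import numpy as np
import pytest

from molclsp.backbone import Backbone, BackboneConfig, graph_from_smiles
from molclsp.chemio import generate_fixture_set
from molclsp.espf import build_vocab, tokenize


@pytest.fixture(scope="session")
def fixture_records():
    """40 deterministic synthetic molecules with conformers and labels."""
    return generate_fixture_set(40, seed=1)


@pytest.fixture(scope="session")
def vocab(fixture_records):
    return build_vocab([r.smiles for r in fixture_records], min_frequency=2, max_size=200)


@pytest.fixture(scope="session")
def small_cfg():
    """A tiny architecture for unit tests (fast, same code paths)."""
    return BackboneConfig(
        d=32, z=32, n_layers_1d=1, n_heads_1d=2, n_layers_2d=2, n_blocks_3d=1,
        n_rbf=4, n_abf=3, cutoff=5.0, fusion_blocks=1, fusion_heads=2, max_len=64,
    )


@pytest.fixture(scope="session")
def small_backbone(small_cfg, vocab):
    return Backbone(small_cfg, vocab.n_ids, vocab.fingerprint, seed=0)


@pytest.fixture(scope="session")
def ethanol_tok(vocab):
    return tokenize("CCO", vocab)


@pytest.fixture(scope="session")
def ethanol_graph():
    return graph_from_smiles("CCO")
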