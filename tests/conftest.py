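"""Shared fixtures: tiny corpora and a small memorizing model."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from biochemlm.autodiff import Adam
from biochemlm.fixtures import ToyWorldConfig, generate_world, random_molecules
from biochemlm.model import BiochemLM, ModelConfig
from biochemlm.tokenization import PotencyBinner, SmilesVocabulary

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

TINY_SMILES = [
    "CCc1ccc2ccccc2c1",
    "Cc1cc2ccccc2o1",
    "FCc1ccc(-c2ccccc2)cc1",
    "CCCc1cc2ccccc2[nH]1",
    "ClCCc1ccc2ccccc2c1",
    "OCCc1cc2ccccc2s1",
]


@pytest.fixture(scope="session")
def tiny_vocab() -> SmilesVocabulary:
    return SmilesVocabulary.from_corpus(TINY_SMILES)


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    # deliberately small profile so unit tests train in seconds
    return ModelConfig(d_model=32, n_heads=2, d_feedforward=64, dropout=0.0,
                       max_len=40)


@pytest.fixture(scope="session")
def protein_vec() -> np.ndarray:
    rng = np.random.default_rng(42)
    v = rng.standard_normal(32)
    return v / np.linalg.norm(v)


@pytest.fixture(scope="session")
def trained_model(tiny_config, tiny_vocab, protein_vec) -> BiochemLM:
    """A small conditional model that has memorized the tiny corpus."""
    model = BiochemLM(tiny_config, tiny_vocab, seed=0)
    binner = PotencyBinner()
    opt = Adam(model.params, lr=1e-3)
    examples = [(tiny_vocab.encode(s), binner.bin(5.0 + 0.5 * i))
                for i, s in enumerate(TINY_SMILES)]
    for _ in range(120):
        for ids, pbin in examples:
            opt.zero_grad()
            loss = model.forward_loss(protein_vec, pbin, ids)
            loss.backward()
            opt.step()
    return model


@pytest.fixture(scope="session")
def toy_world():
    return generate_world(ToyWorldConfig(seed=11))


@pytest.fixture(scope="session")
def fixture_molecules() -> list[str]:
    return random_molecules(200, seed=5)
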