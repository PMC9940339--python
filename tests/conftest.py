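"""Shared fixtures: synthetic libraries, fragment pairs, trained models.

The expensive session-scoped fixtures (a trained tiny graph transformer
and a fitted affinity model) are shared between the generator, RL and
acceptance tests to keep the suite fast.
"""
from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from molgrow import (
    Environment,
    GraphVocab,
    brics_leaf_fragments,
    generate_fixture_library,
    make_generator,
    pairs_from_library,
    train_affinity_model,
)


@pytest.fixture(scope="session")
def small_library():
    """60 decorated heteroaromatic molecules with planted activities."""
    return generate_fixture_library(seed=1, n=60)


@pytest.fixture(scope="session")
def small_pairs(small_library):
    return pairs_from_library(small_library, rng_seed=0)


@pytest.fixture(scope="session")
def graph_vocab():
    return GraphVocab()


@pytest.fixture(scope="session")
def training_library():
    """The 300-molecule library used for desk-scale model training."""
    return generate_fixture_library(seed=7, n=300)


@pytest.fixture(scope="session")
def training_pairs(training_library):
    return pairs_from_library(training_library, rng_seed=0)


@pytest.fixture(scope="session")
def trained_graph_generator(training_pairs):
    """Tiny graph transformer (d_model 64, 2 layers) trained 30 epochs."""
    gen = make_generator(
        "graph-transformer",
        d_model=64,
        n_heads=4,
        n_layers=2,
        l_max=64,
        lr=1e-3,
        batch_size=128,
        epochs=30,
        patience=100,
        seed=0,
    )
    return gen.fit(training_pairs)


@pytest.fixture(scope="session")
def affinity_model(training_library):
    return train_affinity_model(training_library, n_estimators=200, seed=0)


@pytest.fixture(scope="session")
def affinity_env(affinity_model):
    return Environment(model=affinity_model, objectives=("affinity",))


@pytest.fixture(scope="session")
def small_scaffold_pool(training_library):
    """Small fragments (<= 4 heavy atoms) leaving the core choice free."""
    return sorted(
        {
            f
            for r in training_library
            for f in brics_leaf_fragments(r).fragments
            if Chem.MolFromSmiles(f).GetNumHeavyAtoms() <= 4
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
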