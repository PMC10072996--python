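"""Shared fixtures: a seeded synthetic benchmark run through the full
baseline pipeline once per session, plus small toy objects."""

from __future__ import annotations

import numpy as np
import pytest

from cpascan.datasets import (
    make_positive_windows,
    select_constitutive,
    split_by_chromosome,
    subsample_negatives,
    tile_negatives,
)
from cpascan.features import BASELINE_GRID, assemble_matrix
from cpascan.models import ModelConfig, train
from cpascan.motifs import default_baseline_registry
from cpascan.simulate import (
    ElementParams,
    GeneratorSpec,
    default_element_params,
    generate,
)

SEED = 0


@pytest.fixture(scope="session")
def registry():
    return default_baseline_registry()


@pytest.fixture(scope="session")
def truth():
    """Default-scale synthetic benchmark (400 genes, seeded)."""
    return generate(GeneratorSpec(seed=SEED))


@pytest.fixture(scope="session")
def splits(truth):
    """Constitutive selection, window construction, chromosome split and
    30:1 negative subsampling on the default benchmark."""
    chosen, dropped = select_constitutive(truth.all_known_sites, truth.gene_models())
    positives = make_positive_windows(chosen, truth.sequences)
    negatives = tile_negatives(
        truth.gene_models(), truth.sequences, truth.all_known_sites
    )
    pos_train, pos_test, _ = split_by_chromosome(positives)
    neg_train, neg_test, _ = split_by_chromosome(negatives)
    neg_train_sub = subsample_negatives(neg_train, len(pos_train), seed=SEED)
    return {
        "constitutive": chosen,
        "dropped": dropped,
        "positives": positives,
        "negatives": negatives,
        "pos_train": pos_train,
        "pos_test": pos_test,
        "neg_train": neg_train_sub,
        "neg_train_pool": neg_train,
        "neg_test": neg_test,
    }


@pytest.fixture(scope="session")
def train_matrix(splits, registry):
    return assemble_matrix(
        splits["pos_train"] + splits["neg_train"], registry, BASELINE_GRID
    )


@pytest.fixture(scope="session")
def test_matrix(splits, registry):
    return assemble_matrix(
        splits["pos_test"] + splits["neg_test"], registry, BASELINE_GRID
    )


@pytest.fixture(scope="session")
def lr_model(train_matrix):
    return train(ModelConfig.linear(seed=SEED), train_matrix)


@pytest.fixture(scope="session")
def rf_model(train_matrix):
    # forest scaled down from the full 30 000 trees for desk-scale runs
    return train(ModelConfig.forest(n_trees=300, seed=SEED), train_matrix)


@pytest.fixture(scope="session")
def full_element_truth():
    """Genes carrying one full-element site each: every inclusion
    probability 1, no decoys, no alternative sites (planting fidelity kept
    at the benchmark defaults)."""
    params = {
        name: ElementParams(inclusion=1.0, strength=p.strength)
        for name, p in default_element_params().items()
    }
    return generate(
        GeneratorSpec(
            n_genes=40,
            element_params=params,
            decoy_rate_per_kb=0.0,
            alt_site_prob=0.0,
            seed=SEED,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
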