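import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from trmscore import DropletDataset, SimConfig, generate_dataset
from trmscore.diffexpr import normalize_log
from trmscore.pipeline import _truth_labels


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A fast five-cluster config with all artifact classes present."""
    kwargs = dict(
        n_genes=1000,
        n_cells_per_cluster=[120] * 5,
        n_empty_droplets=400,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def clean_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """Artifact-free config: every droplet is a single live cell."""
    kwargs = dict(
        n_genes=1000,
        n_cells_per_cluster=[120] * 5,
        n_empty_droplets=0,
        doublet_fraction=0.0,
        dying_fraction=0.0,
        sticky_fraction=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = small_sim_config(seed=11)
    dataset, truth = generate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def clean_expr():
    """Normalized expression of an artifact-free dataset with truth labels."""
    cfg = clean_sim_config(seed=21)
    dataset, truth = generate_dataset(cfg)
    expr = normalize_log(dataset, cell_labels=_truth_labels(truth))
    return cfg, dataset, truth, expr


def tiny_dataset(counts, mito_rows=(0,), hashtags=None, isotypes=None):
    """Hand-built DropletDataset from a dense count array."""
    counts = np.asarray(counts)
    g, n = counts.shape
    mito = np.zeros(g, dtype=bool)
    mito[list(mito_rows)] = True
    if hashtags is None:
        hashtags = np.full((2, n), 400)
    if isotypes is None:
        isotypes = np.ones((2, n), dtype=int)
    return DropletDataset(
        counts=sp.csr_matrix(counts),
        hashtag_counts=np.asarray(hashtags),
        isotype_counts=np.asarray(isotypes),
        gene_names=[f"g{i}" for i in range(g)],
        mito_flags=mito,
        barcode_ids=[f"bc{i}" for i in range(n)],
    )


@pytest.fixture(autouse=True)
def _silence_topk_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
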