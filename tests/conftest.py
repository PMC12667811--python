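"""Shared fixtures: small seeded synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

from devatlas import simulate
from devatlas import threshold as thr


def make_detection_matrix(
    n_genes: int, n_classes: int, n_truth: int, seed: int
) -> np.ndarray:
    """Gene x class detection probabilities with a clear on/off structure.

    The first n_truth genes are 'ground-truth' genes: on (p in
    [0.6, 0.95]) in a random subset of classes and near-silent
    (p in [0.005, 0.05]) elsewhere.  Remaining genes get intermediate
    sparse patterns.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.005, 0.05, size=(n_genes, n_classes))
    for g in range(n_truth):
        on = rng.random(n_classes) < rng.uniform(0.2, 0.8)
        if not on.any():
            on[rng.integers(n_classes)] = True
        p[g, on] = rng.uniform(0.6, 0.95, size=int(on.sum()))
    for g in range(n_truth, n_genes):
        on = rng.random(n_classes) < 0.3
        p[g, on] = rng.uniform(0.2, 0.7, size=int(on.sum()))
    return p


@pytest.fixture(scope="session")
def calib_fixture():
    """Profile + ground truth: 40 truth genes, 10 classes, seed 11."""
    n_genes, n_classes, n_truth = 100, 10, 40
    cfg = simulate.SimulationConfig(
        n_classes=n_classes,
        cells_per_class=100,
        n_genes=n_genes,
        detection_prob=make_detection_matrix(n_genes, n_classes, n_truth, seed=11),
        nb_mean=2.0,
        nb_dispersion=1.0,
        libsize_sigma=0.3,
        seed=11,
    )
    ds = simulate.generate_counts(cfg)
    norm = thr.size_factor_normalize(ds)
    profile = thr.aggregate_profiles(norm, ds.cell_class)
    truth = simulate.generate_ground_truth(
        cfg, p_on=0.5, genes=[f"gene{g}" for g in range(n_truth)]
    )
    return {"config": cfg, "dataset": ds, "profile": profile, "truth": truth}


@pytest.fixture()
def toy_profile():
    """Hand-built pseudobulk profile for closed-form thresholding checks."""
    prop = pd.DataFrame(
        {
            "PHC": [0.423, 0.50, 0.90],
            "AVA": [0.015, 0.02, 0.015],
            "AVM": [0.020, 0.30, 0.012],
        },
        index=["php-3", "geneB", "geneC"],
    )
    tpm = pd.DataFrame(
        np.full(prop.shape, 100.0), index=prop.index, columns=prop.columns
    )
    n_cells = pd.Series([50, 50, 50], index=prop.columns)
    return thr.PseudobulkProfile(proportion=prop, tpm=tpm, n_cells=n_cells)
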