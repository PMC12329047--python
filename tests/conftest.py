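"""Shared fixtures: small synthetic references reused across test modules."""

import numpy as np
import pytest

from ptalign.align import train_predictor
from ptalign.reference import bin_reference
from ptalign.synth import SynthConfig, make_reference
from ptalign.synth import true_trajectory_genes


@pytest.fixture(scope="session")
def perm_setup():
    """A permutation-test-sized reference: 300 cells, 600 genes, 60 trajectory."""
    cfg = SynthConfig(seed=11, n_cells=300, n_genes=600, n_traj_genes=60)
    ref, truth = make_reference(cfg)
    genes = true_trajectory_genes(truth)
    binned = bin_reference(ref, genes, n_bins=15)
    model = train_predictor(ref, binned, genes, seed=11)
    return cfg, ref, truth, genes, binned, model


@pytest.fixture(scope="session")
def align_setup():
    """A mid-sized reference for alignment tests: 600 cells, 20 bins."""
    cfg = SynthConfig(seed=7, n_cells=600, n_genes=300, n_traj_genes=100)
    ref, truth = make_reference(cfg)
    genes = true_trajectory_genes(truth)
    binned = bin_reference(ref, genes, n_bins=20)
    model = train_predictor(ref, binned, genes, seed=7)
    return cfg, ref, truth, genes, binned, model
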