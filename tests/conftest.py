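import datetime as dt

import numpy as np
import pytest

from daycast import simulate
from daycast.io_model import Environment, MarkerMatrix, MetDataset, PhenotypeRecord


@pytest.fixture(scope="session")
def small_met():
    """A compact simulated MET shared by read-only tests."""
    cfg = simulate.SimConfig(n_genotypes=12, n_markers=80, n_environments=8,
                             seed=7)
    dataset, truth = simulate.simulate_met(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def small_series(small_met):
    dataset, _ = small_met
    return simulate.build_series(dataset)


@pytest.fixture()
def tiny_dataset():
    """Hand-built 3-genotype x 2-environment dataset with markers."""
    envs = [
        Environment("E1", 36.0, dt.date(2016, 5, 20)),
        Environment("E2", 34.5, dt.date(2016, 6, 5)),
    ]
    phen = [
        PhenotypeRecord("G1", "E1", 90), PhenotypeRecord("G1", "E2", 84),
        PhenotypeRecord("G2", "E1", 95), PhenotypeRecord("G2", "E2", 88),
        PhenotypeRecord("G3", "E1", 100),
    ]
    markers = MarkerMatrix(
        ["G1", "G2", "G3"], ["M1", "M2", "M3", "M4"],
        np.array([[0, 2, 1, 0], [2, 0, 1, 2], [0, 2, 0, 1]], dtype=float))
    return MetDataset(envs, phen, markers)
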