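import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the reference oracles

from epiquant import synthetic as syn


@pytest.fixture(scope="session")
def burden_world():
    """One fully loaded synthetic recording: seizure + spikes + trains."""
    cfg = syn.EegSimConfig(
        duration_s=120.0,
        baseline_amp_uV=80.0,
        spike_specs=((60.0, 400.0, 30.0), (65.0, 700.0, 20.0), (70.0, 300.0, 40.0)),
        train_specs=((90.0, 4, 0.3, 350.0), (100.0, 3, 0.8, 500.0)),
        seizure_specs=((30.0, 20.0, 4.0),),
        seed=7,
    )
    rec, truth = syn.gen_eeg(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def myelin_world():
    cfg = syn.FiberSimConfig(n_fibers=20, pathological_fraction=0.3, seed=11)
    img, truth = syn.gen_myelin_image(cfg)
    return cfg, img, truth


@pytest.fixture(scope="session")
def ifpair_world():
    cfg = syn.PlaqueSimConfig(n_plaques=12, coloc_fraction=0.75, seed=5)
    green, red, truth = syn.gen_if_pair(cfg)
    return cfg, green, red, truth


@pytest.fixture(scope="session")
def counts_world():
    genes = tuple(f"Gene{i + 1:04d}" for i in range(40, 44))
    cfg = syn.CountSimConfig(
        n_genes=1500,
        cells_per_type={"OL": 150, "Neuron": 150},
        planted_sets=(
            syn.PlantedSet("sig", genes, log2_fold=1.0, cell_type="OL", group="TLE"),
        ),
        seed=13,
    )
    matrix, truth = syn.gen_count_matrix(cfg)
    return cfg, matrix, truth
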