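"""Shared fixtures: synthetic datasets and pipeline runs.

The full default dataset (600 DHSs, 100 per class, seed 1) and its
pipeline run are session-scoped because several recovery tests measure
different properties of the same run.
"""

from dataclasses import replace

import pytest

from divtx.pipeline import run_pipeline
from divtx.synthetic_data import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small dataset (120 DHSs) for structural / file-format tests."""
    return generate_dataset(replace(SimulationConfig(), n_per_class=20),
                            seed=7)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 600 DHSs, 6 planted classes, seed 1."""
    return generate_dataset(SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def default_run(default_dataset):
    ds = default_dataset
    return run_pipeline(
        ds.ctss, ds.libraries, ds.dhss, ds.genes, ds.chrom_lengths,
        genome=ds.genome, starr=ds.starr, tads=ds.tads,
        interactions=ds.interactions,
    )
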