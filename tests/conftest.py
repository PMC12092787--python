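"""Shared fixtures: small seeded synthetic datasets and their decompositions."""

import numpy as np
import pytest

import sbmorph as sm


@pytest.fixture(scope="session")
def default_cfg():
    """Study-scale synthetic design: 20/20 subjects, 4 sources, 24x28x24 grid."""
    return sm.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(default_cfg):
    """(VolumeSet, participants, ground truth) for the default design."""
    return sm.synthesize_dataset(default_cfg)


@pytest.fixture(scope="session")
def measure(dataset):
    """Measure matrix + mask for the default dataset."""
    vs, table, gt = dataset
    mask = sm.build_mask(vs)
    return sm.vectorize(vs, mask)


@pytest.fixture(scope="session")
def decomposition(measure):
    """A stability-selected decomposition of the default dataset (k=4)."""
    return sm.run_icasso(measure, 4, n_runs=5, seed=7)


@pytest.fixture(scope="session")
def small_cfg():
    """Tiny, fast design for pipeline/CLI tests."""
    return sm.SyntheticConfig(
        grid_shape=(14, 14, 14),
        k_true=2,
        blobs_per_source=2,
        blob_sigma_mm=4.5,
        group_effect=(0.0, 2.0),
        n_patients=6,
        n_controls=6,
        clinical_link=sm.ClinicalLink(source=1, column="magnification", r=-0.6),
        seed=3,
    )
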