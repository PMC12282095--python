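"""Shared fixtures for the test suite."""

from pathlib import Path

import numpy as np
import pytest

from nrcd import CohortConfig, generate_cohort

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort reused by tests that only need plausible tables."""
    cfg = CohortConfig(n_low=12, n_high=8, n_tcd=15, n_taxa=25,
                       n_backbone_edges=30, n_differential_pairs=4,
                       n_metabolites=15, n_coupled_metabolites=6)
    return generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort (87 samples, 50 taxa)."""
    return generate_cohort(CohortConfig(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def annotation_path():
    return DATA_DIR / "annotation.tsv"
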