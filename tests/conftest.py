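"""Shared fixtures: a small simulated cohort and a fast analysis config."""

from __future__ import annotations

import logging

import pytest

from gemcov.config import AnalysisConfig, SimConfig
from gemcov.covariation import build_association_map
from gemcov.preprocess import preprocess_cohort
from gemcov.simulate import generate_cohort
from gemcov.util import setup_logging

setup_logging(logging.WARNING)


@pytest.fixture(scope="session")
def fast_config() -> AnalysisConfig:
    """Analysis config with reduced hub-set sizes and a fast RF protocol
    (no hyperparameter search, few repeats) for small test cohorts."""
    return AnalysisConfig(
        n_hvg_genes=60, n_hvg_metabolites=20, n_hub_genes=8,
        n_hub_metabolites=5, n_specific_hubs=3, n_pan_hubs=5,
        n_density_perms=50, rf_repeats_metabolite=4, rf_repeats_severity=6,
        rf_search=False, rf_n_estimators_fixed=30, seed=11)


@pytest.fixture(scope="session")
def toy_sim() -> SimConfig:
    return SimConfig(
        n_patients=80, n_celltypes=3, n_genes=60, n_metabolites=20,
        n_planted_pairs=4, n_planted_hub_genes=1, n_planted_hub_metabolites=1,
        hub_fanout=6, n_kl_metabolites=2, pathway_count=5, seed=11)


@pytest.fixture(scope="session")
def toy_data(toy_sim):
    """(cohort, truth, pathway gene sets, pathway metabolite sets)."""
    return generate_cohort(toy_sim)


@pytest.fixture(scope="session")
def toy_pre(toy_data, fast_config):
    cohort, *_ = toy_data
    return preprocess_cohort(cohort, fast_config)


@pytest.fixture(scope="session")
def toy_assoc(toy_pre, fast_config):
    return build_association_map(toy_pre, fast_config)
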