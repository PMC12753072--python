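"""Shared fixtures: the default synthetic landscape and a trained model.

Session-scoped so the expensive pieces (network training, variant scanning)
are built once and shared by every test that inspects them.
"""

import warnings

import numpy as np
import pytest

from chromrisk import allelic, chromatin_model as cm, synthetic

warnings.filterwarnings("ignore", message="scores are correlated")


@pytest.fixture(scope="session")
def default_spec():
    return synthetic.SimulationSpec(seed=1)


@pytest.fixture(scope="session")
def bundle(default_spec):
    """The default planted landscape every recovery test runs on."""
    return synthetic.simulate_bundle(default_spec)


@pytest.fixture(scope="session")
def training_set(bundle):
    return cm.build_training_set(
        bundle["genome"], bundle["peaksets"]["LE2"], L=200,
        excluded_chrom="chrB", seed=5)


@pytest.fixture(scope="session")
def trained_model(training_set):
    config = cm.ModelConfig.small(cv_folds=0, seed=7)
    model, _ = cm.train_model(config, training_set)
    return model


@pytest.fixture(scope="session")
def scored_variants(trained_model, bundle):
    return allelic.scan_variants(trained_model, bundle["genome"],
                                 bundle["variants"])


@pytest.fixture(scope="session")
def tiny_spec():
    """A miniature landscape for structural (non-recovery) tests."""
    return synthetic.SimulationSpec(
        seed=3, chrom_lengths={"chrA": 120_000, "chrB": 120_000},
        peaks_per_type=20, cells_per_type=15, n_variants=300, n_ld_blocks=40)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_spec):
    return synthetic.simulate_bundle(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
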