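import numpy as np
import pytest

from radbench import CohortConfig, generate_cohort, generate_paired_cohorts


@pytest.fixture(scope="session")
def small_cohort():
    """100 samples x 300 genes, planted signal, mild noise."""
    cfg = CohortConfig(
        n_samples=100,
        n_tissues=5,
        n_genes=300,
        n_signal_genes=20,
        signal_effect=1.5,
        survival_noise_sd=0.03,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted signal: outcome independent of expression."""
    cfg = CohortConfig(
        n_samples=100,
        n_tissues=5,
        n_genes=300,
        n_signal_genes=0,
        signal_effect=0.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def paired_cohorts():
    """Discovery (150) / validation (60) with a shared strong signal."""
    disc = CohortConfig(
        n_samples=300,
        n_tissues=8,
        n_genes=400,
        n_signal_genes=10,
        signal_effect=3.0,
        expression_noise_sd=0.1,
        latent_noise_sd=0.3,
        survival_noise_sd=0.0,
        seed=21,
    )
    valid = CohortConfig(
        n_samples=60,
        n_tissues=5,
        n_genes=400,
        n_signal_genes=10,
        signal_effect=3.0,
        expression_noise_sd=0.1,
        latent_noise_sd=0.3,
        survival_noise_sd=0.0,
        dose_grid=(2.0, 4.0, 6.0),
        seed=22,
    )
    return generate_paired_cohorts(disc, valid, shared_gene_fraction=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
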