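import numpy as np
import pytest

from exemplarmix import (
    ExemplarMemory,
    FitConfig,
    GenerationRegime,
    GridConfig,
    generate_judgments,
    run_cell,
    sample_design,
)


@pytest.fixture
def table1_memory():
    """Two 2-cue exemplars with criteria 3 and 7; probe [0,1] matches the first."""
    return ExemplarMemory(cues=[[0, 1], [1, 1]], criteria=[3.0, 7.0])


@pytest.fixture
def tiny_fit_config():
    """Very short MCMC schedule for unit tests of the fitting machinery."""
    return FitConfig(
        chains=2, draws_per_chain=600, burn_in=200, adaptation=600, thin=1, seed=123
    )


@pytest.fixture
def dataset_factory():
    """Build one synthetic judgment dataset for a given (s, P_r, seed)."""

    def make(s_true=0.3, recall_prob=0.0, noise_sd=0.0, seed=0, n_cues=5, n_exemplars=12):
        rng = np.random.default_rng(seed)
        design = sample_design(rng, n_cues=n_cues, n_exemplars=n_exemplars)
        regime = GenerationRegime(s_true=s_true, recall_prob=recall_prob, noise_sd=noise_sd)
        return design, generate_judgments(design, regime, rng)

    return make


# ---------------------------------------------------------------------------
# Recovery cells shared by the acceptance tests.  Thirty replications per
# cell of the full pipeline (fresh design, data generation, three fits,
# Bayes factor, both RMSEs), at the desk-scale MCMC schedule.
# ---------------------------------------------------------------------------

RECOVERY_CELLS = [(0.8, 1.0), (0.8, 0.5), (0.8, 0.1), (0.1, 1.0), (0.001, 0.1)]


@pytest.fixture(scope="session")
def recovery_grid_config():
    return GridConfig(replications=30, master_seed=7)


@pytest.fixture(scope="session")
def recovery_cells(recovery_grid_config):
    return {
        (s, pr): run_cell(s, pr, recovery_grid_config) for s, pr in RECOVERY_CELLS
    }
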