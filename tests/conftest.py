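import numpy as np
import pandas as pd
import pytest

from crnpipe import SimConfig, simulate_cohort, simulate_trial_amplitudes
from crnpipe.model import build_design_matrix


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects x 12 trials: small enough for brute-force oracles."""
    cfg = SimConfig(group_sizes=(1, 1, 1), n_blocks=1, go_per_block=10, nogo_per_block=2, miss_rate=0.2, seed=5)
    trials, traits, truth = simulate_cohort(cfg)
    return trials, traits, truth


@pytest.fixture(scope="session")
def tiny_design(tiny_cohort):
    trials, traits, truth = tiny_cohort
    amps = simulate_trial_amplitudes(trials, traits, truth, seed=6)
    design = build_design_matrix(amps, traits, conditions=("gain", "loss", "control"))
    return design, amps, traits


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects x 5 blocks with enough misses for ErrN variance."""
    cfg = SimConfig(group_sizes=(10, 10, 10), n_blocks=5, miss_rate=0.1, seed=11)
    trials, traits, truth = simulate_cohort(cfg)
    return trials, traits, truth


@pytest.fixture(scope="session")
def small_amps(small_cohort):
    trials, traits, truth = small_cohort
    return simulate_trial_amplitudes(trials, traits, truth, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_rank1_outcomes(noise: float = 0.5, seed: int = 3, n: int = 200, rank2: bool = False):
    """Subject-level outcomes with known low-rank structure (for RRR tests)."""
    from crnpipe.behavior import OUTCOME_COLUMNS, build_rrr_predictors

    gen = np.random.default_rng(seed)
    traits = pd.DataFrame(
        {
            "subject": np.arange(n),
            "promotion": gen.normal(3.8, 0.6, n),
            "prevention": gen.normal(3.3, 0.9, n),
        }
    )
    outcomes = pd.DataFrame({"subject": np.arange(n), "condition": gen.choice(["gain", "loss", "control"], n)})
    X = build_rrr_predictors(outcomes, traits)
    a_true = np.array([0.5, 0.8, -0.3, 0.2, 0.0, 0.0, 0.4, -0.2])
    w_true = np.array([1.0, -0.5, 0.3, 0.7])
    Y = np.outer(X @ a_true, w_true) + noise * gen.standard_normal((n, 4))
    if rank2:
        a2 = np.array([-0.4, 0.1, 0.6, -0.5, 0.3, 0.0, 0.0, 0.5])
        w2 = np.array([0.3, 0.9, -0.6, 0.4])
        Y += np.outer(X @ a2, w2)
    for i, c in enumerate(OUTCOME_COLUMNS):
        outcomes[c] = Y[:, i]
    return outcomes, traits, np.outer(a_true, w_true) / Y.std(axis=0)[None, :]
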