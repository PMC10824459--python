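import numpy as np
import pytest

from ambigchoice import (
    CohortSpec,
    SubjectParams,
    generate_session,
    simulate_agent,
    simulate_cohort,
    trials_to_frame,
)
from ambigchoice.task_design import TrialDesign


@pytest.fixture(scope="session")
def session40():
    return generate_session(40, seed=7)


@pytest.fixture(scope="session")
def default_params():
    return SubjectParams()


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects x 40 trials with choices, as a trial-table DataFrame."""
    ds, _ = simulate_cohort(CohortSpec(n_subjects=3, session_template="fmri", seed=5))
    return ds


@pytest.fixture(scope="session")
def noisy_dataset():
    """Study-calibrated cohort (stochastic choices), 3 subjects x 60 trials."""
    from ambigchoice import study_cohort

    ds, _ = simulate_cohort(study_cohort(
        n_subjects=3, session_template="custom", n_trials=60, block_size=10,
        seed=17))
    return ds


@pytest.fixture
def ambiguous_design():
    return TrialDesign(
        subject_id="s01", block=0, trial_index=0,
        p_obj_left=0.6, p_obj_right=0.4, p_a=0.4,
        p_obs_left=0.36, p_obs_right=0.24,
        reward_left=40.0, reward_right=60.0,
        condition="ambiguity",
    )


def random_design(rng: np.random.Generator) -> TrialDesign:
    """One random valid trial, ambiguous with probability 1/2."""
    session = generate_session(2, seed=int(rng.integers(2 ** 31)), block_size=1)
    return session[int(rng.integers(2))]


def random_params(rng: np.random.Generator, **fixed) -> SubjectParams:
    draw = dict(
        alpha=float(rng.uniform(0.2, 1.5)),
        beta1=float(rng.uniform(-1.0, 6.0)),
        beta0=float(rng.uniform(-1.0, 1.0)),
        gamma=float(rng.uniform(0.35, 2.5)),
        tau_i=float(rng.uniform(0.0, 2.5)),
        tau_b=float(rng.uniform(0.1, 0.9)),
        w_r=float(rng.uniform(-0.5, 0.5)),
        beta_ppe=float(rng.uniform(-1.0, 0.5)),
        beta_val=float(rng.uniform(-0.5, 0.5)),
    )
    draw.update(fixed)
    return SubjectParams(**draw)
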