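"""Model mathematics: hand-checked values, reductions, properties."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ambigchoice import (
    ChoiceRecord,
    SubjectParams,
    allocated_probability,
    assigned_probability,
    choice_probability,
    decision_value,
    discount_model_probability,
    effective_tau_i,
    prediction_errors,
    probability_weight,
    subjective_value,
    trial_loglik,
)
from ambigchoice.task_design import TrialDesign

from conftest import random_design, random_params


def make_design(p_obj_left=0.6, p_a=0.0, p_obs_left=None, rewards=(40.0, 60.0)):
    if p_obs_left is None:
        p_obs_left = p_obj_left * (1 - p_a)  # proportional mask
    p_obs_right = (1 - p_a) - p_obs_left
    return TrialDesign(
        subject_id="s", block=0, trial_index=0,
        p_obj_left=p_obj_left, p_obj_right=1 - p_obj_left,
        p_a=p_a, p_obs_left=p_obs_left, p_obs_right=p_obs_right,
        reward_left=rewards[0], reward_right=rewards[1],
        condition="ambiguity" if p_a > 0 else "no-ambiguity",
    )


# --- hidden-mass assignment ------------------------------------------------

@pytest.mark.parametrize("p_a, tau_i, tau_b, expected", [
    (0.4, 1.0, 0.5, (0.2, 0.2)),
    (0.4, 0.0, 0.5, (0.0, 0.0)),
    (0.5, 1.8, 0.5, (0.45, 0.45)),
    (0.6, 1.0, 0.25, (0.15, 0.45)),
])
def test_assigned_probability_hand_values(p_a, tau_i, tau_b, expected):
    d = make_design(p_a=p_a) if p_a else make_design()
    d = replace(d, p_a=p_a, p_obs_left=d.p_obj_left * (1 - p_a),
                p_obs_right=d.p_obj_right * (1 - p_a),
                condition="ambiguity" if p_a else "no-ambiguity")
    assert assigned_probability(d, tau_i, tau_b) == pytest.approx(expected)


def test_allocation_ignoring_hidden_mass_renormalises_visible():
    d = make_design(p_obj_left=0.6, p_a=0.4)  # p_obs = (0.36, 0.24)
    assert allocated_probability(d, tau_i=0.0) == pytest.approx((0.6, 0.4))


def test_allocation_objective_reading_adds_half_mask():
    # tau_i = 1, tau_b = 0.5: denominator is exactly 1
    for p_a in (0.4, 0.8):
        d = make_design(p_obj_left=0.7, p_a=p_a)
        left, right = allocated_probability(d, tau_i=1.0, tau_b=0.5)
        assert left == pytest.approx(d.p_obs_left + p_a / 2)
        assert right == pytest.approx(d.p_obs_right + p_a / 2)


def test_allocation_symmetric_under_equal_visible():
    d = make_design(p_obj_left=0.55, p_a=0.4, p_obs_left=0.3)
    for tau in (0.0, 0.7, 1.9):
        assert allocated_probability(d, tau, 0.5) == pytest.approx((0.5, 0.5))


def test_allocation_degenerate_trial_raises():
    # fully masked display with no assignment: nothing to normalise
    class Bare:
        p_a = 0.8
        p_obs_left = 0.0
        p_obs_right = 0.0
    with pytest.raises(ValueError, match="degenerate"):
        allocated_probability(Bare(), tau_i=0.0)


@settings(max_examples=200, deadline=None)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 3.0), st.floats(0.05, 0.95))
def test_allocation_conserves_probability(seed, tau_i, tau_b):
    d = random_design(np.random.default_rng(seed))
    left, right = allocated_probability(d, tau_i, tau_b)
    assert left + right == pytest.approx(1.0, abs=1e-12)
    assert 0 < left < 1


# --- probability weighting --------------------------------------------------

def test_weighting_is_identity_at_unit_curvature():
    for p in np.linspace(0, 1, 21):
        assert probability_weight(p, 1.0) == pytest.approx(p, abs=1e-12)


def test_weighting_fixes_endpoints():
    for g in (0.4, 0.61, 1.7):
        assert probability_weight(0.0, g) == 0.0
        assert probability_weight(1.0, g) == 1.0


def test_weighting_known_value():
    # independent evaluation: 0.5**g / (2 * 0.5**g) ** (1/g) at g = 0.61
    g = 0.61
    expected = 0.5 ** g / (0.5 ** g + 0.5 ** g) ** (1 / g)
    assert expected == pytest.approx(0.4206, abs=5e-4)
    assert probability_weight(0.5, g) == pytest.approx(expected, abs=1e-12)


def test_weighting_monotone_for_moderate_curvature():
    # inverse-S family is monotone for gamma >= 0.3 (checked on a dense
    # grid); smaller curvature is a known non-monotonic regime
    for g in (0.3, 0.5, 0.8, 1.0, 2.0):
        w = [probability_weight(p, g) for p in np.linspace(0, 1, 501)]
        assert all(b >= a - 1e-12 for a, b in zip(w, w[1:]))


# --- value function ---------------------------------------------------------

def test_value_is_linear_without_curvature():
    p = SubjectParams(alpha=1.0)
    assert subjective_value(73.0, 27.0, p) == pytest.approx(73.0)


def test_value_known_curvature():
    p = SubjectParams(alpha=0.88)
    assert subjective_value(100.0, 1.0, p) == pytest.approx(57.54, abs=0.01)


def test_reward_bias_shifts_exponent_of_larger_reward_only():
    p = SubjectParams(alpha=0.8, w_r=0.2)
    assert subjective_value(70.0, 30.0, p, ambiguous=True) == pytest.approx(70.0)
    # smaller reward keeps the base exponent
    assert subjective_value(30.0, 70.0, p, ambiguous=True) == pytest.approx(30.0 ** 0.8)
    # and the shift is inert without ambiguity
    assert subjective_value(70.0, 30.0, p, ambiguous=False) == pytest.approx(70.0 ** 0.8)


# --- decision value and choice rule ----------------------------------------

def test_decision_value_zero_for_symmetric_options():
    d = make_design(p_obj_left=0.55, p_a=0.4, p_obs_left=0.3, rewards=(50.0, 60.0))
    d = replace(d, reward_left=60.0, reward_right=50.0)
    # equal P_all, equal rewards would give 0; check composed example instead
    d2 = make_design(p_obj_left=0.6, p_a=0.4)  # p_obs (0.36, 0.24)
    p = SubjectParams(alpha=1.0, gamma=1.0, tau_i=0.0)
    assert decision_value(d2, p) == pytest.approx(40 * 0.6 - 60 * 0.4, abs=1e-12)


def test_decision_value_reduces_to_expected_value():
    d = make_design(p_obj_left=0.7, p_a=0.5)
    p = SubjectParams(alpha=1.0, gamma=1.0, tau_i=1.3, tau_b=0.4)
    pl, pr = allocated_probability(d, 1.3, 0.4)
    assert decision_value(d, p) == pytest.approx(40 * pl - 60 * pr)


def test_decision_value_antisymmetric_under_side_swap():
    d = make_design(p_obj_left=0.65, p_a=0.6, p_obs_left=0.3)
    mirrored = replace(
        d, p_obj_left=d.p_obj_right, p_obj_right=d.p_obj_left,
        p_obs_left=d.p_obs_right, p_obs_right=d.p_obs_left,
        reward_left=d.reward_right, reward_right=d.reward_left,
    )
    p = SubjectParams(tau_b=0.5, w_r=0.0)
    assert decision_value(mirrored, p) == pytest.approx(-decision_value(d, p))


def test_choice_rule_midpoint_and_known_value():
    assert choice_probability(0.3, beta1=2.0, beta0=0.3) == 0.5
    assert choice_probability(0.5, beta1=2.0) == pytest.approx(0.7311, abs=1e-4)
    assert choice_probability(5.0, beta1=500.0) == pytest.approx(1.0, abs=1e-12)
    assert choice_probability(-5.0, beta1=500.0) == pytest.approx(0.0, abs=1e-12)


# --- trial-dependent assignment ---------------------------------------------

def test_effective_tau_defaults_to_base():
    p = SubjectParams(tau_i=1.3, beta_ppe=-0.9, beta_val=0.2)
    assert effective_tau_i(p) == 1.3
    assert effective_tau_i(p, prev_ppe=0.0, prev_valency=0) == 1.3


def test_effective_tau_ppe_adjustment_and_clamp():
    p = SubjectParams(tau_i=1.0, beta_ppe=-0.87)
    assert effective_tau_i(p, prev_ppe=0.5) == pytest.approx(0.565)
    p2 = SubjectParams(tau_i=0.1, beta_ppe=-0.87)
    assert effective_tau_i(p2, prev_ppe=0.9) == 0.0


def test_effective_tau_rejects_invalid_ppe():
    with pytest.raises(ValueError):
        effective_tau_i(SubjectParams(), prev_ppe=1.4)


# --- prediction errors -------------------------------------------------------

def test_prediction_errors_hand_values():
    d = make_design(p_obj_left=0.7, p_a=0.0)
    p = SubjectParams(tau_i=0.0)
    win = ChoiceRecord(design=d, choice="left", win=1)
    loss = ChoiceRecord(design=d, choice="left", win=0)
    ppe_w, _ = prediction_errors(win, p)
    ppe_l, _ = prediction_errors(loss, p)
    assert ppe_w == pytest.approx(0.3)
    assert ppe_l == pytest.approx(0.7)


def test_reward_prediction_error_uses_expected_reward():
    d = make_design(p_obj_left=0.4, rewards=(60.0, 40.0))
    rec = ChoiceRecord(design=d, choice="left", win=1)
    p = SubjectParams(tau_i=0.0)
    pl, _ = allocated_probability(d, 0.0, 0.5)
    _, rpe = prediction_errors(rec, p)
    assert rpe == pytest.approx(abs(60.0 - pl * 60.0))
    # the spec'd toy: P_all(chosen) = 0.5, reward 60, win
    assert abs(60 - 0.5 * 60) == 30


# --- discount comparator ------------------------------------------------------

def test_discount_limits_match_assignment_model():
    d = make_design(p_obj_left=0.65, p_a=0.6, p_obs_left=0.25)
    assert discount_model_probability(d, 0.0) == pytest.approx(
        allocated_probability(d, tau_i=1.0, tau_b=0.5))
    assert discount_model_probability(d, 1.0) == pytest.approx(
        allocated_probability(d, tau_i=0.0))


def test_discount_symmetry():
    d = make_design(p_obj_left=0.55, p_a=0.4, p_obs_left=0.3)
    assert discount_model_probability(d, 0.5) == pytest.approx((0.5, 0.5))


# --- likelihood ---------------------------------------------------------------

def test_loglik_of_even_odds_is_log_half():
    d = make_design(p_obj_left=0.55, p_a=0.4, p_obs_left=0.3)
    d = replace(d, reward_left=60.0, reward_right=50.0)
    # choose parameters making theta exactly 0.5: U = beta0
    p = SubjectParams(beta1=3.0, beta0=0.0, alpha=1.0, gamma=1.0)
    U = decision_value(d, p)
    p = replace(p, beta0=U)
    rec = ChoiceRecord(design=d, choice="left", win=1)
    assert trial_loglik(rec, p) == pytest.approx(math.log(0.5))


def test_loglik_sums_over_trials_match_per_trial_oracle():
    rng = np.random.default_rng(0)
    params = random_params(rng, beta_ppe=0.0, beta_val=0.0)
    recs = []
    for _ in range(3):
        d = random_design(rng)
        recs.append(ChoiceRecord(design=d, choice="left" if rng.random() < 0.5
                                 else "right", win=int(rng.random() < 0.5)))
    total = sum(trial_loglik(r, params) for r in recs)
    oracle = sum(_oracle_loglik(r, params) for r in recs)
    assert total == pytest.approx(oracle, abs=1e-10)


def test_loglik_monotone_in_inverse_temperature():
    d = make_design(p_obj_left=0.6, p_a=0.0)
    p0 = SubjectParams(alpha=1.0, gamma=1.0, beta0=0.0)
    U = decision_value(d, p0)
    rec = ChoiceRecord(design=d, choice="left" if U > 0 else "right", win=1)
    lls = [trial_loglik(rec, replace(p0, beta1=b)) for b in (0.5, 1, 2, 4, 8)]
    assert all(b >= a for a, b in zip(lls, lls[1:]))


def test_ambiguity_machinery_inert_without_mask():
    """p_a = 0 trials give identical likelihood for any tau/W_r setting."""
    rng = np.random.default_rng(1)
    for _ in range(50):
        d = random_design(rng)
        if d.p_a > 0:
            continue
        rec = ChoiceRecord(design=d, choice="left", win=1)
        base = random_params(rng, tau_i=0.0, tau_b=0.5, w_r=0.0)
        varied = replace(base, tau_i=2.3, tau_b=0.12, w_r=0.8)
        assert trial_loglik(rec, base) == pytest.approx(
            trial_loglik(rec, varied), abs=1e-12)


def _oracle_loglik(rec, prm):
    """From-scratch straight-line recomposition of the model equations,
    kept independent of the library implementation."""
    d = rec.design
    p_as_l = d.p_a * prm.tau_b * prm.tau_i
    p_as_r = d.p_a * (1 - prm.tau_b) * prm.tau_i
    num_l, num_r = d.p_obs_left + p_as_l, d.p_obs_right + p_as_r
    p_all_l = num_l / (num_l + num_r)
    p_all_r = num_r / (num_l + num_r)

    def pi(p, g):
        if p in (0.0, 1.0):
            return p
        return p ** g / (p ** g + (1 - p) ** g) ** (1 / g)

    amb = d.p_a > 0
    exp_l = prm.alpha + (prm.w_r if amb and d.reward_left >= d.reward_right else 0.0)
    exp_r = prm.alpha + (prm.w_r if amb and d.reward_right >= d.reward_left else 0.0)
    U = d.reward_left ** exp_l * pi(p_all_l, prm.gamma) \
        - d.reward_right ** exp_r * pi(p_all_r, prm.gamma)
    z = prm.beta1 * (U - prm.beta0)
    if z > 700:
        theta = 1.0
    elif z < -700:
        theta = 0.0
    else:
        theta = 1.0 / (1.0 + math.exp(-z))
    theta = min(max(theta, 1e-12), 1 - 1e-12)
    return math.log(theta if rec.choice == "left" else 1 - theta)


def test_likelihood_against_independent_recomposition():
    """1,000 random trial/parameter draws agree with the from-scratch
    oracle to 1e-10."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        d = random_design(rng)
        prm = random_params(rng)
        rec = ChoiceRecord(
            design=d,
            choice="left" if rng.random() < 0.5 else "right",
            win=int(rng.random() < 0.5),
        )
        assert trial_loglik(rec, prm) == pytest.approx(
            _oracle_loglik(rec, prm), abs=1e-10)
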