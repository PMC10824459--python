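"""Deterministic model mathematics.

The decision maker sees visible probability fractions ``p_obs`` and, on
ambiguous trials, a hidden fraction ``p_a``.  A fraction ``tau_i`` of the
hidden mass is assigned back to the options, split ``tau_b`` / ``1-tau_b``
between left and right; the resulting masses are renormalised to the
allocated probabilities ``P_all`` that enter valuation.  Values follow a
power utility ``v(x) = x**alpha``, probabilities are distorted by an
inverse-S weighting with curvature ``gamma``, and the signed subjective
value difference is mapped to a left-choice probability by a logistic
rule with inverse temperature ``beta1`` and bias ``beta0``.

All functions are pure; scalars in, scalars out.  The vectorised
likelihood used by the sampler lives in :mod:`ambigchoice.likelihood` and
is tested against these reference functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .task_design import TrialDesign

#: probability clamp keeping the Bernoulli log-likelihood finite
LIK_EPS = 1e-12


@dataclass(frozen=True)
class SubjectParams:
    """One subject's model parameters.

    alpha : value-curvature exponent (> 0); 1 = linear utility.
    beta1 : inverse temperature of the logistic choice rule.
    beta0 : choice bias (left/right) of the logistic rule.
    gamma : probability-weighting curvature (> 0); 1 = no distortion.
    tau_i : fraction of the hidden mass assigned to the options (>= 0).
    tau_b : laterality bias of the assignment, in (0, 1); 0.5 = none.
    w_r : exponent shift toward the larger reward under ambiguity
        (0 disables it).
    beta_ppe : coupling of the previous trial's probability prediction
        error onto tau_i (0 disables trial dependence).
    beta_val : coupling of the previous trial's feedback valency
        (win = 1 / loss = 0) onto tau_i.
    """

    alpha: float = 0.9
    beta1: float = 5.0
    beta0: float = 0.0
    gamma: float = 0.8
    tau_i: float = 1.8
    tau_b: float = 0.5
    w_r: float = 0.0
    beta_ppe: float = 0.0
    beta_val: float = 0.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.tau_i < 0:
            raise ValueError("tau_i must be >= 0")
        if not 0 < self.tau_b < 1:
            raise ValueError("tau_b must lie in (0, 1)")


@dataclass(frozen=True)
class ChoiceRecord:
    """A trial design plus the observed choice and feedback."""

    design: TrialDesign
    choice: str  # "left" | "right"
    win: int  # 1 = rewarded, 0 = not
    reward_obtained: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.choice not in ("left", "right"):
            raise ValueError(f"choice must be 'left' or 'right', got {self.choice!r}")
        if self.win not in (0, 1):
            raise ValueError("win must be 0 or 1")
        chosen_reward = (
            self.design.reward_left if self.choice == "left" else self.design.reward_right
        )
        expected = chosen_reward if self.win else 0.0
        if self.reward_obtained is None:
            object.__setattr__(self, "reward_obtained", expected)
        elif abs(self.reward_obtained - expected) > 1e-9:
            raise ValueError(
                f"reward_obtained={self.reward_obtained} inconsistent with "
                f"choice/win (expected {expected})"
            )

    @property
    def chosen_reward(self) -> float:
        return self.design.reward_left if self.choice == "left" else self.design.reward_right


def assigned_probability(design: TrialDesign, tau_i: float, tau_b: float = 0.5):
    """Hidden-mass assignments ``(P_as_left, P_as_right)``.

    ``P_as_left = p_a * tau_b * tau_i`` and symmetrically for the right
    option with weight ``1 - tau_b``.
    """
    if tau_i < 0:
        raise ValueError("tau_i must be >= 0")
    if not 0 < tau_b < 1:
        raise ValueError("tau_b must lie in (0, 1)")
    return design.p_a * tau_b * tau_i, design.p_a * (1.0 - tau_b) * tau_i


def allocated_probability(design: TrialDesign, tau_i: float, tau_b: float = 0.5):
    """Normalised allocation ``(P_all_left, P_all_right)`` entering valuation.

    The visible fractions plus the assigned hidden masses, renormalised
    so the pair sums to one.  With ``tau_i = 1`` and ``tau_b = 0.5`` this
    reduces to ``p_obs + p_a / 2`` (the objective-uncertainty reading).
    """
    as_l, as_r = assigned_probability(design, tau_i, tau_b)
    num_l = design.p_obs_left + as_l
    num_r = design.p_obs_right + as_r
    denom = num_l + num_r
    if denom <= 0:
        raise ValueError(
            "degenerate trial: no visible probability and no assignment "
            f"(p_obs=0, tau_i={tau_i})"
        )
    return num_l / denom, num_r / denom


def probability_weight(p: float, gamma: float) -> float:
    """Inverse-S probability weighting ``p**g / (p**g + (1-p)**g)**(1/g)``.

    Identity at ``gamma = 1``; fixes 0 and 1.  Known to lose monotonicity
    for very small curvature (roughly ``gamma < 0.28``); callers fitting
    data keep gamma well above that regime.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p in (0.0, 1.0):
        return p
    pg = p ** gamma
    return pg / (pg + (1.0 - p) ** gamma) ** (1.0 / gamma)


def subjective_value(
    x: float,
    other_x: float,
    params: SubjectParams,
    ambiguous: bool = False,
) -> float:
    """Power utility ``x**alpha``; on ambiguous trials the exponent of the
    (weakly) larger reward becomes ``alpha + w_r`` when the reward-bias
    variant is enabled."""
    if x <= 0:
        raise ValueError("rewards must be positive")
    exponent = params.alpha
    if ambiguous and params.w_r != 0 and x >= other_x:
        exponent = params.alpha + params.w_r
    return x ** exponent


def decision_value(
    design: TrialDesign,
    params: SubjectParams,
    tau_i: float | None = None,
) -> float:
    """Signed subjective value difference ``U`` (left minus right).

    ``U = v(x_l) pi(P_all_l) - v(x_r) pi(P_all_r)``.  ``tau_i`` may be
    overridden to evaluate trial-dependent assignment.
    """
    ti = params.tau_i if tau_i is None else tau_i
    ambiguous = design.p_a > 0
    p_l, p_r = allocated_probability(design, ti, params.tau_b)
    v_l = subjective_value(design.reward_left, design.reward_right, params, ambiguous)
    v_r = subjective_value(design.reward_right, design.reward_left, params, ambiguous)
    return v_l * probability_weight(p_l, params.gamma) - v_r * probability_weight(
        p_r, params.gamma
    )


def choice_probability(U: float, beta1: float, beta0: float = 0.0) -> float:
    """Logistic rule: probability of choosing left given ``U``."""
    z = -beta1 * (U - beta0)
    if z >= 0:
        e = math.exp(-z)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(z))


def effective_tau_i(
    params: SubjectParams,
    prev_ppe: float | None = None,
    prev_valency: int | None = None,
) -> float:
    """Trial-dependent assignment ratio.

    ``tau_eff = max(0, tau_i + beta_ppe * prev_ppe + beta_val * prev_valency)``;
    equals ``tau_i`` on the first trial of a block or when the couplings
    are disabled.
    """
    tau = params.tau_i
    if prev_ppe is not None:
        if not 0 <= prev_ppe <= 1:
            raise ValueError("prev_ppe must lie in [0, 1]")
        tau += params.beta_ppe * prev_ppe
    if prev_valency is not None:
        tau += params.beta_val * prev_valency
    return max(0.0, tau)


def trial_loglik(
    record: ChoiceRecord,
    params: SubjectParams,
    prev: tuple[float, int] | None = None,
) -> float:
    """Bernoulli log-likelihood of one observed choice.

    ``prev`` is the previous trial's ``(ppe, valency)`` within the same
    block; when supplied and the couplings are enabled, the assignment
    ratio becomes :func:`effective_tau_i`.  The choice probability is
    clamped to ``[LIK_EPS, 1 - LIK_EPS]``.
    """
    if record.choice not in ("left", "right"):
        raise ValueError("record has no valid choice")
    tau = params.tau_i
    if prev is not None and (params.beta_ppe != 0 or params.beta_val != 0):
        tau = effective_tau_i(params, prev[0], prev[1])
    U = decision_value(record.design, params, tau_i=tau)
    theta = choice_probability(U, params.beta1, params.beta0)
    theta = min(max(theta, LIK_EPS), 1.0 - LIK_EPS)
    return math.log(theta) if record.choice == "left" else math.log(1.0 - theta)


def prediction_errors(
    record: ChoiceRecord,
    params: SubjectParams,
    tau_i: float | None = None,
):
    """Unsigned prediction errors at feedback.

    ppe = ``|win - P_all(chosen)|`` (probability prediction error, in
    [0, 1]); rpe = ``|reward_obtained - P_all(chosen) * reward(chosen)|``
    (reward prediction error vs the expected reward of the chosen
    option).
    """
    ti = params.tau_i if tau_i is None else tau_i
    p_l, p_r = allocated_probability(record.design, ti, params.tau_b)
    p_chosen = p_l if record.choice == "left" else p_r
    ppe = abs(record.win - p_chosen)
    rpe = abs(record.reward_obtained - p_chosen * record.chosen_reward)
    return ppe, rpe


def discount_model_probability(design: TrialDesign, beta_amb: float):
    """Comparator model: linear discount of the hidden area.

    Each side receives ``p_obs + (p_a / 2) * (1 - beta_amb)``,
    renormalised over sides.  ``beta_amb > 0`` is ambiguity aversion,
    ``< 0`` ambiguity seeking; ``beta_amb = 0`` matches ``tau_i = 1``
    (unbiased) and ``beta_amb = 1`` matches ``tau_i = 0``.
    """
    half = design.p_a / 2.0 * (1.0 - beta_amb)
    num_l = design.p_obs_left + half
    num_r = design.p_obs_right + half
    denom = num_l + num_r
    if denom <= 0 or num_l < 0 or num_r < 0:
        raise ValueError("discount parameter produces negative probability mass")
    return num_l / denom, num_r / denom
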