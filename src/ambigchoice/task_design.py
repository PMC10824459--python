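"""PDM task sessions: trial generation and trial-table I/O.

A trial presents two options (left/right) with complementary objective
reward probabilities (``p_obj_left + p_obj_right = 1``) and misaligned
rewards: the more probable option always carries the strictly smaller
reward.  On ambiguous trials a mask hides a fraction ``p_a`` of the
probability bar, so only the visible fractions ``p_obs_*`` (summing to
``1 - p_a``) are shown; the mask never flips the visible ranking relative
to the objective one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: mask sizes used in the task (0 = no-ambiguity trial)
P_A_LEVELS = (0.0, 0.4, 0.5, 0.6, 0.7, 0.8)

#: canonical column order of the delimited trial table
TRIAL_COLUMNS = [
    "subject",
    "block",
    "trial",
    "condition",
    "tms",
    "p_obj_left",
    "p_obj_right",
    "p_a",
    "p_obs_left",
    "p_obs_right",
    "reward_left",
    "reward_right",
    "choice",
    "win",
    "reward_obtained",
]

_TMS_LABELS = ("none", "vertex", "ips", "ppc")
_PROB_TOL = 1e-9


class SchemaError(ValueError):
    """A trial table violates the documented schema or an invariant."""


@dataclass(frozen=True)
class TrialDesign:
    """One lottery pair before any choice is made.

    ``p_obj_*`` are the true (complementary) reward probabilities,
    ``p_obs_*`` the visible bar fractions after masking a fraction
    ``p_a`` of the display, and rewards are in points.
    """

    subject_id: str
    block: int
    trial_index: int
    p_obj_left: float
    p_obj_right: float
    p_a: float
    p_obs_left: float
    p_obs_right: float
    reward_left: float
    reward_right: float
    condition: str = "no-ambiguity"
    tms: str = "none"
    lottery_display: bool = False  # replication variant: independent lotteries

    def validate(self) -> None:
        d = self
        if not (0 < d.p_obj_left < 1 and 0 < d.p_obj_right < 1):
            raise SchemaError(f"objective probabilities outside (0,1): {d}")
        if abs(d.p_obj_left + d.p_obj_right - 1.0) > _PROB_TOL:
            raise SchemaError(f"objective probabilities not complementary: {d}")
        if not 0 <= d.p_a < 1:
            raise SchemaError(f"ambiguity fraction outside [0,1): {d}")
        if abs(d.p_obs_left + d.p_obs_right - (1.0 - d.p_a)) > 1e-6:
            raise SchemaError(
                f"visible fractions do not sum to 1 - p_a on trial {d.trial_index}"
            )
        if d.p_obs_left > d.p_obj_left + _PROB_TOL or d.p_obs_right > d.p_obj_right + _PROB_TOL:
            raise SchemaError(f"visible fraction exceeds objective probability: {d}")
        if (d.p_a == 0) != (d.condition == "no-ambiguity"):
            raise SchemaError(f"condition label inconsistent with p_a: {d}")
        if d.reward_left <= 0 or d.reward_right <= 0 or d.reward_left == d.reward_right:
            raise SchemaError(f"rewards must be positive and unequal: {d}")
        hi_prob_reward = d.reward_left if d.p_obj_left > d.p_obj_right else d.reward_right
        lo_prob_reward = d.reward_right if d.p_obj_left > d.p_obj_right else d.reward_left
        if hi_prob_reward >= lo_prob_reward:
            raise SchemaError(f"rewards not misaligned with probabilities: {d}")
        if d.tms not in _TMS_LABELS:
            raise SchemaError(f"unknown tms label {d.tms!r}")

    @property
    def higher_prob_side(self) -> str:
        return "left" if self.p_obj_left > self.p_obj_right else "right"


def _draw_p_obj_left(rng: np.random.Generator) -> float:
    # uniform on [0.15, 0.85] excluding a +-0.02 band around 0.5 so the
    # "highest probability" side is always well defined
    while True:
        p = rng.uniform(0.15, 0.85)
        if abs(p - 0.5) > 0.02:
            return p


def _draw_rewards(rng: np.random.Generator, reward_total: float, p_obj_left: float):
    # integer rewards summing to reward_total, larger reward on the
    # lower-probability side (misalignment); the asymmetry is wide enough
    # that the high-reward side carries the larger expected value on
    # average, so reward-seeking pays in points while lowering win rate
    lo = int(math.ceil(0.15 * reward_total))
    hi = int(math.floor(0.40 * reward_total))
    small = int(rng.integers(lo, hi + 1))
    large = int(round(reward_total)) - small
    if p_obj_left > 0.5:
        return float(small), float(large)
    return float(large), float(small)


def _draw_mask(rng: np.random.Generator, p_obj_left: float, p_a: float):
    """Split the hidden mass ``p_a`` between sides.

    The hidden amount taken from the left bar, ``a_l``, is drawn uniformly
    from the interval that keeps both visible fractions non-negative and
    preserves the visible ranking (same side on top as objectively).
    """
    p_l, p_r = p_obj_left, 1.0 - p_obj_left
    lo = max(0.0, p_a - p_r)  # a_r = p_a - a_l <= p_r
    hi = min(p_l, p_a)
    # ranking constraint: p_obs_l - p_obs_r = (p_l - p_r) - (a_l - a_r)
    # keeps the sign of p_l - p_r
    #   a_l - a_r < p_l - p_r  when p_l > p_r, i.e. a_l < (p_l - p_r + p_a)/2
    mid = (p_l - p_r + p_a) / 2.0
    if p_l > p_r:
        hi = min(hi, mid)
    else:
        lo = max(lo, mid)
    if not lo < hi:  # pragma: no cover - cannot happen for valid p_a < 1
        raise ValueError("empty mask interval")
    a_l = rng.uniform(lo, hi)
    return p_l - a_l, p_r - (p_a - a_l)


def generate_session(
    n_trials: int,
    p_a_levels: Iterable[float] = P_A_LEVELS,
    reward_total: float = 100.0,
    seed: int | np.random.Generator = 0,
    subject_id: str = "s01",
    block_size: int = 5,
    tms: str = "none",
    start_block: int = 0,
    lottery_display: bool = False,
) -> list[TrialDesign]:
    """Generate one session of the PDM task.

    Half the trials are no-ambiguity (``p_a = 0``) and half draw ``p_a``
    uniformly from the nonzero levels.  Trials are organised in blocks of
    ``block_size`` trials of the same condition, alternating between
    conditions (no-ambiguity first), as in the scanner sessions.

    Parameters
    ----------
    n_trials : even positive integer.
    p_a_levels : candidate mask fractions; zeros are ignored (the
        no-ambiguity half always uses ``p_a = 0``).
    reward_total : sum of the two integer rewards of a trial.
    seed : int seed or a ``numpy.random.Generator``.
    block_size : trials per same-condition block; must divide
        ``n_trials / 2``.
    tms : stimulation label attached to every trial of the session.
    lottery_display : replication-sample variant in which the options are
        presented as two independent lotteries; presentation metadata
        only, probabilities are unchanged.
    """
    if n_trials < 2 or n_trials % 2:
        raise ValueError("n_trials must be an even integer >= 2")
    nonzero = sorted({float(p) for p in p_a_levels if p != 0})
    if not nonzero:
        raise ValueError("p_a_levels must contain at least one nonzero level")
    if any(not 0 < p < 1 for p in nonzero):
        raise ValueError("p_a levels must lie in [0, 1)")
    if reward_total <= 0:
        raise ValueError("reward_total must be positive")
    half = n_trials // 2
    if half % block_size:
        raise ValueError("block_size must divide n_trials / 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    trials: list[TrialDesign] = []
    n_blocks = n_trials // block_size
    for b in range(n_blocks):
        ambiguous_block = b % 2 == 1  # alternate, no-ambiguity first
        for t in range(block_size):
            p_l = _draw_p_obj_left(rng)
            x_l, x_r = _draw_rewards(rng, reward_total, p_l)
            if ambiguous_block:
                p_a = float(rng.choice(nonzero))
                obs_l, obs_r = _draw_mask(rng, p_l, p_a)
                cond = "ambiguity"
            else:
                p_a, obs_l, obs_r, cond = 0.0, p_l, 1.0 - p_l, "no-ambiguity"
            trial = TrialDesign(
                subject_id=subject_id,
                block=start_block + b,
                trial_index=t,
                p_obj_left=p_l,
                p_obj_right=1.0 - p_l,
                p_a=p_a,
                p_obs_left=obs_l,
                p_obs_right=obs_r,
                reward_left=x_l,
                reward_right=x_r,
                condition=cond,
                tms=tms,
                lottery_display=lottery_display,
            )
            trial.validate()
            trials.append(trial)
    return trials


def session_template(
    name: str,
    seed: int | np.random.Generator = 0,
    subject_id: str = "s01",
    reward_total: float = 100.0,
) -> list[TrialDesign]:
    """Build a session matching one of the study designs.

    ``fmri``: 40 trials in 5-trial blocks (20 per condition).
    ``tms``: 240 trials in 10-trial blocks, as 6 runs of 40 trials with
    stimulation at ppc, ips or vertex (2 runs each, randomly ordered).
    ``replication``: 150 trials in 5-trial blocks, independent-lottery
    display.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if name == "fmri":
        return generate_session(40, seed=rng, subject_id=subject_id,
                                block_size=5, reward_total=reward_total)
    if name == "replication":
        return generate_session(150, seed=rng, subject_id=subject_id, block_size=5,
                                reward_total=reward_total, lottery_display=True)
    if name == "tms":
        runs = ["ppc", "ppc", "ips", "ips", "vertex", "vertex"]
        rng.shuffle(runs)
        trials: list[TrialDesign] = []
        for i, site in enumerate(runs):
            trials.extend(
                generate_session(40, seed=rng, subject_id=subject_id, block_size=10,
                                 reward_total=reward_total, tms=site, start_block=4 * i)
            )
        return trials
    raise ValueError(f"unknown session template {name!r}")


# ---------------------------------------------------------------------------
# trial-table I/O


def trials_to_frame(records: Sequence) -> pd.DataFrame:
    """Convert TrialDesign or ChoiceRecord sequences to the canonical table."""
    rows = []
    for r in records:
        design = getattr(r, "design", r)
        row = {
            "subject": design.subject_id,
            "block": design.block,
            "trial": design.trial_index,
            "condition": design.condition,
            "tms": design.tms,
            "p_obj_left": design.p_obj_left,
            "p_obj_right": design.p_obj_right,
            "p_a": design.p_a,
            "p_obs_left": design.p_obs_left,
            "p_obs_right": design.p_obs_right,
            "reward_left": design.reward_left,
            "reward_right": design.reward_right,
        }
        if hasattr(r, "choice"):
            row["choice"] = r.choice
            row["win"] = r.win
            row["reward_obtained"] = r.reward_obtained
        else:
            row["choice"] = ""
            row["win"] = ""
            row["reward_obtained"] = ""
        rows.append(row)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the schema; returns the frame."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    for i, row in df.iterrows():
        for col in ("p_obj_left", "p_obj_right", "p_a", "p_obs_left", "p_obs_right"):
            v = row[col]
            if not 0 <= v <= 1:
                raise SchemaError(f"row {i}: {col}={v} outside [0,1]")
        if abs(row.p_obs_left + row.p_obs_right - (1 - row.p_a)) > 1e-6:
            raise SchemaError(
                f"row {i}: p_obs_left + p_obs_right != 1 - p_a "
                f"({row.p_obs_left} + {row.p_obs_right} vs 1 - {row.p_a})"
            )
        if abs(row.p_obj_left + row.p_obj_right - 1) > 1e-6:
            raise SchemaError(f"row {i}: objective probabilities not complementary")
        choice = row.get("choice")
        if not _is_missing(choice) and str(choice) not in ("left", "right"):
            raise SchemaError(f"row {i}: choice must be 'left' or 'right', got {choice!r}")
    return df


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or v == ""


def read_trials(path) -> list:
    """Read a trial table; returns ChoiceRecords, or TrialDesigns for
    design-only rows (missing choice)."""
    from .model_core import ChoiceRecord

    df = pd.read_csv(path, float_precision="round_trip")
    validate_frame(df)
    out = []
    for _, row in df.iterrows():
        design = TrialDesign(
            subject_id=str(row.subject),
            block=int(row.block),
            trial_index=int(row.trial),
            p_obj_left=float(row.p_obj_left),
            p_obj_right=float(row.p_obj_right),
            p_a=float(row.p_a),
            p_obs_left=float(row.p_obs_left),
            p_obs_right=float(row.p_obs_right),
            reward_left=float(row.reward_left),
            reward_right=float(row.reward_right),
            condition=str(row.condition),
            tms=str(row.tms),
        )
        if _is_missing(row.get("choice")):
            out.append(design)
        else:
            out.append(
                ChoiceRecord(
                    design=design,
                    choice=str(row.choice),
                    win=int(row.win),
                    reward_obtained=float(row.reward_obtained),
                )
            )
    return out


def write_trials(records: Sequence, path) -> None:
    """Write records (TrialDesign or ChoiceRecord) as a UTF-8 CSV table.

    Floats are written with shortest round-tripping representation so a
    write/read cycle reproduces every fraction bit-exactly.
    """
    trials_to_frame(records).to_csv(
        path, index=False, float_format=lambda x: repr(float(x))
    )


def frame_to_trials(df: pd.DataFrame) -> list:
    """In-memory counterpart of :func:`read_trials`."""
    import io

    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return read_trials(buf)
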