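"""Vectorised trial-table likelihood used by the MCMC sampler.

This module re-expresses the per-trial mathematics of
:mod:`ambigchoice.model_core` as array operations over an entire dataset,
with per-subject parameter arrays.  Unit tests assert exact agreement
(1e-12) with the scalar reference functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import LIK_EPS

try:  # numba accelerates the per-trial kernel ~10x; numpy path is the
    # reference fallback and is what the unit tests cross-check
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

#: subject-level parameters in canonical order
PARAM_NAMES = (
    "alpha", "beta1", "beta0", "gamma", "tau_i", "tau_b",
    "w_r", "beta_ppe", "beta_val", "beta_amb",
)

PARIETAL_SITES = ("ips", "ppc")


@dataclass
class TrialData:
    """Column arrays of a trial table, ready for vectorised likelihoods."""

    subjects: list  # subject labels, index = code
    subj: np.ndarray  # (n,) int subject code per trial
    p_obs_l: np.ndarray
    p_obs_r: np.ndarray
    p_a: np.ndarray
    x_l: np.ndarray
    x_r: np.ndarray
    choice: np.ndarray  # (n,) 1 = left, 0 = right
    win: np.ndarray
    reward_obtained: np.ndarray
    ambiguous: np.ndarray  # bool
    ips: np.ndarray  # bool
    ppc: np.ndarray  # bool
    prev_idx: np.ndarray  # (n,) previous trial of same (subject, block), -1 if none
    pos: np.ndarray  # (n,) position within block

    def __post_init__(self):
        with np.errstate(divide="ignore"):
            self.log_x_l = np.log(self.x_l)
            self.log_x_r = np.log(self.x_r)

    @property
    def n_trials(self) -> int:
        return self.subj.size

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def parietal(self) -> np.ndarray:
        return self.ips | self.ppc

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialData":
        if "choice" not in df or df["choice"].isna().any():
            raise ValueError("dataset must contain a choice on every trial")
        subjects = sorted(df["subject"].astype(str).unique().tolist())
        code = {s: i for i, s in enumerate(subjects)}
        subj = df["subject"].astype(str).map(code).to_numpy(dtype=np.int64)
        tms = df["tms"].astype(str).to_numpy()
        n = len(df)
        # previous-trial pointers within (subject, block), in table order
        prev_idx = np.full(n, -1, dtype=np.int64)
        pos = np.zeros(n, dtype=np.int64)
        last: dict = {}
        blocks = df["block"].to_numpy()
        for i in range(n):
            key = (subj[i], blocks[i])
            if key in last:
                prev_idx[i] = last[key]
                pos[i] = pos[last[key]] + 1
            last[key] = i
        return cls(
            subjects=subjects,
            subj=subj,
            p_obs_l=df["p_obs_left"].to_numpy(dtype=float),
            p_obs_r=df["p_obs_right"].to_numpy(dtype=float),
            p_a=df["p_a"].to_numpy(dtype=float),
            x_l=df["reward_left"].to_numpy(dtype=float),
            x_r=df["reward_right"].to_numpy(dtype=float),
            choice=(df["choice"].astype(str) == "left").to_numpy(dtype=float),
            win=df["win"].to_numpy(dtype=float),
            reward_obtained=df["reward_obtained"].to_numpy(dtype=float),
            ambiguous=df["p_a"].to_numpy(dtype=float) > 0,
            ips=tms == "ips",
            ppc=tms == "ppc",
            prev_idx=prev_idx,
            pos=pos,
        )


def _weight(p: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Vectorised inverse-S probability weighting (safe at p = 0, 1)."""
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        pg = p ** g
        qg = (1.0 - p) ** g
        w = pg / (pg + qg) ** (1.0 / g)
    w = np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, w))
    return w


def _per_trial_param(values: np.ndarray, data: TrialData, deltas, name: str,
                     lo=None, hi=None) -> np.ndarray:
    """Expand a per-subject parameter to per-trial, applying additive
    TMS condition shifts on parietal-stimulation trials."""
    v = values[data.subj].astype(float)
    if deltas:
        if (name, "parietal") in deltas:
            v = np.where(data.parietal, v + deltas[(name, "parietal")], v)
        if (name, "ips") in deltas:
            v = np.where(data.ips, v + deltas[(name, "ips")], v)
        if (name, "ppc") in deltas:
            v = np.where(data.ppc, v + deltas[(name, "ppc")], v)
    if lo is not None or hi is not None:
        v = np.clip(v, lo, hi)
    return v


def _ll_kernel_py(num_l, num_r, log_x_l, log_x_r, amb, choice,
                  alpha, beta1, beta0, gamma, w_r, log_eps):
    # powers are evaluated as exp(g * log p); rewards enter through their
    # precomputed logs (log_x encodes the reward ordering via its sign
    # difference, used for the W_r exponent shift)
    n = num_l.size
    out = np.empty(n)
    for i in range(n):
        denom = num_l[i] + num_r[i]
        if not (denom > 0.0) or num_l[i] < 0.0 or num_r[i] < 0.0:
            out[i] = -np.inf
            continue
        pl = num_l[i] / denom
        g = gamma[i]
        if pl <= 0.0:
            wl, wr = 0.0, 1.0
        elif pl >= 1.0:
            wl, wr = 1.0, 0.0
        else:
            la = g * math.log(pl)
            lb = g * math.log1p(-pl)
            # wl = e^la / (e^la + e^lb)^(1/g), computed via logs
            if la > lb:
                lse = la + math.log1p(math.exp(lb - la))
            else:
                lse = lb + math.log1p(math.exp(la - lb))
            wl = math.exp(la - lse / g)
            wr = math.exp(lb - lse / g)
        el = alpha[i]
        er = alpha[i]
        if amb[i]:
            if log_x_l[i] >= log_x_r[i]:
                el += w_r[i]
            if log_x_r[i] >= log_x_l[i]:
                er += w_r[i]
        U = math.exp(el * log_x_l[i]) * wl - math.exp(er * log_x_r[i]) * wr
        if math.isnan(U):
            out[i] = -np.inf
            continue
        z = beta1[i] * (U - beta0[i])
        if math.isnan(z):
            out[i] = -np.inf
            continue
        if z >= 0.0:
            e = math.exp(-z)
            lt = -math.log1p(e)
            l1 = -z + lt
        else:
            e = math.exp(z)
            l1 = -math.log1p(e)
            lt = z + l1
        if lt < log_eps:
            lt = log_eps
        if l1 < log_eps:
            l1 = log_eps
        out[i] = lt if choice[i] > 0.5 else l1
    return out


_ll_kernel = _njit(cache=False)(_ll_kernel_py) if _njit is not None else _ll_kernel_py


def loglik_trials(
    data: TrialData,
    params: dict,
    *,
    discount: bool = False,
    trial_dependence: bool = False,
    deltas: dict | None = None,
) -> np.ndarray:
    """Per-trial Bernoulli log-likelihood.

    ``params`` maps parameter names to per-subject arrays; ``deltas``
    maps ``(param, site)`` to scalar additive TMS condition shifts with
    site in {"parietal", "ips", "ppc"}.  Returns shape ``(n_trials,)``;
    entries are ``-inf`` where parameters drive the model out of its
    numeric domain (the sampler rejects such states).
    """
    deltas = deltas or {}
    alpha = _per_trial_param(params["alpha"], data, deltas, "alpha", lo=1e-6)
    beta1 = _per_trial_param(params["beta1"], data, deltas, "beta1")
    beta0 = _per_trial_param(params["beta0"], data, deltas, "beta0")
    gamma = _per_trial_param(params["gamma"], data, deltas, "gamma", lo=1e-6)
    w_r = _per_trial_param(params["w_r"], data, deltas, "w_r")

    if discount:
        beta_amb = _per_trial_param(params["beta_amb"], data, deltas, "beta_amb", hi=1.0)
        half = data.p_a / 2.0 * (1.0 - beta_amb)
        num_l = data.p_obs_l + half
        num_r = data.p_obs_r + half
    else:
        tau_b = _per_trial_param(params["tau_b"], data, deltas, "tau_b",
                                 lo=1e-6, hi=1.0 - 1e-6)
        tau = _per_trial_param(params["tau_i"], data, deltas, "tau_i", lo=0.0)
        if trial_dependence:
            tau = _tau_path(data, params, deltas, tau, tau_b)
        num_l = data.p_obs_l + data.p_a * tau_b * tau
        num_r = data.p_obs_r + data.p_a * (1.0 - tau_b) * tau

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        return _ll_kernel(
            np.ascontiguousarray(num_l), np.ascontiguousarray(num_r),
            data.log_x_l, data.log_x_r, data.ambiguous, data.choice,
            alpha, beta1, beta0, gamma, w_r, float(np.log(LIK_EPS)),
        )


def _tau_path(data: TrialData, params, deltas, tau_base, tau_b) -> np.ndarray:
    """Trial-dependent assignment ratio along observed outcomes.

    Within each block, ``tau_eff(t) = max(0, tau_base(t)
    + beta_ppe * ppe(t-1) + beta_val * win(t-1))`` where the previous
    trial's ppe is evaluated at that trial's own effective ratio.
    Iterates over within-block positions (vectorised across blocks).
    """
    b_ppe = _per_trial_param(params["beta_ppe"], data, deltas, "beta_ppe")
    b_val = _per_trial_param(params["beta_val"], data, deltas, "beta_val")
    tau = tau_base.copy()
    ppe = np.zeros(data.n_trials)
    for p in range(int(data.pos.max()) + 1):
        sel = np.flatnonzero(data.pos == p)
        if p > 0:
            prev = data.prev_idx[sel]
            tau[sel] = np.maximum(
                0.0, tau_base[sel] + b_ppe[sel] * ppe[prev] + b_val[sel] * data.win[prev]
            )
        num_l = data.p_obs_l[sel] + data.p_a[sel] * tau_b[sel] * tau[sel]
        num_r = data.p_obs_r[sel] + data.p_a[sel] * (1 - tau_b[sel]) * tau[sel]
        denom = num_l + num_r
        with np.errstate(divide="ignore", invalid="ignore"):
            p_chosen = np.where(data.choice[sel] > 0.5, num_l, num_r) / denom
        ppe[sel] = np.abs(data.win[sel] - p_chosen)
    return tau


def subject_loglik(data: TrialData, ll: np.ndarray) -> np.ndarray:
    """Sum a per-trial log-likelihood by subject (``-inf`` propagates)."""
    out = np.zeros(data.n_subjects)
    bad = ~np.isfinite(ll)
    if bad.any():
        out[np.unique(data.subj[bad])] = -np.inf
        ok = ~np.isin(np.arange(data.n_subjects), np.unique(data.subj[bad]))
        sums = np.bincount(data.subj[~bad], weights=ll[~bad], minlength=data.n_subjects)
        out[ok] = sums[ok]
        return out
    return np.bincount(data.subj, weights=ll, minlength=data.n_subjects)
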