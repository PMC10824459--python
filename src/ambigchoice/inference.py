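"""Hierarchical Bayesian estimation of the choice-model family.

The generative hierarchy has two levels.  At the trial level, choices
are Bernoulli in the logistic choice probability of the cognitive model.
At the participant level, the positive parameters (alpha, gamma, tau_i)
are zero-truncated normals around group means, the unconstrained ones
(beta0, beta1, W_r, the trial-dependence couplings and the discount
comparator's beta_amb) are plain normals, and the laterality bias tau_b
is Beta with group mean and dispersion.  Hyperpriors are flat uniforms
for the positive means and all group sds, wide normals for the
unconstrained means, Beta(1,1) / flat for the tau_b mean / dispersion.

Posteriors are sampled with an adaptive Metropolis-within-Gibbs kernel:
per-parameter Gaussian random walks, vectorised across subjects (valid
because subjects are conditionally independent given the group level),
with proposal scales adapted toward a 0.44 acceptance rate during
burn-in only.  The sampling protocol follows the study's convention:
three chains with distinct seeds, at least 10,000 burn-in iterations,
10,000 retained iterations thinned by 10 (3,000 stored draws), and a
Gelman-Rubin gate with automatic burn-in extension on failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .likelihood import TrialData, loglik_trials, subject_loglik
from .task_design import trials_to_frame

# ---------------------------------------------------------------------------
# parameter kinds and prior constants

_POSITIVE = ("alpha", "gamma", "tau_i")
_REAL = ("beta1", "beta0", "w_r", "beta_ppe", "beta_val", "beta_amb")

MU_POS_BOUNDS = (0.01, 100.0)  # flat hyperprior on positive-parameter means
SIGMA_BOUNDS = (0.001, 100.0)  # flat hyperprior on all group sds
KAPPA_BOUNDS = (0.001, 100.0)  # flat hyperprior on tau_b dispersion
MU_REAL_SD = 100.0  # normal(0, 100) hyperprior on unconstrained means
DELTA_PRIOR_SD = 100.0  # normal(0, 100) prior on TMS condition shifts

# numerical support guards (far outside any plausible posterior mass)
_SUPPORT = {
    "alpha": (1e-9, 120.0),
    "gamma": (1e-9, 120.0),
    "tau_i": (0.0, 120.0),
    "tau_b": (1e-9, 1.0 - 1e-9),
    "beta1": (-1e3, 1e3),
    "beta0": (-1e3, 1e3),
    "w_r": (-1e3, 1e3),
    "beta_ppe": (-1e3, 1e3),
    "beta_val": (-1e3, 1e3),
    "beta_amb": (-10.0, 1.0),  # mass above 1 would turn probabilities negative
}

_NEUTRAL = {
    "alpha": 1.0, "beta1": 1.0, "beta0": 0.0, "gamma": 1.0,
    "tau_i": 0.0, "tau_b": 0.5, "w_r": 0.0,
    "beta_ppe": 0.0, "beta_val": 0.0, "beta_amb": 0.0,
}

_INIT = {
    "alpha": 0.9, "beta1": 3.0, "beta0": 0.0, "gamma": 0.9,
    "tau_i": 1.0, "tau_b": 0.5, "w_r": 0.0,
    "beta_ppe": 0.0, "beta_val": 0.0, "beta_amb": 0.2,
}

#: default references for posterior tail probabilities
P_MCMC_REFERENCES = {
    "mu_alpha": 1.0, "mu_gamma": 1.0, "mu_tau_i": 1.0, "mu_tau_b": 0.5,
    "mu_beta1": 0.0, "mu_beta0": 0.0, "mu_w_r": 0.0,
    "mu_beta_ppe": 0.0, "mu_beta_val": 0.0, "mu_beta_amb": 0.0,
}


class ConvergenceError(RuntimeError):
    """Chains failed the Gelman-Rubin gate after all burn-in extensions."""


@dataclass(frozen=True)
class GroupModel:
    """Variant flags of the model family.

    Disabled parameters are pinned at neutral values (tau_i = 0 only in
    the explicit null; tau_b = 0.5; W_r and the couplings at 0).  The
    comparator replaces the assignment machinery by a linear discount of
    the hidden area.
    """

    name: str = "tau_i"
    use_tau_i: bool = True
    use_tau_b: bool = False
    use_wr: bool = False
    use_trial_dependence: bool = False
    use_condition_effects: bool = False
    separate_parietal_sites: bool = False
    comparator_discount: bool = False
    effect_params: tuple = ("tau_i",)
    pinned_tau_i: float = 0.0

    @classmethod
    def from_name(cls, name: str, **kw) -> "GroupModel":
        presets = {
            "tau_i": dict(),
            "null": dict(use_tau_i=False),
            "tau_i_tau_b": dict(use_tau_b=True),
            "wr": dict(use_wr=True),
            "trialdep": dict(use_trial_dependence=True),
            "tms": dict(use_condition_effects=True),
            "discount": dict(use_tau_i=False, comparator_discount=True),
        }
        if name not in presets:
            raise ValueError(f"unknown model variant {name!r}; options: {sorted(presets)}")
        return cls(name=name, **presets[name], **kw)

    def sampled_params(self) -> list[str]:
        names = ["alpha", "beta1", "beta0", "gamma"]
        if self.comparator_discount:
            names.append("beta_amb")
        elif self.use_tau_i:
            names.append("tau_i")
        if self.use_tau_b:
            names.append("tau_b")
        if self.use_wr:
            names.append("w_r")
        if self.use_trial_dependence:
            names += ["beta_ppe", "beta_val"]
        return names

    def delta_names(self) -> list[tuple[str, str]]:
        if not self.use_condition_effects:
            return []
        sites = ("ips", "ppc") if self.separate_parietal_sites else ("parietal",)
        return [(p, s) for p in self.effect_params for s in sites]

    def n_free_parameters(self, n_subjects: int) -> int:
        n = 0
        for p in self.sampled_params():
            n += n_subjects + 2  # subjects + (mu, sigma) or (mu, kappa)
        n += len(self.delta_names())
        return n


@dataclass(frozen=True)
class MCMCConfig:
    """Sampling protocol (defaults follow the study's convention)."""

    burn_in: int = 10_000
    draws: int = 10_000
    chains: int = 3
    thin: int = 10
    seed: int = 0
    rhat_threshold: float = 1.05
    max_extensions: int = 3
    check_convergence: bool = True

    def __post_init__(self):
        if self.chains < 2 and self.check_convergence:
            raise ValueError("convergence checking requires >= 2 chains")
        if self.draws < self.thin:
            raise ValueError("draws must be >= thin")


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    hdi_low: float
    hdi_high: float
    p_mcmc: float
    reference: float
    r_hat: float
    ess: float


@dataclass
class FitResult:
    """Retained draws plus bookkeeping for summaries and model selection."""

    model: GroupModel
    config: MCMCConfig
    subjects: list
    scalar_draws: dict  # name -> (chains, kept)
    subject_draws: dict  # name -> (chains, kept, n_subjects)
    log_lik: np.ndarray  # (chains, kept, n_trials)
    deviance_at_mean: float
    r_hat: dict
    n_extensions: int
    dataset_hash: int
    pinned: dict

    @property
    def n_retained(self) -> int:
        c, k = next(iter(self.scalar_draws.values())).shape
        return c * k

    def pooled(self, name: str) -> np.ndarray:
        """All retained draws of a scalar quantity, chains pooled."""
        if name in self.scalar_draws:
            return self.scalar_draws[name].reshape(-1)
        raise KeyError(f"no scalar quantity {name!r}; have {sorted(self.scalar_draws)}")

    @property
    def deviance_draws(self) -> np.ndarray:
        return -2.0 * self.log_lik.sum(axis=2)

    def subject_posterior_means(self, param: str) -> pd.Series:
        draws = self.subject_draws[param]
        return pd.Series(draws.mean(axis=(0, 1)), index=self.subjects, name=param)

    def summarize(self, name: str, reference: float | None = None) -> PosteriorSummary:
        draws = self.scalar_draws[name]
        pooled = draws.reshape(-1)
        ref = reference if reference is not None else P_MCMC_REFERENCES.get(name, 0.0)
        lo, hi = hdi(pooled)
        return PosteriorSummary(
            mean=float(pooled.mean()),
            hdi_low=lo,
            hdi_high=hi,
            p_mcmc=p_mcmc(pooled, ref),
            reference=ref,
            r_hat=self.r_hat.get(name, float("nan")),
            ess=_ess(draws),
        )

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name in self.scalar_draws:
            s = self.summarize(name)
            rows[name] = {
                "mean": s.mean, "hdi_low": s.hdi_low, "hdi_high": s.hdi_high,
                "p_mcmc": s.p_mcmc, "reference": s.reference,
                "r_hat": s.r_hat, "ess": s.ess,
            }
        return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# posterior summaries


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding ``mass`` of the draws."""
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).reshape(-1))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    m = max(2, int(math.ceil(mass * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def p_mcmc(samples, reference: float) -> float:
    """Two-sided posterior tail probability vs a reference value,
    floored at ``1 / n_draws`` and capped at 1."""
    x = np.asarray(samples, dtype=float).reshape(-1)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    above = float(np.mean(x > reference))
    below = float(np.mean(x < reference))
    p = 2.0 * min(above, below)
    return float(min(1.0, max(p, 1.0 / x.size)))


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor (classic between/within form).

    ``chains`` is an (m, n) array of m >= 2 equal-length chains.  The
    statistic is floored at 1 (values marginally below 1 are sampling
    noise); identical chains give exactly 1.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = c.shape
    if n < 2:
        raise ValueError("chains must have length >= 2")
    w = float(np.mean(np.var(c, axis=1, ddof=1)))
    b_over_n = float(np.var(c.mean(axis=1), ddof=1))
    if w == 0.0:
        return 1.0
    v_hat = (n - 1) / n * w + (1.0 + 1.0 / m) * b_over_n
    return float(max(1.0, math.sqrt(v_hat / w)))


def _ess(draws_2d: np.ndarray) -> float:
    """Bulk effective sample size via arviz."""
    import arviz as az

    with np.errstate(all="ignore"):
        vals = az.ess(az.convert_to_dataset(draws_2d[:, :, None]))["x"].values
    return float(np.asarray(vals).reshape(-1)[0])


# ---------------------------------------------------------------------------
# priors


_LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)


def _log_normal(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma) - _LOG_SQRT_2PI


def _log_trunc_normal(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """log density of a zero-truncated normal (lower tail cut at 0)."""
    from scipy.special import log_ndtr

    z = _log_normal(x, mu, sigma) - log_ndtr(mu / sigma)
    return np.where(x > 0, z, -np.inf)


def _log_beta_ms(x: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    """Beta log density parameterised by mean and dispersion."""
    a = mu * kappa
    b = (1.0 - mu) * kappa
    if a <= 0 or b <= 0:
        return np.full(np.shape(x), -np.inf)
    lognorm = math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) + lognorm
    return np.where((x > 0) & (x < 1), z, -np.inf)


def _subject_log_prior(name: str, values: np.ndarray, hyper: dict) -> np.ndarray:
    if name in _POSITIVE:
        return _log_trunc_normal(values, hyper["mu"], hyper["sigma"])
    if name == "tau_b":
        return _log_beta_ms(values, hyper["mu"], hyper["kappa"])
    return _log_normal(values, hyper["mu"], hyper["sigma"])


def _hyper_log_prior(name: str, hyper: dict) -> float:
    if name == "tau_b":
        mu, kappa = hyper["mu"], hyper["kappa"]
        if not (0 < mu < 1 and KAPPA_BOUNDS[0] <= kappa <= KAPPA_BOUNDS[1]):
            return -np.inf
        return 0.0
    mu, sigma = hyper["mu"], hyper["sigma"]
    if not SIGMA_BOUNDS[0] <= sigma <= SIGMA_BOUNDS[1]:
        return -np.inf
    if name in _POSITIVE:
        if not MU_POS_BOUNDS[0] <= mu <= MU_POS_BOUNDS[1]:
            return -np.inf
        return 0.0
    return float(_log_normal(np.asarray(mu), 0.0, MU_REAL_SD))


# ---------------------------------------------------------------------------
# the sampler


# joint-proposal working coordinates: "log", "asinh", "logit" or identity
_JOINT_TRANSFORM = {
    "alpha": "log", "gamma": "log",
    "beta1": "asinh", "tau_i": "asinh", "w_r": "asinh", "beta_amb": "asinh",
    "tau_b": "logit",
}


def _to_u(name: str, x: np.ndarray) -> np.ndarray:
    t = _JOINT_TRANSFORM.get(name)
    with np.errstate(divide="ignore", invalid="ignore"):
        if t == "log":
            return np.log(x)
        if t == "asinh":
            return np.arcsinh(x)
        if t == "logit":
            return np.log(x) - np.log1p(-x)
    return x


def _from_u(name: str, u: np.ndarray) -> np.ndarray:
    t = _JOINT_TRANSFORM.get(name)
    with np.errstate(over="ignore"):
        if t == "log":
            return np.exp(u)
        if t == "asinh":
            return np.sinh(u)
        if t == "logit":
            return 1.0 / (1.0 + np.exp(-u))
    return u


def _log_jac(name: str, x: np.ndarray) -> np.ndarray:
    """log |dx/du| at x — the density correction for sampling in u."""
    t = _JOINT_TRANSFORM.get(name)
    with np.errstate(divide="ignore", invalid="ignore"):
        if t == "log":
            return np.log(x)
        if t == "asinh":
            return 0.5 * np.log1p(x * x)
        if t == "logit":
            return np.log(x) + np.log1p(-x)
    return np.zeros_like(x)


class _ChainState:
    def __init__(self, model: GroupModel, n_subj: int, rng: np.random.Generator):
        self.rng = rng
        self.subj: dict[str, np.ndarray] = {}
        self.hyper: dict[str, dict] = {}
        self.deltas: dict[tuple, float] = {}
        for name in _POSITIVE + ("tau_b",) + _REAL:
            self.subj[name] = np.full(n_subj, _NEUTRAL[name], dtype=float)
        for name in model.sampled_params():
            init = _INIT[name]
            jitter = rng.normal(0, 0.05, n_subj)
            vals = np.clip(init + jitter, *_SUPPORT[name])
            if name in _POSITIVE:
                vals = np.maximum(vals, 0.02)
            self.subj[name] = vals
            if name == "tau_b":
                self.hyper[name] = {"mu": float(np.clip(vals.mean(), 0.05, 0.95)),
                                    "kappa": 20.0}
            else:
                mu0 = float(vals.mean())
                if name in _POSITIVE:
                    mu0 = float(np.clip(mu0, *MU_POS_BOUNDS))
                self.hyper[name] = {"mu": mu0, "sigma": 0.3}
        if model.use_tau_i is False and not model.comparator_discount:
            self.subj["tau_i"] = np.full(n_subj, model.pinned_tau_i, dtype=float)
        for key in model.delta_names():
            self.deltas[key] = float(rng.normal(0, 0.02))
        # adaptive proposal scales
        self.scale_subj = {n: np.full(n_subj, 0.15) for n in model.sampled_params()}
        self.scale_hyper = {(n, h): 0.15 for n in model.sampled_params()
                            for h in self.hyper[n]}
        self.scale_delta = {k: 0.1 for k in self.deltas}
        self.adapt_step = 0
        # running per-subject moments for the joint (Haario-style) block,
        # which handles ridge-shaped correlations (e.g. alpha vs beta1)
        p = len(model.sampled_params())
        self.joint_n = 0
        self.joint_mean = np.zeros((n_subj, p))
        self.joint_m2 = np.zeros((n_subj, p, p))
        self.joint_log_scale = np.zeros(n_subj)


class _Sampler:
    """One model + dataset; runs chains and collects retained draws."""

    def __init__(self, data: TrialData, model: GroupModel):
        self.data = data
        self.model = model
        self.names = model.sampled_params()

    def _ll(self, subj_params: dict, deltas: dict) -> np.ndarray:
        return loglik_trials(
            self.data, subj_params,
            discount=self.model.comparator_discount,
            trial_dependence=self.model.use_trial_dependence,
            deltas=deltas,
        )

    def _sweep(self, st: _ChainState, ll_subj: np.ndarray, adapting: bool):
        rng = st.rng
        st.adapt_step += 1
        rate = 1.0 / st.adapt_step ** 0.6 if adapting else 0.0
        n_subj = self.data.n_subjects
        for name in self.names:
            cur = st.subj[name]
            prop = cur + st.scale_subj[name] * rng.standard_normal(n_subj)
            lo, hi = _SUPPORT[name]
            valid = (prop > lo) & (prop < hi)
            trial = dict(st.subj)
            trial[name] = np.where(valid, prop, cur)
            ll_new = subject_loglik(self.data, self._ll(trial, st.deltas))
            lp_new = _subject_log_prior(name, trial[name], st.hyper[name])
            lp_old = _subject_log_prior(name, cur, st.hyper[name])
            with np.errstate(invalid="ignore"):
                log_ratio = (ll_new - ll_subj) + (lp_new - lp_old)
            accept = valid & (np.log(rng.random(n_subj)) < log_ratio)
            st.subj[name] = np.where(accept, trial[name], cur)
            ll_subj = np.where(accept, ll_new, ll_subj)
            if adapting:
                st.scale_subj[name] *= np.exp(rate * (accept.astype(float) - 0.44))
                np.clip(st.scale_subj[name], 1e-4, 50.0, out=st.scale_subj[name])
        ll_subj = self._joint_update(st, ll_subj, adapting, rate)
        # hyperparameters: conditioned on subject values only (cheap, so
        # several repetitions per sweep to keep the group level mixing)
        for name, h in [(n, h) for _ in range(3)
                        for n in self.names for h in st.hyper[n]]:
            cur = st.hyper[name][h]
            prop = cur + st.scale_hyper[(name, h)] * rng.standard_normal()
            cand = dict(st.hyper[name])
            cand[h] = prop
            lp_new = _hyper_log_prior(name, cand)
            if np.isfinite(lp_new):
                lp_new += float(np.sum(_subject_log_prior(name, st.subj[name], cand)))
            lp_old = _hyper_log_prior(name, st.hyper[name]) + float(
                np.sum(_subject_log_prior(name, st.subj[name], st.hyper[name]))
            )
            acc = np.isfinite(lp_new) and math.log(rng.random()) < lp_new - lp_old
            if acc:
                st.hyper[name][h] = prop
            if adapting:
                st.scale_hyper[(name, h)] *= math.exp(rate * (float(acc) - 0.44))
                st.scale_hyper[(name, h)] = float(
                    np.clip(st.scale_hyper[(name, h)], 1e-4, 50.0)
                )
        # TMS condition shifts: scalar MH with full-data likelihood
        for key in st.deltas:
            cur = st.deltas[key]
            prop = cur + st.scale_delta[key] * rng.standard_normal()
            cand = dict(st.deltas)
            cand[key] = prop
            ll_new = subject_loglik(self.data, self._ll(st.subj, cand))
            lr = float(ll_new.sum() - ll_subj.sum())
            lr += float(_log_normal(np.asarray(prop), 0, DELTA_PRIOR_SD)
                        - _log_normal(np.asarray(cur), 0, DELTA_PRIOR_SD))
            acc = np.isfinite(lr) and math.log(rng.random()) < lr
            if acc:
                st.deltas[key] = prop
                ll_subj = ll_new
            if adapting:
                st.scale_delta[key] *= math.exp(rate * (float(acc) - 0.44))
                st.scale_delta[key] = float(np.clip(st.scale_delta[key], 1e-4, 50.0))
        return ll_subj

    def _joint_update(self, st: _ChainState, ll_subj: np.ndarray, adapting: bool,
                      rate: float) -> np.ndarray:
        """One joint Metropolis step over each subject's full parameter
        vector, with proposal covariance learned during burn-in.

        Proposals live in transformed coordinates (log for alpha/gamma,
        asinh for beta1/tau_i, logit for tau_b) where the posterior's
        scale ridges — e.g. the beta1 * x**alpha trade-off — are close
        to linear, so the learned covariance tracks them; the Jacobian
        of the back-transform enters the acceptance ratio.
        """
        rng = st.rng
        n_subj = self.data.n_subjects
        names = self.names
        p = len(names)
        u = np.column_stack([_to_u(n, st.subj[n]) for n in names])
        if adapting:
            st.joint_n += 1
            delta = u - st.joint_mean
            st.joint_mean += delta / st.joint_n
            st.joint_m2 += np.einsum("si,sj->sij", delta, u - st.joint_mean)
        if st.joint_n < 50:
            return ll_subj  # not enough history for a stable covariance
        cov = st.joint_m2 / max(st.joint_n - 1, 1)
        cov = (2.38 ** 2 / p) * cov
        cov[:, np.arange(p), np.arange(p)] += 1e-8
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            return ll_subj
        step = np.exp(st.joint_log_scale)[:, None]
        u_prop = u + step * np.einsum("sij,sj->si", chol,
                                      rng.standard_normal((n_subj, p)))
        trial = dict(st.subj)
        valid = np.ones(n_subj, dtype=bool)
        log_ratio = np.zeros(n_subj)
        prop_cols = {}
        for j, n in enumerate(names):
            x_new = _from_u(n, u_prop[:, j])
            lo, hi = _SUPPORT[n]
            valid &= np.isfinite(x_new) & (x_new > lo) & (x_new < hi)
            prop_cols[n] = x_new
        for j, n in enumerate(names):
            col = np.where(valid, prop_cols[n], st.subj[n])
            trial[n] = col
            log_ratio += _subject_log_prior(n, col, st.hyper[n]) \
                - _subject_log_prior(n, st.subj[n], st.hyper[n])
            log_ratio += np.where(valid,
                                  _log_jac(n, col) - _log_jac(n, st.subj[n]), 0.0)
        ll_new = subject_loglik(self.data, self._ll(trial, st.deltas))
        with np.errstate(invalid="ignore"):
            log_ratio = log_ratio + (ll_new - ll_subj)
        accept = valid & (np.log(rng.random(n_subj)) < log_ratio)
        for n in names:
            st.subj[n] = np.where(accept, trial[n], st.subj[n])
        ll_subj = np.where(accept, ll_new, ll_subj)
        if adapting:
            st.joint_log_scale += rate * (accept.astype(float) - 0.23)
            np.clip(st.joint_log_scale, -5.0, 3.0, out=st.joint_log_scale)
        return ll_subj

    def run_chain(self, seed_seq, burn_in: int, draws: int, thin: int):
        rng = np.random.default_rng(seed_seq)
        st = _ChainState(self.model, self.data.n_subjects, rng)
        ll_subj = subject_loglik(self.data, self._ll(st.subj, st.deltas))
        for _ in range(burn_in):
            ll_subj = self._sweep(st, ll_subj, adapting=True)
        kept = draws // thin
        scalars = {f"mu_{n}": np.empty(kept) for n in self.names}
        for n in self.names:
            second = "kappa" if n == "tau_b" else "sigma"
            scalars[f"{second}_{n}"] = np.empty(kept)
        for key in st.deltas:
            scalars[_delta_label(key)] = np.empty(kept)
        subj_draws = {n: np.empty((kept, self.data.n_subjects)) for n in self.names}
        log_lik = np.empty((kept, self.data.n_trials))
        k = 0
        for i in range(draws):
            ll_subj = self._sweep(st, ll_subj, adapting=False)
            if (i + 1) % thin == 0:
                for n in self.names:
                    scalars[f"mu_{n}"][k] = st.hyper[n]["mu"]
                    second = "kappa" if n == "tau_b" else "sigma"
                    scalars[f"{second}_{n}"][k] = st.hyper[n][second]
                    subj_draws[n][k] = st.subj[n]
                for key, v in st.deltas.items():
                    scalars[_delta_label(key)][k] = v
                log_lik[k] = self._ll(st.subj, st.deltas)
                k += 1
        return st, scalars, subj_draws, log_lik


def _delta_label(key: tuple) -> str:
    return f"delta_{key[0]}_{key[1]}"


def _dataset_frame(dataset) -> pd.DataFrame:
    if isinstance(dataset, pd.DataFrame):
        return dataset
    return trials_to_frame(dataset)


def fit_hierarchical(dataset, model: GroupModel | str = "tau_i",
                     mcmc: MCMCConfig | None = None) -> FitResult:
    """Fit one model variant to a trial table.

    ``dataset`` is a trial-table DataFrame or a sequence of ChoiceRecords.
    Raises :class:`ConvergenceError` when the Gelman-Rubin gate fails
    after all configured burn-in extensions.
    """
    if isinstance(model, str):
        model = GroupModel.from_name(model)
    mcmc = mcmc or MCMCConfig()
    df = _dataset_frame(dataset)
    if len(df) == 0:
        raise ValueError("empty dataset")
    data = TrialData.from_frame(df)
    needs_ambiguity = model.use_tau_i or model.use_tau_b or model.comparator_discount
    if needs_ambiguity and not data.ambiguous.any():
        raise ValueError("ambiguity parameters enabled but no ambiguity trials present")
    if model.use_condition_effects:
        sites = {t for t, present in
                 [("ips", data.ips.any()), ("ppc", data.ppc.any()),
                  ("vertex", (~data.parietal).any())] if present}
        if len(sites) < 2:
            raise ValueError("condition effects require >= 2 TMS conditions in the data")

    sampler = _Sampler(data, model)
    burn = mcmc.burn_in
    for attempt in range(mcmc.max_extensions + 1):
        chain_seqs = np.random.SeedSequence((mcmc.seed, attempt)).spawn(mcmc.chains)
        results = [
            sampler.run_chain(sq, burn, mcmc.draws, mcmc.thin) for sq in chain_seqs
        ]
        scalar_draws = {
            name: np.stack([r[1][name] for r in results])
            for name in results[0][1]
        }
        r_hat = {name: gelman_rubin(v) if mcmc.chains >= 2 else float("nan")
                 for name, v in scalar_draws.items()}
        bad = [n for n, v in r_hat.items() if v > mcmc.rhat_threshold]
        if not bad or not mcmc.check_convergence:
            break
        if attempt == mcmc.max_extensions:
            raise ConvergenceError(
                f"R-hat above {mcmc.rhat_threshold} after {attempt} burn-in "
                f"extensions for: {sorted(bad)}"
            )
        burn *= 2
    subject_draws = {
        n: np.stack([r[2][n] for r in results]) for n in results[0][2]
    }
    log_lik = np.stack([r[3] for r in results])

    # deviance at posterior-mean parameters (classic DIC plug-in)
    mean_subj = {n: v.mean(axis=(0, 1)) for n, v in subject_draws.items()}
    pinned = {}
    full_subj = {}
    for n in _POSITIVE + ("tau_b",) + _REAL:
        if n in mean_subj:
            full_subj[n] = mean_subj[n]
        else:
            v = model.pinned_tau_i if (n == "tau_i" and not model.comparator_discount) \
                else _NEUTRAL[n]
            full_subj[n] = np.full(data.n_subjects, v)
            pinned[n] = float(v)
    mean_deltas = {
        key: float(scalar_draws[_delta_label(key)].mean())
        for key in model.delta_names()
    }
    ll_at_mean = loglik_trials(
        data, full_subj,
        discount=model.comparator_discount,
        trial_dependence=model.use_trial_dependence,
        deltas=mean_deltas,
    )
    deviance_at_mean = float(-2.0 * ll_at_mean.sum())

    return FitResult(
        model=model,
        config=mcmc,
        subjects=data.subjects,
        scalar_draws=scalar_draws,
        subject_draws=subject_draws,
        log_lik=log_lik,
        deviance_at_mean=deviance_at_mean,
        r_hat=r_hat,
        n_extensions=attempt,
        dataset_hash=int(pd.util.hash_pandas_object(df).sum()) & 0x7FFFFFFF,
        pinned=pinned,
    )


def condition_effect_fit(
    dataset,
    base_model: GroupModel | str = "tau_i",
    mcmc: MCMCConfig | None = None,
    effect_params: tuple = ("tau_i",),
    separate_sites: bool = False,
) -> FitResult:
    """Fit with additive group-level TMS condition shifts.

    Each parameter in ``effect_params`` gains a group-level additive
    shift applied on parietal-stimulation (ips/ppc) trials, with vertex
    as the reference; ``separate_sites`` estimates distinct ips and ppc
    shifts.  Shift posteriors are summarised against reference 0.
    """
    if isinstance(base_model, str):
        base_model = GroupModel.from_name(base_model)
    sampled = base_model.sampled_params()
    missing = [p for p in effect_params if p not in sampled]
    if missing:
        raise ValueError(f"effect parameters not sampled by the base model: {missing}")
    model = dc_replace(
        base_model,
        name=base_model.name + "+tms",
        use_condition_effects=True,
        separate_parietal_sites=separate_sites,
        effect_params=tuple(effect_params),
    )
    return fit_hierarchical(dataset, model, mcmc)
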