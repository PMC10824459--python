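"""Model comparison: DIC and PSIS-LOO information criteria.

DIC uses the classic plug-in form: ``DIC = Dbar + pD`` with
``pD = Dbar - D(theta_bar)``, where ``Dbar`` is the posterior mean
deviance and ``D(theta_bar)`` the deviance at the posterior-mean
parameters.  LOOIC is ``-2 * elpd_loo`` from Pareto-smoothed importance
sampling over per-trial log-likelihood draws (the trial is the pointwise
unit, matching the Bernoulli trial-level likelihood); points with a
Pareto tail-shape diagnostic above the threshold are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import FitResult


@dataclass(frozen=True)
class LooResult:
    looic: float
    se: float
    pareto_k: np.ndarray
    n_flagged: int


def dic(fit: FitResult) -> tuple[float, float]:
    """Deviance information criterion; returns ``(DIC, p_D)``."""
    if fit.log_lik is None or fit.log_lik.size == 0:
        raise ValueError("fit contains no log-likelihood draws")
    dbar = float(fit.deviance_draws.mean())
    p_d = dbar - fit.deviance_at_mean
    return dbar + p_d, p_d


def looic(fit: FitResult, k_threshold: float = 0.7) -> LooResult:
    """PSIS leave-one-out information criterion over trials."""
    import arviz as az

    if fit.log_lik is None or fit.log_lik.size == 0:
        raise ValueError("fit contains no log-likelihood draws")
    idata = az.from_dict(
        posterior={"dummy": fit.log_lik[:, :, :1] * 0.0},
        log_likelihood={"choice": fit.log_lik},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    k = np.asarray(res.pareto_k)
    return LooResult(
        looic=float(-2.0 * res.elpd_loo),
        se=float(2.0 * res.se),
        pareto_k=k,
        n_flagged=int((k > k_threshold).sum()),
    )


def compare(fits: dict[str, FitResult] | list[FitResult]) -> pd.DataFrame:
    """Rank model variants fitted to the same dataset.

    Returns one row per model with DIC, p_D, LOOIC, deltas against the
    best model and ranks per criterion.  Ties rank the model with fewer
    free parameters first.
    """
    if not isinstance(fits, dict):
        fits = {f.model.name: f for f in fits}
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    hashes = {f.dataset_hash for f in fits.values()}
    if len(hashes) > 1:
        raise ValueError("fits were computed on different datasets")
    rows = {}
    for name, fit in fits.items():
        d, p_d = dic(fit)
        loo = looic(fit)
        rows[name] = {
            "dic": d,
            "p_d": p_d,
            "looic": loo.looic,
            "looic_se": loo.se,
            "n_flagged": loo.n_flagged,
            "n_free": fit.model.n_free_parameters(len(fit.subjects)),
        }
    table = pd.DataFrame(rows).T
    for crit in ("dic", "looic"):
        table[f"d_{crit}"] = table[crit] - table[crit].min()
        order = table.sort_values([crit, "n_free"]).index
        table[f"rank_{crit}"] = pd.Series(
            np.arange(1, len(table) + 1), index=order
        )
    return table.sort_values("rank_looic")
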