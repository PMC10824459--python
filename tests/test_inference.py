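"""Posterior summaries, convergence diagnostics, and small-scale fits."""

import numpy as np
import pytest

from ambigchoice import (
    CohortSpec,
    GroupModel,
    MCMCConfig,
    condition_effect_fit,
    fit_hierarchical,
    gelman_rubin,
    hdi,
    p_mcmc,
    simulate_cohort,
    study_cohort,
)
from ambigchoice.inference import ConvergenceError

FAST = MCMCConfig(burn_in=400, draws=400, chains=2, thin=4, seed=0,
                  check_convergence=False)


# --- hdi ---------------------------------------------------------------------

def test_hdi_degenerate_samples():
    assert hdi([3.0] * 50) == (3.0, 3.0)


def test_hdi_matches_normal_quantiles():
    x = np.random.default_rng(1).standard_normal(100_000)
    lo, hi = hdi(x)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def test_hdi_uniform_length():
    x = np.random.default_rng(2).uniform(0, 1, 100_000)
    lo, hi = hdi(x)
    assert hi - lo == pytest.approx(0.95, abs=0.01)


def test_hdi_agrees_with_arviz():
    import arviz as az

    x = np.random.default_rng(3).gamma(2.0, size=20_000)
    lo, hi = hdi(x)
    ref = az.hdi(x, hdi_prob=0.95)
    assert lo == pytest.approx(ref[0], abs=0.02)
    assert hi == pytest.approx(ref[1], abs=0.02)


def test_hdi_rejects_bad_mass():
    with pytest.raises(ValueError):
        hdi([1.0, 2.0], mass=1.2)


# --- p_mcmc ------------------------------------------------------------------

def test_p_mcmc_floor_when_all_mass_on_one_side():
    x = np.linspace(1, 2, 3000)
    assert p_mcmc(x, 0.5) == pytest.approx(1 / 3000)


def test_p_mcmc_balanced_tails():
    x = np.concatenate([np.linspace(-2, -0.1, 500), np.linspace(0.1, 2, 500)])
    assert p_mcmc(x, 0.0) == pytest.approx(1.0)


def test_p_mcmc_hand_count():
    x = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 1.1]
    assert p_mcmc(x, 1.0) == pytest.approx(0.2)


# --- gelman-rubin ------------------------------------------------------------

def test_gelman_rubin_identical_chains():
    c = np.random.default_rng(4).standard_normal(5000)
    assert gelman_rubin([c, c]) == pytest.approx(1.0, abs=1e-6)


def test_gelman_rubin_same_distribution_is_small():
    rng = np.random.default_rng(5)
    chains = rng.standard_normal((2, 5000))
    assert gelman_rubin(chains) < 1.05


def test_gelman_rubin_divergent_chains_is_large():
    rng = np.random.default_rng(6)
    chains = np.stack([rng.standard_normal(2000), rng.standard_normal(2000) + 10])
    assert gelman_rubin(chains) > 1.1


def test_gelman_rubin_single_chain_rejected():
    with pytest.raises(ValueError):
        gelman_rubin(np.ones((1, 100)))


# --- model variants ----------------------------------------------------------

def test_variant_flags_control_sampled_parameters():
    assert "tau_i" in GroupModel.from_name("tau_i").sampled_params()
    assert "tau_i" not in GroupModel.from_name("null").sampled_params()
    assert "tau_b" in GroupModel.from_name("tau_i_tau_b").sampled_params()
    assert "beta_amb" in GroupModel.from_name("discount").sampled_params()
    assert "w_r" in GroupModel.from_name("wr").sampled_params()
    with pytest.raises(ValueError):
        GroupModel.from_name("bogus")


def test_fit_smoke_records_diagnostics(small_dataset):
    fit = fit_hierarchical(small_dataset, "tau_i", FAST)
    # every sampled scalar quantity carries an R-hat
    assert set(fit.r_hat) == set(fit.scalar_draws)
    assert fit.n_retained == 2 * (400 // 4)
    # pinned parameters are not sampled and are reported as pinned
    assert "mu_tau_b" not in fit.scalar_draws
    assert fit.pinned["tau_b"] == 0.5
    summary = fit.summary()
    assert (summary["hdi_low"] < summary["hdi_high"]).all()
    assert summary["p_mcmc"].between(1 / fit.n_retained, 1).all()


def test_fit_is_deterministic_for_fixed_seed(small_dataset):
    a = fit_hierarchical(small_dataset, "tau_i", FAST)
    b = fit_hierarchical(small_dataset, "tau_i", FAST)
    for k in a.scalar_draws:
        assert np.array_equal(a.scalar_draws[k], b.scalar_draws[k])
    assert np.array_equal(a.log_lik, b.log_lik)


def test_fit_rejects_empty_and_ambiguity_free_data(small_dataset):
    import pandas as pd

    with pytest.raises(ValueError, match="empty"):
        fit_hierarchical(small_dataset.iloc[:0], "tau_i", FAST)
    no_amb = small_dataset[small_dataset["condition"] == "no-ambiguity"]
    with pytest.raises(ValueError, match="ambiguity"):
        fit_hierarchical(no_amb, "tau_i", FAST)


def test_unreachable_convergence_gate_raises_listing_parameters(small_dataset):
    cfg = MCMCConfig(burn_in=50, draws=80, chains=2, thin=4, seed=1,
                     rhat_threshold=1.0 + 1e-9, max_extensions=0)
    with pytest.raises(ConvergenceError, match="mu_"):
        fit_hierarchical(small_dataset, "tau_i", cfg)


def test_condition_effects_require_multiple_sites(small_dataset):
    with pytest.raises(ValueError, match="TMS"):
        condition_effect_fit(small_dataset, "tau_i", FAST)


def test_condition_effects_only_for_sampled_parameters(small_dataset):
    with pytest.raises(ValueError, match="w_r"):
        condition_effect_fit(small_dataset, "tau_i", FAST, effect_params=("w_r",))


def test_shift_draws_present_only_when_enabled():
    ds, _ = simulate_cohort(study_cohort(n_subjects=2, session_template="tms",
                                         seed=3))
    plain = fit_hierarchical(ds, "tau_i", FAST)
    assert not any(k.startswith("delta_") for k in plain.scalar_draws)
    shifted = condition_effect_fit(ds, "tau_i", FAST)
    assert "delta_tau_i_parietal" in shifted.scalar_draws
    s = shifted.summarize("delta_tau_i_parietal")
    assert s.reference == 0.0


def test_prior_predictive_cohorts_are_fittable():
    """Parameters drawn from wide group distributions simulate datasets
    the fitter accepts without crashing."""
    rng = np.random.default_rng(12)
    tiny = MCMCConfig(burn_in=30, draws=30, chains=2, thin=3, seed=0,
                      check_convergence=False)
    for rep in range(10):
        spec = CohortSpec(
            n_subjects=2, session_template="custom", n_trials=20, block_size=10,
            seed=rep,
            group_means={
                "alpha": float(rng.uniform(0.2, 1.2)),
                "beta1": float(rng.uniform(0.2, 4.0)),
                "gamma": float(rng.uniform(0.4, 1.6)),
                "tau_i": float(rng.uniform(0.0, 2.5)),
            },
        )
        ds, _ = simulate_cohort(spec)
        fit = fit_hierarchical(ds, "tau_i", tiny)
        assert np.isfinite(fit.log_lik).all()
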