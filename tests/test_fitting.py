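"""Tests of likelihood evaluation, grid fitting, AIC comparison and RPE
replay for the two Q-learning models."""

import math

import numpy as np
import pandas as pd
import pytest

from latentrl import fitting
from latentrl.fitting import (FitResult, GridSpec, compare_models, fit_grid,
                              neg_log_lik_rl_sd, neg_log_lik_rl_sf,
                              rpe_trace)

from conftest import simulate_session

SMALL_GRID = GridSpec(n_alpha=20, n_beta=20, n_eta=11, n_runs=10)


class TestLikelihoodOracles:
    def test_flat_beta_gives_n_ln2_sf(self, rl_sd_frame):
        n = len(rl_sd_frame)
        nll = neg_log_lik_rl_sf(rl_sd_frame, alpha=0.3, beta=0.0)
        assert nll == pytest.approx(n * math.log(2), rel=1e-12)

    def test_flat_beta_gives_n_ln2_sd(self, rl_sd_frame):
        n = len(rl_sd_frame)
        nll = neg_log_lik_rl_sd(rl_sd_frame, alpha=0.3, beta=0.0, eta=0.0)
        assert nll == pytest.approx(n * math.log(2), rel=1e-12)

    def test_single_trial_symmetric_init(self):
        df = pd.DataFrame({"latent_state": ["L"], "action": ["A"],
                           "reward": [1]})
        assert neg_log_lik_rl_sf(df, 0.3, 5.0) == pytest.approx(math.log(2))

    def test_eta_zero_is_deterministic_and_matches_noiseless(self,
                                                             rl_sd_frame):
        vals = {neg_log_lik_rl_sd(rl_sd_frame, 0.4, 6.0, eta=0.0)
                for _ in range(5)}
        assert len(vals) == 1

    def test_eta_positive_is_stochastic(self, rl_sd_frame):
        rng = np.random.default_rng(0)
        vals = [neg_log_lik_rl_sd(rl_sd_frame, 0.4, 6.0, eta=0.3, rng=rng)
                for _ in range(20)]
        assert np.var(vals) > 0

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            neg_log_lik_rl_sf(pd.DataFrame({"action": [], "reward": []}),
                              0.3, 5.0)

    def test_missing_state_column_rejected(self):
        df = pd.DataFrame({"action": ["A", "B"], "reward": [1, 0]})
        with pytest.raises(ValueError):
            neg_log_lik_rl_sd(df, 0.3, 5.0)

    def test_shuffled_trials_refused(self, rl_sd_frame):
        shuffled = rl_sd_frame.sample(frac=1.0, random_state=1)
        with pytest.raises(ValueError, match="sorted"):
            neg_log_lik_rl_sf(shuffled, 0.3, 5.0)

    def test_likelihood_smooth_in_parameters(self, rl_sd_frame):
        # coarse finite-difference continuity check
        base = neg_log_lik_rl_sf(rl_sd_frame, 0.4, 5.0)
        for da, db in ((1e-4, 0.0), (0.0, 1e-3)):
            near = neg_log_lik_rl_sf(rl_sd_frame, 0.4 + da, 5.0 + db)
            assert abs(near - base) < 0.5


class TestGridFit:
    def test_grid_avoids_endpoints(self):
        spec = GridSpec()
        assert spec.alphas[0] > 0 and spec.alphas[-1] < 1
        assert spec.betas[0] > 0 and spec.betas[-1] < 20
        assert spec.etas[0] == 0.0 and spec.etas[-1] == 0.5

    def test_sf_recovery_within_grid_step(self):
        # parameter-recovery oracle at large n for the deterministic model
        frame = simulate_session(kind="rl_sf", alpha=0.3, beta=5.0, eta=0.0,
                                 seed=3, n_blocks=167)
        fit = fit_grid(frame, "rl_sf", GridSpec(n_alpha=25, n_beta=25))
        assert abs(fit.alpha_hat - 0.3) <= 0.1
        assert abs(fit.beta_hat - 5.0) <= 1.7

    def test_random_agent_fits_flat_likelihood(self, random_frame):
        fit = fit_grid(random_frame, "rl_sf", SMALL_GRID)
        # flat likelihood: best beta at or near the smallest grid point
        assert fit.beta_hat <= SMALL_GRID.betas[2]

    def test_noisy_fit_reproducible_from_seed(self, rl_sd_frame):
        spec = GridSpec(n_alpha=10, n_beta=10, n_eta=6, n_runs=5)
        a = fit_grid(rl_sd_frame, "rl_sd_noisy", spec, seed=42)
        b = fit_grid(rl_sd_frame, "rl_sd_noisy", spec, seed=42)
        assert (a.alpha_hat, a.beta_hat, a.eta_hat, a.neg_log_lik) == \
               (b.alpha_hat, b.beta_hat, b.eta_hat, b.neg_log_lik)

    def test_degenerate_single_action_flagged(self):
        df = pd.DataFrame({"latent_state": ["L", "R"] * 10,
                           "action": ["A"] * 20, "reward": [1, 0] * 10})
        with pytest.warns(UserWarning, match="single action"):
            fit = fit_grid(df, "rl_sf", SMALL_GRID)
        assert fit.boundary

    def test_aic_identity(self, rl_sd_frame):
        for model, k in (("rl_sf", 2), ("rl_sd_noiseless", 2)):
            fit = fit_grid(rl_sd_frame, model, SMALL_GRID)
            assert fit.aic == pytest.approx(2 * k + 2 * fit.neg_log_lik)
        fit = fit_grid(rl_sd_frame, "rl_sd_noisy",
                       GridSpec(n_alpha=8, n_beta=8, n_eta=4, n_runs=4),
                       seed=0)
        assert fit.aic == pytest.approx(6 + 2 * fit.neg_log_lik)


class TestModelComparison:
    def _fit(self, model, nll, n=100):
        k = FitResult.n_params(model)
        return FitResult(model, 0.3, 5.0, 0.1 if k == 3 else None, nll, n,
                         2 * k + 2 * nll, 2 * k + 2 * nll / n, GridSpec())

    def test_equal_likelihood_costs_extra_parameter(self):
        cmp = compare_models(self._fit("rl_sd_noisy", 100.0),
                             self._fit("rl_sf", 100.0))
        assert cmp.delta_aic == pytest.approx(2.0)

    def test_arithmetic(self):
        cmp = compare_models(self._fit("rl_sd_noisy", 100.0),
                             self._fit("rl_sf", 110.0))
        assert cmp.delta_aic == pytest.approx(206.0 - 224.0)

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError):
            compare_models(self._fit("rl_sd_noisy", 100.0, n=100),
                           self._fit("rl_sf", 100.0, n=101))


class TestRPETrace:
    def test_first_trial_from_uninformed_prior(self):
        df = pd.DataFrame({"latent_state": ["L"], "action": ["A"],
                           "reward": [1]})
        out = rpe_trace(df, alpha=0.4, beta=5.0)
        assert out["rpe"].iloc[0] == pytest.approx(0.5)

    def test_frozen_values_at_zero_alpha(self, rl_sd_frame):
        out = rpe_trace(rl_sd_frame, alpha=0.0, beta=5.0)
        expected = rl_sd_frame["reward"].to_numpy() - 0.5
        np.testing.assert_allclose(out["rpe"].to_numpy(), expected)

    def test_replay_matches_generating_agent_exactly(self):
        # self-consistency oracle: replaying with the generating
        # parameters and eta=0 reproduces the simulator's internal RPEs
        frame = simulate_session(kind="rl_sd", alpha=0.35, beta=4.0,
                                 eta=0.0, seed=9)
        out = rpe_trace(frame, alpha=0.35, beta=4.0)
        np.testing.assert_allclose(out["rpe"].to_numpy(),
                                   frame["gen_rpe"].to_numpy(), atol=1e-12)

    def test_magnitude_bounded(self, rl_sd_frame):
        out = rpe_trace(rl_sd_frame, alpha=0.4, beta=6.0)
        assert ((out["abs_rpe"] >= 0) & (out["abs_rpe"] <= 1)).all()
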