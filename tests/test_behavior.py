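"""Tests of the behavioural statistics: rates, WSLS replay, state bias,
confidence bins, bootstrap and the nonparametric tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentrl import behavior as bh

from conftest import simulate_session


def _frame(actions, rewards, states=None, optimal=None, session=1):
    n = len(actions)
    states = states or ["L"] * n
    optimal = optimal or ["A"] * n
    return pd.DataFrame({
        "session": [session] * n, "block": [1] * n,
        "trial": list(range(1, n + 1)),
        "latent_state": states, "action": actions, "reward": rewards,
        "optimal_action": optimal})


class TestOptimalActionRate:
    def test_oracle_and_anti_oracle(self):
        df = _frame(["A", "A"], [1, 1])
        assert bh.optimal_action_rate(df) == 1.0
        df = _frame(["B", "B"], [0, 0])
        assert bh.optimal_action_rate(df) == 0.0

    def test_complement_sums_to_one(self, rl_sd_frame):
        rate = bh.optimal_action_rate(rl_sd_frame)
        other = (rl_sd_frame["action"]
                 != rl_sd_frame["optimal_action"]).mean()
        assert rate + other == pytest.approx(1.0)

    def test_random_agent_near_chance(self):
        frames = [simulate_session(kind="random", seed=s, n_blocks=70)
                  for s in range(10)]
        rate = np.mean([bh.optimal_action_rate(f) for f in frames])
        assert rate == pytest.approx(0.5, abs=0.01)


class TestWSLSReplay:
    def test_hand_traced_observed_convention(self):
        # rewards 1,0,1,0 starting from A replay as A,A,B,B
        df = _frame(["A", "B", "A", "B"], [1, 0, 1, 0])
        _, actions = bh.wsls_replay(df, convention="observed",
                                    return_actions=True)
        assert list(actions) == ["A", "A", "B", "B"]

    def test_reproduces_wsls_agent_exactly(self):
        # a WSLS agent's own data: the replay never leaves the subject's
        # path, so both conventions reproduce the sequence exactly
        frame = simulate_session(kind="wsls", seed=5)
        for convention in ("observed", "counterfactual"):
            rate, actions = bh.wsls_replay(frame, convention=convention,
                                           n_replays=3,
                                           return_actions=True)
            assert list(actions) == list(frame["action"])
            assert rate == pytest.approx(
                bh.optimal_action_rate(frame))

    def test_single_trial(self):
        df = _frame(["A"], [1])
        rate = bh.wsls_replay(df, convention="observed")
        assert rate in (0.0, 1.0)

    def test_counterfactual_is_seeded_deterministic(self, rl_sd_frame):
        a = bh.wsls_replay(rl_sd_frame, seed=3)
        b = bh.wsls_replay(rl_sd_frame, seed=3)
        assert a == b


class TestStateBias:
    def test_constant_sequence_fully_biased(self):
        trace = bh.state_bias_trace(["R"] * 60)
        np.testing.assert_allclose(trace, 1.0)

    def test_alternating_sequence_unbiased(self):
        raw = bh.state_bias_trace(["R", "L"] * 40, smooth_span=1)
        interior = raw[20:-20]
        assert (interior <= 1 / 30 + 1e-12).all()

    def test_window_count_arithmetic(self):
        # 20 R then 10 L: the full window around the centre holds all 30
        seq = ["R"] * 20 + ["L"] * 10
        raw = bh.state_bias_trace(seq, smooth_span=1)
        assert raw[15] == pytest.approx(10 / 30)

    def test_relabel_invariance_and_range(self):
        rng = np.random.default_rng(0)
        seq = ["R" if rng.random() < 0.6 else "L" for _ in range(200)]
        flipped = ["L" if s == "R" else "R" for s in seq]
        a = bh.state_bias_trace(seq)
        b = bh.state_bias_trace(flipped)
        np.testing.assert_allclose(a, b)
        assert ((a >= 0) & (a <= 1)).all()


class TestConfidenceBinned:
    def test_constant_metric(self):
        out = bh.confidence_binned([1.0] * 8, [1, 2, 3, 4] * 2)
        occupied = out.dropna()
        assert (occupied["mean"] == 1.0).all()

    def test_empty_levels_reported_missing(self):
        out = bh.confidence_binned([0.2, 0.4], [2, 2])
        assert out.loc[out["confidence"] == 2, "count"].item() == 2
        missing = out[out["confidence"] != 2]
        assert missing["mean"].isna().all()
        assert (missing["count"] == 0).all()

    def test_coupled_metric_orders_bins(self):
        rng = np.random.default_rng(1)
        conf = rng.integers(1, 5, 4000)
        metric = 1.0 - 0.2 * conf + rng.normal(0, 0.01, 4000)
        out = bh.confidence_binned(metric, conf)
        means = out["mean"].to_numpy()
        assert (np.diff(means) < 0).all()


class TestMedianSplitBootstrap:
    def test_identical_groups_ci_contains_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 200)
        conf = np.tile([1, 4], 100)
        _, ci = bh.median_split_bootstrap(vals, conf, rng=1)
        assert ci[0] < 0 < ci[1]

    def test_constructed_difference_recovered(self):
        rng = np.random.default_rng(2)
        conf = np.tile([1, 4], 300)
        vals = np.where(conf >= 2, 0.1, 0.0) + rng.normal(0, 0.02, 600)
        diffs, ci = bh.median_split_bootstrap(vals, conf, rng=3)
        assert diffs.mean() == pytest.approx(0.1, abs=0.02)
        assert ci[0] > 0

    def test_median_ties_go_high(self):
        high = bh.median_split([2, 2, 2, 4])
        assert high.all()

    def test_empty_group_named(self):
        with pytest.raises(ValueError, match="low"):
            bh.median_split_bootstrap([1.0, 2.0], [3, 3], rng=0)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(4)
        widths = []
        for n in (100, 400, 1600):
            conf = np.tile([1, 4], n // 2)
            vals = rng.normal(0, 1, n)
            _, ci = bh.median_split_bootstrap(vals, conf, rng=5)
            widths.append(ci[1] - ci[0])
        assert widths[0] > widths[1] > widths[2]


class TestExactTests:
    def test_sign_test_extreme_one_sided(self):
        a = np.arange(10) + 1.0   # all positive differences
        b = np.zeros(10)
        k, p = bh.sign_test(b, a, sided="one")   # 10 of 10 negative... as b<a
        assert k == 10
        k, p = bh.sign_test(a, b, sided="one")   # 0 negative
        assert k == 0
        assert p == pytest.approx(2 ** -10, rel=1e-9)

    def test_sign_test_balanced_two_sided(self):
        a = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], float)
        b = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], float)
        _, p = bh.sign_test(a, b, sided="two")
        assert p == pytest.approx(1.0)

    def test_sign_test_monotone_invariance(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=20), rng.normal(size=20)
        k1, p1 = bh.sign_test(a, b)
        k2, p2 = bh.sign_test(np.exp(a), np.exp(b))
        assert (k1, p1) == (k2, p2)

    def test_all_ties_rejected(self):
        with pytest.raises(ValueError):
            bh.sign_test([1.0, 2.0], [1.0, 2.0])

    def test_binomial_16_of_18(self):
        # exact tail: 172/2^18, doubled
        assert bh.binomial_vs_half(16, 18) == pytest.approx(
            2 * 172 / 2 ** 18, rel=1e-9)
        assert bh.binomial_vs_half(16, 18) == pytest.approx(0.0013, abs=2e-4)

    def test_binomial_capped_and_extreme(self):
        assert bh.binomial_vs_half(9, 18) == 1.0
        assert bh.binomial_vs_half(18, 18) == pytest.approx(2 * 2 ** -18)

    def test_binomial_bad_input(self):
        with pytest.raises(ValueError):
            bh.binomial_vs_half(1, 0)


class TestChanceTest:
    def test_degenerate_at_chance(self):
        mean_diff, t, p = bh.chance_test([0.5, 0.5, 0.5], 0.5)
        assert (mean_diff, t, p) == (0.0, 0.0, 1.0)

    def test_constructed_effect_detected(self):
        rng = np.random.default_rng(7)
        rates = rng.normal(0.55, 0.02, 18)
        mean_diff, t, p = bh.chance_test(rates, 0.5)
        assert mean_diff == pytest.approx(0.05, abs=0.02)
        assert p < 0.001

    def test_shift_invariance(self):
        rates = [0.52, 0.58, 0.49, 0.61]
        d1, _, _ = bh.chance_test(rates, 0.5)
        d2, _, _ = bh.chance_test(np.array(rates) + 0.1, 0.5)
        assert d2 - d1 == pytest.approx(0.1)


class TestCorrelations:
    def test_fisher_z_zero(self):
        assert bh.fisher_z(0.0) == 0.0

    def test_fisher_z_infinite_flagged(self):
        with pytest.warns(UserWarning):
            assert bh.fisher_z(1.0) == np.inf

    def test_spearman_perfect_and_hand_example(self):
        assert bh.spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert bh.spearman_rho([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=20,
                    unique=True))
    @settings(max_examples=40, deadline=None)
    def test_spearman_bounded(self, x):
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(x))
        assert -1.0 <= bh.spearman_rho(x, y) <= 1.0
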