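"""Behavioural statistics for the hidden-state gambling task.

Covers the session-level learning measures: optimal-action selection
rates against the 0.5 chance level, the win-stay-lose-switch (WSLS)
replay baseline, the latent-state-bias statistic, confidence-binned
summaries, bootstrap median-split contrasts, and the nonparametric tests
(exact sign and binomial tests, one-sample tests against chance,
Spearman/Fisher transforms, Benjamini-Hochberg FDR).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .task import TaskConfig


def optimal_action_rate(data: pd.DataFrame) -> float:
    """Fraction of trials on which the chosen action was the optimal one
    for the trial's latent state."""
    if len(data) == 0:
        raise ValueError("empty trial data")
    return float((data["action"] == data["optimal_action"]).mean())


def discrimination_accuracy(data: pd.DataFrame) -> float:
    """Fraction of trials with a correct perceptual report of the
    (decoder-defined) latent state."""
    if len(data) == 0:
        raise ValueError("empty trial data")
    return float((data["discrimination"] == data["latent_state"]).mean())


def _wsls_replay_once(actions, rewards, states, optimal_actions,
                      convention: str, config: TaskConfig,
                      rng: np.random.Generator | None) -> np.ndarray:
    replay = np.empty(len(actions), dtype=object)
    replay[0] = actions[0]
    prev_reward = None
    for t in range(len(actions)):
        if t > 0:
            if prev_reward == 1:
                replay[t] = replay[t - 1]
            else:
                replay[t] = "B" if replay[t - 1] == "A" else "A"
        if convention == "observed" or replay[t] == actions[t]:
            prev_reward = int(rewards[t])
        else:
            # off the subject's path: draw the counterfactual reward the
            # heuristic would have received under the 0.8/0.2 rule
            p = (config.reward_p_optimal if replay[t] == optimal_actions[t]
                 else config.reward_p_other)
            prev_reward = int(rng.random() < p)
    return replay


def wsls_replay(data: pd.DataFrame, convention: str = "counterfactual",
                n_replays: int = 100, seed: int = 0,
                config: TaskConfig | None = None,
                return_actions: bool = False):
    """Win-stay-lose-switch baseline replayed over a subject's data.

    The heuristic starts from the subject's first action of each session
    and thereafter repeats its own previous action if that trial was
    rewarded, switching otherwise. Because rewards depend on the action
    taken, the observed reward is only defined on the subject's own path:

    * ``observed`` -- condition on the subject's observed rewards
      regardless of the replayed action (hand-traceable, deterministic);
    * ``counterfactual`` (default) -- use the observed reward when the
      replayed action matches the subject's, otherwise draw the reward
      the heuristic would have received from the 0.8/0.2 rule; the
      returned p(optimal) is averaged over ``n_replays`` seeded replays.

    Returns the replayed optimal-action rate (and, if requested, the
    replayed action sequence of the last replay).
    """
    if convention not in ("observed", "counterfactual"):
        raise ValueError(f"unknown convention {convention!r}")
    config = config or TaskConfig()
    sessions = ([g for _, g in data.groupby("session", sort=True)]
                if "session" in data.columns else [data])
    n_rep = 1 if convention == "observed" else n_replays
    rng = np.random.default_rng(seed)
    rates = []
    last_actions = []
    for _ in range(n_rep):
        n_opt = n_tot = 0
        last_actions = []
        for sess in sessions:
            replay = _wsls_replay_once(
                sess["action"].to_numpy(), sess["reward"].to_numpy(),
                sess["latent_state"].to_numpy(),
                sess["optimal_action"].to_numpy(), convention, config, rng)
            n_opt += int((replay == sess["optimal_action"].to_numpy()).sum())
            n_tot += len(replay)
            last_actions.append(replay)
        rates.append(n_opt / n_tot)
    rate = float(np.mean(rates))
    if return_actions:
        return rate, np.concatenate(last_actions)
    return rate


def state_bias_trace(states, window: int = 30,
                     smooth_span: int = 5) -> np.ndarray:
    """Trial-by-trial latent-state bias.

    The bias at trial t is the unsigned difference between the number of
    occurrences of each state within a centered window (span 30 trials,
    truncated at the edges), normalized by the window's trial count, then
    smoothed with a centered moving-average filter (span 5, shrinking at
    the edges). Values lie in [0, 1] and are invariant under a global
    relabeling of the two states.
    """
    s = np.asarray([1 if v in ("R", 1) else 0 for v in states])
    n = len(s)
    if n == 0:
        raise ValueError("empty state sequence")
    half = window // 2
    raw = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + (window - half))
        w = s[lo:hi]
        raw[i] = abs(int(w.sum()) - (len(w) - int(w.sum()))) / len(w)
    return (pd.Series(raw)
            .rolling(smooth_span, center=True, min_periods=1)
            .mean().to_numpy())


def confidence_binned(metric_values, confidence_levels,
                      levels=(1, 2, 3, 4)) -> pd.DataFrame:
    """Mean of a trial metric per confidence level, with counts.

    Unoccupied levels are reported as missing (NaN mean, zero count),
    never as zero means.
    """
    metric = np.asarray(metric_values, dtype=float)
    conf = np.asarray(confidence_levels)
    if metric.shape != conf.shape:
        raise ValueError("metric and confidence must have the same length")
    rows = []
    for lv in levels:
        mask = conf == lv
        rows.append({"confidence": lv,
                     "mean": float(metric[mask].mean()) if mask.any()
                     else np.nan,
                     "count": int(mask.sum())})
    return pd.DataFrame(rows)


def median_split(confidence) -> np.ndarray:
    """Boolean high-confidence mask: ratings equal to or above the median
    count as 'high', below as 'low'."""
    conf = np.asarray(confidence, dtype=float)
    return conf >= np.median(conf)


def median_split_bootstrap(values, confidence, n_boot: int = 500,
                           rng: np.random.Generator | int | None = 0):
    """Bootstrapped mean difference (high minus low confidence).

    Trials are split at the within-set median confidence (ties to high).
    On each of ``n_boot`` runs both groups are resampled with replacement
    at their own sizes and the difference of means recorded. Returns the
    bootstrap distribution and its empirical 95% CI (2.5/97.5
    percentiles); the absence of 0 in the CI is read as significance.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    values = np.asarray(values, dtype=float)
    high = median_split(confidence)
    hi_vals, lo_vals = values[high], values[~high]
    for name, grp in (("high", hi_vals), ("low", lo_vals)):
        if len(grp) == 0:
            raise ValueError(f"{name}-confidence group is empty")
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        diffs[b] = (rng.choice(hi_vals, len(hi_vals)).mean()
                    - rng.choice(lo_vals, len(lo_vals)).mean())
    ci = (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))
    return diffs, ci


def sign_test(paired_a, paired_b, sided: str = "two") -> tuple[int, float]:
    """Exact sign test on paired values; ties are dropped.

    Returns the count of negative differences (a < b) and the exact
    binomial tail probability at p = 0.5 (one-sided: lower tail of the
    count; two-sided: doubled smaller tail, capped at 1).
    """
    a, b = np.asarray(paired_a, float), np.asarray(paired_b, float)
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all pairs tied; sign test undefined")
    k = int((d < 0).sum())
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    if sided == "one":
        p = lower
    elif sided == "two":
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    return k, float(p)


def binomial_vs_half(successes: int, n: int) -> float:
    """Two-sided exact binomial test against 0.5, doubling the smaller
    tail and capping at 1."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= successes <= n):
        raise ValueError("successes out of range")
    lower = stats.binom.cdf(successes, n, 0.5)
    upper = stats.binom.sf(successes - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def chance_test(subject_rates, chance: float = 0.5
                ) -> tuple[float, float, float]:
    """One-sample test of subject-level rates against chance.

    This is the subject-level summary form of an intercept-only
    random-effects model: the intercept estimate is the mean difference
    from chance and inference is a two-sided one-sample t-test. Returns
    (mean_diff, t, p).
    """
    rates = np.asarray(subject_rates, dtype=float)
    if len(rates) < 2:
        raise ValueError("need at least 2 subjects")
    diffs = rates - chance
    mean_diff = float(diffs.mean())
    if np.allclose(diffs.std(ddof=1), 0.0):
        if mean_diff == 0.0:
            return 0.0, 0.0, 1.0
        return mean_diff, np.inf, 0.0
    t, p = stats.ttest_1samp(diffs, 0.0)
    return mean_diff, float(t), float(p)


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform, atanh(r)."""
    if abs(r) > 1:
        raise ValueError("correlation must lie in [-1, 1]")
    if abs(r) == 1:
        warnings.warn("|r| = 1: Fisher z is infinite", stacklevel=2)
        return float(np.sign(r) * np.inf)
    return float(np.arctanh(r))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    return float(stats.spearmanr(x, y).statistic)


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for one test family."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def session_summary(data: pd.DataFrame) -> pd.DataFrame:
    """Per-(subject, session) summary of the core behavioural measures."""
    rows = []
    for (subj, sess), g in data.groupby(["subject", "session"], sort=True):
        correct_opt = (g["action"] == g["optimal_action"]).astype(float)
        correct_dis = (g["discrimination"] == g["latent_state"]).astype(float)
        row = {
            "subject": subj, "session": sess,
            "p_opt_action": optimal_action_rate(g),
            "p_correct_discrimination": discrimination_accuracy(g),
            "wsls_p_opt": wsls_replay(g),
            "state_bias_mean": float(state_bias_trace(
                g["latent_state"].to_numpy()).mean()),
            "median_confidence": float(g["confidence"].median()),
        }
        for lv, sub in (("p_opt", correct_opt),
                        ("p_discr", correct_dis)):
            binned = confidence_binned(sub.to_numpy(),
                                       g["confidence"].to_numpy())
            for _, r in binned.iterrows():
                row[f"{lv}_conf{int(r['confidence'])}"] = r["mean"]
        rows.append(row)
    return pd.DataFrame(rows)
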