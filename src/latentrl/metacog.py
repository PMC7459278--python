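"""Type-2 signal-detection analysis: d', meta-d', and their use.

meta-d' expresses metacognitive sensitivity -- how well trial-by-trial
confidence tracks discrimination accuracy -- on the type-1 d' scale: it
is the type-1 sensitivity an SDT-ideal observer would need, given the
observed type-1 response criterion, to produce the observed
response-conditional confidence distributions. It is estimated by
maximum likelihood over a multinomial model of the type-2 data under
equal-variance Gaussian assumptions, with response-specific type-2
criteria fitted jointly with a single meta-d'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .behavior import median_split

_EPS = 1e-12


def type2_counts(stimulus, response, confidence,
                 n_levels: int = 4) -> np.ndarray:
    """Tabulate (stimulus x response x confidence) counts.

    ``stimulus`` and ``response`` are binary class labels (any two
    values; they are matched against each other), confidence is 1..n.
    Returns an array of shape (2, 2, n_levels) indexed
    [stimulus, response, confidence-1].
    """
    stimulus = np.asarray(stimulus)
    response = np.asarray(response)
    confidence = np.asarray(confidence, dtype=int)
    classes = np.unique(stimulus)
    if len(classes) != 2:
        raise ValueError("both stimulus classes must be present")
    if confidence.min() < 1 or confidence.max() > n_levels:
        raise ValueError("confidence outside 1..n_levels")
    counts = np.zeros((2, 2, n_levels))
    for s, r, c in zip(stimulus, response, confidence):
        counts[int(s == classes[1]), int(r == classes[1]), c - 1] += 1
    return counts


def _rates(counts: np.ndarray, pad: bool) -> tuple[float, float]:
    c = counts.sum(axis=2).astype(float)
    if pad:
        c = c + 0.5
    far = c[0, 1] / c[0].sum()
    hit = c[1, 1] / c[1].sum()
    return hit, far


def dprime(counts: np.ndarray, pad: bool = True) -> tuple[float, float]:
    """Type-1 sensitivity and criterion, ``d' = z(H) - z(FA)`` and
    ``c = -(z(H) + z(FA)) / 2``, with half-count cell padding."""
    if counts[0].sum() == 0 or counts[1].sum() == 0:
        raise ValueError("both stimulus classes must be present")
    hit, far = _rates(counts, pad)
    zh, zf = stats.norm.ppf(hit), stats.norm.ppf(far)
    return float(zh - zf), float(-(zh + zf) / 2.0)


@dataclass
class MetaDFit:
    meta_d: float
    d_prime: float
    criterion: float
    neg_log_lik: float
    success: bool
    t2_criteria_low: np.ndarray   # below the type-1 criterion (resp 0)
    t2_criteria_high: np.ndarray  # above the type-1 criterion (resp 1)


def _t2_log_lik(params: np.ndarray, counts: np.ndarray, c1_ratio: float,
                n_levels: int) -> float:
    """Negative log-likelihood of response-conditional confidence counts.

    ``params`` = [meta_d, log-increments of the (n_levels-1) criteria on
    each side of the scaled type-1 criterion].
    """
    meta_d = params[0]
    inc_lo = np.exp(params[1:n_levels])
    inc_hi = np.exp(params[n_levels:])
    c1 = c1_ratio * meta_d
    crit_hi = c1 + np.cumsum(inc_hi)          # ascending above c1
    crit_lo = c1 - np.cumsum(inc_lo)          # descending below c1
    mus = (-meta_d / 2.0, meta_d / 2.0)
    nll = 0.0
    for s, mu in enumerate(mus):
        # response 1: decision variable above c1; confidence grows with
        # distance above c1 (bins split by crit_hi)
        edges_hi = np.concatenate(([c1], crit_hi, [np.inf]))
        p_hi = stats.norm.cdf(edges_hi[1:] - mu) - stats.norm.cdf(
            edges_hi[:-1] - mu)
        p_resp_hi = max(stats.norm.sf(c1 - mu), _EPS)
        nll -= np.sum(counts[s, 1] * np.log(
            np.maximum(p_hi / p_resp_hi, _EPS)))
        # response 0: below c1, confidence grows with distance below
        edges_lo = np.concatenate(([c1], crit_lo, [-np.inf]))
        p_lo = stats.norm.cdf(edges_lo[:-1] - mu) - stats.norm.cdf(
            edges_lo[1:] - mu)
        p_resp_lo = max(stats.norm.cdf(c1 - mu), _EPS)
        nll -= np.sum(counts[s, 0] * np.log(
            np.maximum(p_lo / p_resp_lo, _EPS)))
    return nll


def fit_meta_d(counts: np.ndarray, pad: bool = True) -> MetaDFit:
    """Maximum-likelihood meta-d' from type-2 count data.

    The type-1 criterion is carried into the meta model at a fixed
    relative position (c' = c * meta_d / d'), and a single meta-d' plus
    response-specific type-2 criteria are fitted to the
    response-conditional confidence distributions. Before fitting,
    ``1/(2 * n_levels)`` is added to every type-2 cell so the likelihood
    is finite for all inputs with at least two occupied levels.
    """
    n_levels = counts.shape[2]
    occupied = (counts.sum(axis=(0, 1)) > 0).sum()
    if occupied < 2:
        raise ValueError("need at least 2 occupied confidence levels")
    d1, c1 = dprime(counts, pad=pad)
    work = counts + (1.0 / (2 * n_levels) if pad else 0.0)
    c1_ratio = c1 / d1 if abs(d1) > 1e-8 else 0.0

    x0 = np.concatenate(([d1], np.full(2 * (n_levels - 1), np.log(0.4))))
    res = optimize.minimize(
        _t2_log_lik, x0, args=(work, c1_ratio, n_levels),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    if not res.success:
        # one restart from a neutral sensitivity
        x0[0] = 1.0
        res2 = optimize.minimize(
            _t2_log_lik, x0, args=(work, c1_ratio, n_levels),
            method="Nelder-Mead", options={"maxiter": 8000})
        if res2.fun <= res.fun:
            res = res2
    if not np.isfinite(res.fun):
        raise RuntimeError(
            f"meta-d' fit failed to converge (final NLL {res.fun!r})")
    meta_d = float(res.x[0])
    c1m = c1_ratio * meta_d
    return MetaDFit(
        meta_d=meta_d, d_prime=d1, criterion=c1,
        neg_log_lik=float(res.fun), success=bool(res.success),
        t2_criteria_low=c1m - np.cumsum(np.exp(res.x[1:n_levels])),
        t2_criteria_high=c1m + np.cumsum(np.exp(res.x[n_levels:])))


def meta_dprime(counts: np.ndarray, pad: bool = True) -> float:
    """Convenience wrapper returning only the fitted meta-d'."""
    return fit_meta_d(counts, pad=pad).meta_d


def binarize_confidence(ratings) -> np.ndarray:
    """Median-split 1-4 ratings into 'low'/'high' labels; ratings equal
    to or above the median are 'high'."""
    ratings = np.asarray(ratings)
    if len(ratings) == 0:
        raise ValueError("empty ratings")
    return np.where(median_split(ratings), "high", "low")


def metacog_vs_baseline(meta_d_values, baseline_p_opt
                        ) -> tuple[float, float, float]:
    """Across-subject association between metacognitive ability and
    baseline gambling performance.

    ``baseline_p_opt`` is each subject's minimal optimal-action rate over
    the first two sessions. Returns (Pearson r, robust regression slope,
    two-sided p of the correlation). The robust slope comes from an
    iteratively reweighted (Huber) linear fit.
    """
    import statsmodels.api as sm

    x = np.asarray(meta_d_values, dtype=float)
    y = np.asarray(baseline_p_opt, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired subjects")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in meta-d' or baseline rates")
    r, p = stats.pearsonr(x, y)
    rlm = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.HuberT()).fit()
    return float(r), float(rlm.params[1]), float(p)


def baseline_performance(summary) -> "pd.Series":
    """Per-subject baseline (minimal) optimal-action rate over sessions
    1 and 2, from a session-summary table."""
    import pandas as pd  # noqa: F401  (type only)

    early = summary[summary["session"].isin([1, 2])]
    return early.groupby("subject")["p_opt_action"].min()
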