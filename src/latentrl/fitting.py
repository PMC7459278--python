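"""Likelihood evaluation and grid-search fitting of the Q-learning models.

Two models are fit to choice data by minimizing the negative
log-likelihood of actions under the softmax rule:

* ``rl_sf`` -- state-free: Q attaches to actions only (k = 2 parameters);
* ``rl_sd`` -- state-dependent: Q attaches to (state, action) pairs; its
  noisy variant assumes partial, stochastic access to the state -- on a
  fraction ``eta`` of trials the value update (and choice) is based on
  the alternative state rather than the decoded one (k = 3 parameters).

The fit is a grid search over alpha in (0, 1) and beta in (0, 20) with 50
steps each. Because the noisy model is stochastic, it is evaluated over
100 resampling runs at each of 100 noise levels from 0 to 50%; the
likelihood at each level is averaged over runs, and the best level is
taken. Model comparison uses AIC = 2k + 2*NLL; a per-trial normalized
variant (2k + 2*NLL/n) is also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import Q_INIT

LN2 = float(np.log(2.0))

_STATE_CODE = {"L": 0, "R": 1}
_ACTION_CODE = {"A": 0, "B": 1}


def _encode(values, mapping, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    try:
        return np.array([mapping[v] for v in arr], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid {name} value {exc.args[0]!r}") from exc


def _extract(data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pull (states, actions, rewards) out of a trial table, enforcing
    chronological order -- the likelihood is sequential."""
    if isinstance(data, pd.DataFrame):
        if data.empty:
            raise ValueError("empty trial data")
        keys = [k for k in ("session", "block", "trial") if k in data.columns]
        if keys:
            idx = data[keys].to_numpy()
            if not all(tuple(idx[i]) <= tuple(idx[i + 1])
                       for i in range(len(idx) - 1)):
                raise ValueError(
                    "trials must be sorted by session/block/trial; "
                    "refusing shuffled data")
        states = (_encode(data["latent_state"], _STATE_CODE, "state")
                  if "latent_state" in data.columns else None)
        actions = _encode(data["action"], _ACTION_CODE, "action")
        rewards = np.asarray(data["reward"], dtype=np.int64)
    else:
        states, actions, rewards = data
        states = None if states is None else _encode(states, _STATE_CODE,
                                                     "state")
        actions = _encode(actions, _ACTION_CODE, "action")
        rewards = np.asarray(rewards, dtype=np.int64)
    if len(actions) == 0:
        raise ValueError("empty trial data")
    return states, actions, rewards


@dataclass
class GridSpec:
    """Grid-search resolution. Grid points are midpoints of equal
    subintervals, avoiding the open-interval endpoints exactly."""

    n_alpha: int = 50
    n_beta: int = 50
    beta_max: float = 20.0
    n_eta: int = 100
    eta_max: float = 0.5
    n_runs: int = 100

    @property
    def alphas(self) -> np.ndarray:
        return (np.arange(self.n_alpha) + 0.5) / self.n_alpha

    @property
    def betas(self) -> np.ndarray:
        return self.beta_max * (np.arange(self.n_beta) + 0.5) / self.n_beta

    @property
    def etas(self) -> np.ndarray:
        return np.linspace(0.0, self.eta_max, self.n_eta)


@dataclass
class FitResult:
    model: str                       # rl_sf | rl_sd_noiseless | rl_sd_noisy
    alpha_hat: float
    beta_hat: float
    eta_hat: float | None
    neg_log_lik: float
    n_trials: int
    aic: float
    aic_normalized: float
    grid_spec: GridSpec
    seed: int | None = None
    boundary: bool = False           # degenerate data flag

    @staticmethod
    def n_params(model: str) -> int:
        return 3 if model == "rl_sd_noisy" else 2


def _aic(nll: float, k: int) -> float:
    return 2.0 * k + 2.0 * nll


def _dq_trace_sf(actions, rewards, alphas) -> np.ndarray:
    """Signed value difference of the chosen action per trial, vectorized
    over the alpha grid. Shape (n_alpha, T)."""
    n_alpha, T = len(alphas), len(actions)
    q = np.full((n_alpha, 2), Q_INIT)
    out = np.empty((n_alpha, T))
    for t in range(T):
        a = actions[t]
        dq = q[:, 0] - q[:, 1]
        out[:, t] = dq if a == 0 else -dq
        q[:, a] += alphas * (rewards[t] - q[:, a])
    return out


def _dq_trace_sd(states, actions, rewards, alphas,
                 choice_states=None) -> np.ndarray:
    """As `_dq_trace_sf` but state-dependent; ``states`` may be a 2-D
    array (n_runs, T) of perceived states, vectorizing over resampling
    runs. When ``choice_states`` (1-D, the decoded states) is given, the
    choice-probability state is taken from it while the update still uses
    the perceived states (the update-only noise variant). Shape
    (n_runs, n_alpha, T)."""
    states = np.atleast_2d(states)
    R, T = states.shape
    n_alpha = len(alphas)
    q = np.full((R, n_alpha, 2, 2), Q_INIT)
    out = np.empty((R, n_alpha, T))
    rows = np.arange(R)
    for t in range(T):
        s = states[:, t]
        a = actions[t]
        sc = s if choice_states is None else np.full(R, choice_states[t])
        dq = q[rows, :, sc, 0] - q[rows, :, sc, 1]
        out[:, :, t] = dq if a == 0 else -dq
        cur = q[rows, :, s, a]
        q[rows, :, s, a] = cur + alphas[None, :] * (rewards[t] - cur)
    return out


def _nll_from_dq(dq_signed: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """NLL over the beta grid from signed chosen-action value differences.

    ``-log P(chosen) = softplus(-beta * dq_signed)`` summed over trials.
    Input (..., T); output (..., n_beta).
    """
    x = -dq_signed[..., None, :] * betas[:, None]
    return np.logaddexp(0.0, x).sum(axis=-1)


def neg_log_lik_rl_sf(data, alpha: float, beta: float) -> float:
    """Deterministic NLL of the state-free model at one (alpha, beta)."""
    _, actions, rewards = _extract(data)
    dq = _dq_trace_sf(actions, rewards, np.array([alpha]))
    return float(_nll_from_dq(dq, np.array([beta]))[0, 0])


def neg_log_lik_rl_sd(data, alpha: float, beta: float, eta: float = 0.0,
                      rng: np.random.Generator | None = None,
                      noise_on_choice: bool = True) -> float:
    """One (stochastic, unless eta=0) NLL evaluation of the
    state-dependent model: each trial's state is flipped w.p. eta, and
    the flipped state drives the value update and -- by default -- also
    the choice likelihood (``noise_on_choice=False`` restricts the flip
    to the update)."""
    true_states, actions, rewards = _extract(data)
    if true_states is None:
        raise ValueError("state-dependent model requires a latent_state "
                         "column")
    if not (0.0 <= eta <= 0.5):
        raise ValueError("eta must lie in [0, 0.5]")
    states = true_states
    if eta > 0:
        if rng is None:
            raise ValueError("eta > 0 requires an rng")
        flips = rng.random(len(states)) < eta
        states = np.where(flips, 1 - states, states)
    dq = _dq_trace_sd(states, actions, rewards, np.array([alpha]),
                      choice_states=None if noise_on_choice
                      else true_states)
    return float(_nll_from_dq(dq, np.array([beta]))[0, 0, 0])


def fit_grid(data, model: str, grid_spec: GridSpec | None = None,
             seed: int | None = None, run_chunk: int = 25,
             noise_on_choice: bool = True) -> FitResult:
    """Grid-search fit of one subject-session's choices.

    For ``rl_sf`` and ``rl_sd_noiseless`` the fit is the deterministic
    argmin over the (alpha, beta) grid. For ``rl_sd_noisy``, each noise
    level's NLL surface is averaged over resampling runs with fresh RNG
    substreams; the selected level minimizes the mean of the grid-
    minimized NLL over runs, and (alpha_hat, beta_hat) come from the best
    run-averaged cell at that level. Ties break toward the smallest eta,
    then alpha, then beta.
    """
    spec = grid_spec or GridSpec()
    states, actions, rewards = _extract(data)
    n = len(actions)
    boundary = len(np.unique(actions)) < 2
    if boundary:
        warnings.warn("single action throughout; fit is at a likelihood "
                      "boundary", stacklevel=2)
    alphas, betas = spec.alphas, spec.betas
    k = FitResult.n_params(model)

    if model == "rl_sf":
        grid = _nll_from_dq(_dq_trace_sf(actions, rewards, alphas), betas)
        ia, ib = np.unravel_index(np.argmin(grid), grid.shape)
        nll = float(grid[ia, ib])
        return FitResult(model, float(alphas[ia]), float(betas[ib]), None,
                         nll, n, _aic(nll, k), 2 * k + 2 * nll / n, spec,
                         seed, boundary)

    if states is None:
        raise ValueError("state-dependent model requires latent_state data")

    if model == "rl_sd_noiseless":
        grid = _nll_from_dq(
            _dq_trace_sd(states, actions, rewards, alphas), betas)[0]
        ia, ib = np.unravel_index(np.argmin(grid), grid.shape)
        nll = float(grid[ia, ib])
        return FitResult(model, float(alphas[ia]), float(betas[ib]), None,
                         nll, n, _aic(nll, k), 2 * k + 2 * nll / n, spec,
                         seed, boundary)

    if model != "rl_sd_noisy":
        raise ValueError(f"unknown model {model!r}")

    ss = np.random.SeedSequence(0 if seed is None else seed)
    best = None  # (mean_min_nll, eta_idx, avg_grid)
    for ie, eta in enumerate(spec.etas):
        if eta == 0.0:
            grid = _nll_from_dq(
                _dq_trace_sd(states, actions, rewards, alphas), betas)[0]
            mean_min = float(grid.min())
            avg_grid = grid
        else:
            # fresh substream per eta level; runs chunked within it
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(ie,)))
            sum_grid = np.zeros((len(alphas), len(betas)))
            sum_min = 0.0
            done = 0
            while done < spec.n_runs:
                r = min(run_chunk, spec.n_runs - done)
                flips = rng.random((r, len(states))) < eta
                pstates = np.where(flips, 1 - states[None, :],
                                   states[None, :])
                grids = _nll_from_dq(
                    _dq_trace_sd(pstates, actions, rewards, alphas,
                                 choice_states=None if noise_on_choice
                                 else states), betas)
                sum_grid += grids.sum(axis=0)
                sum_min += float(grids.min(axis=(1, 2)).sum())
                done += r
            avg_grid = sum_grid / spec.n_runs
            mean_min = sum_min / spec.n_runs
        if best is None or mean_min < best[0]:
            best = (mean_min, ie, avg_grid)

    mean_min, ie, avg_grid = best
    ia, ib = np.unravel_index(np.argmin(avg_grid), avg_grid.shape)
    nll = mean_min
    return FitResult("rl_sd_noisy", float(alphas[ia]), float(betas[ib]),
                     float(spec.etas[ie]), nll, n, _aic(nll, k),
                     2 * k + 2 * nll / n, spec, seed, boundary)


@dataclass
class ModelComparison:
    delta_aic: float                 # AIC_sd - AIC_sf; negative favours sd
    delta_aic_normalized: float
    aic_sd: float
    aic_sf: float


def compare_models(fit_sd: FitResult, fit_sf: FitResult) -> ModelComparison:
    """AIC difference between the state-dependent and state-free fits of
    the same data; negative values favour the noisy state-dependent
    model. Also reports the per-trial normalized-likelihood variant."""
    if fit_sd.n_trials != fit_sf.n_trials:
        raise ValueError("fits must be on the same data "
                         f"({fit_sd.n_trials} vs {fit_sf.n_trials} trials)")
    return ModelComparison(
        delta_aic=fit_sd.aic - fit_sf.aic,
        delta_aic_normalized=fit_sd.aic_normalized - fit_sf.aic_normalized,
        aic_sd=fit_sd.aic, aic_sf=fit_sf.aic)


def rpe_trace(data, alpha: float, beta: float) -> pd.DataFrame:
    """Trial-by-trial reward-prediction errors from the noiseless
    state-dependent model replayed over the data.

    ``rpe_t = r_t - Q(s_t, a_t)`` before the update; values reset to the
    uninformed prior at every session boundary. Returns a frame with
    columns ``q_chosen``, ``rpe`` and ``abs_rpe`` aligned to the input
    rows. |RPE| lies in [0, 1] for binary rewards and Q in [0, 1].
    """
    if isinstance(data, pd.DataFrame):
        frames = ([g for _, g in data.groupby("session", sort=True)]
                  if "session" in data.columns else [data])
    else:
        frames = [data]
    qs, rpes = [], []
    for frame in frames:
        states, actions, rewards = _extract(frame)
        if states is None:
            raise ValueError("rpe_trace requires latent_state data")
        q = np.full((2, 2), Q_INIT)
        for s, a, r in zip(states, actions, rewards):
            qs.append(q[s, a])
            rpes.append(r - q[s, a])
            q[s, a] += alpha * (r - q[s, a])
    qs, rpes = np.array(qs), np.array(rpes)
    index = data.index if isinstance(data, pd.DataFrame) else None
    return pd.DataFrame({"q_chosen": qs, "rpe": rpes,
                         "abs_rpe": np.abs(rpes)}, index=index)
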