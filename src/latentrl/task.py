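"""Generative model of the closed-loop hidden-state gambling task.

The task couples a latent binary state -- nominally the output of a
real-time multivoxel decoder classifying leftward vs. rightward motion
representations -- to a two-armed bandit. On every trial one of the two
actions (A/B) is optimal for the current latent state and pays reward
with probability 0.8; the other pays with probability 0.2. The decoder
output likelihood additionally drives the coherence of a random-dot
stimulus in the final (control) session via ``coh = c * arctan(L - 0.5)``.

Here the decoder channel is modelled directly: a hidden ``pattern_class``
(the ground-truth direction represented in the simulated brain activity)
passes through a noisy binary channel of fidelity ``decoder_accuracy``
to yield the ``latent_state`` that defines the reinforcement-learning
state. Agents never observe the pattern class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

STATES = ("L", "R")
ACTIONS = ("A", "B")

#: Per-trial event durations in seconds. The accounted events (ITI 6,
#: random-dot stimulus 8, blank 1, discrimination 1.5, confidence 1.5)
#: leave 4 s of the 22-s trial for action selection and outcome, which we
#: split 2 s / 2 s (outcome presentation lasts 2 s).
DEFAULT_TRIAL_TIMING: Mapping[str, float] = {
    "iti": 6.0,
    "rdm": 8.0,
    "blank": 1.0,
    "discrimination": 1.5,
    "confidence": 1.5,
    "action": 2.0,
    "outcome": 2.0,
}


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")


@dataclass
class TaskConfig:
    """Parameters of the hidden-state bandit task.

    Defaults reproduce the reinforcement-learning stage: three sessions of
    ~10-12 blocks of 12 trials (1 trial = 22 s), each block preceded by a
    30-s fixation and closed by a 6-s blank (1 block = 300 s), rewards
    0.8/0.2, and a reward of 30 JPY per rewarded trial (informational).
    """

    n_sessions: int = 3
    blocks_per_session: Sequence[int] = (10, 11, 11)
    trials_per_block: int = 12
    reward_p_optimal: float = 0.8
    reward_p_other: float = 0.2
    reward_value: float = 30.0
    state_bias: float = 0.5
    decoder_accuracy: float = 0.70
    likelihood_scale: float = 0.15
    trial_timing: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRIAL_TIMING)
    )
    block_lead_in: float = 30.0
    block_tail: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reward_p_optimal", "reward_p_other", "state_bias",
                     "decoder_accuracy"):
            _check_prob(name, getattr(self, name))
        if self.trials_per_block < 0:
            raise ValueError("trials_per_block must be nonnegative")
        if len(self.blocks_per_session) < self.n_sessions:
            raise ValueError("blocks_per_session shorter than n_sessions")

    @property
    def trial_duration(self) -> float:
        return float(sum(self.trial_timing.values()))


@dataclass
class TrialRecord:
    """One task trial with ground truth alongside observable behaviour."""

    subject: str
    group: str
    session: int
    block: int
    trial: int
    pattern_class: str     # simulator-internal ground truth class
    latent_state: str      # decoder output; the RL state s
    likelihood: float      # decoder output L, evidence for state R
    coherence: float       # coh = gain * arctan(L - 0.5)
    discrimination: str    # perceptual report, L or R
    confidence: int        # 1-4
    action: str            # A or B
    reward: int            # 0/1
    optimal_action: str
    gen_rpe: float = float("nan")  # generating agent's prediction error


def sample_latent_state(state_bias: float, decoder_accuracy: float,
                        rng: np.random.Generator) -> tuple[str, str]:
    """Draw a pattern class and pass it through the decoder channel.

    ``pattern_class`` is R with probability ``state_bias``; the returned
    ``latent_state`` equals the pattern class with probability
    ``decoder_accuracy`` and is flipped otherwise. The latent state (the
    decoder output) is what defines the RL state; any asymmetry in it is
    an inherent feature of state estimation through decoding.
    """
    _check_prob("state_bias", state_bias)
    _check_prob("decoder_accuracy", decoder_accuracy)
    pattern = "R" if rng.random() < state_bias else "L"
    if rng.random() < decoder_accuracy:
        latent = pattern
    else:
        latent = "L" if pattern == "R" else "R"
    return pattern, latent


def coherence_from_likelihood(likelihood: float, gain: float) -> float:
    """Motion coherence driven by the decoder likelihood.

    ``coh = gain * arctan(L - 0.5)``: negative values indicate leftward,
    positive rightward motion; zero evidence (L = 0.5) yields zero
    coherence.
    """
    if not (0.0 <= likelihood <= 1.0):
        raise ValueError(f"likelihood must lie in [0, 1], got {likelihood!r}")
    if gain < 0:
        raise ValueError("gain must be nonnegative")
    return gain * math.atan(likelihood - 0.5)


def coherence_gain_schedule(trial_index: int, n_trials_session: int,
                            session: int = 3) -> float:
    """Session-level ramp of the coherence constant c.

    Sessions 1 and 2 present fully random motion (c = 0). In session 3, c
    follows a logistic ramp over (0, 1) across the first half of the
    session and stays at plateau thereafter: midpoint at 25% of the
    session's trials, slope set so the gain exceeds 0.95 by the 50% mark.
    """
    if not (1 <= trial_index <= n_trials_session):
        raise ValueError(
            f"trial_index {trial_index} outside [1, {n_trials_session}]")
    if session < 3:
        return 0.0
    midpoint = 0.25 * n_trials_session
    slope = 12.0 / n_trials_session   # slope * (0.5 - 0.25) * n = 3 logits
    t = min(float(trial_index), 0.5 * n_trials_session)  # plateau after half
    return 1.0 / (1.0 + math.exp(-slope * (t - midpoint)))


def contrast_schedule(trial_index: int, n_trials_session: int,
                      session: int = 3) -> float:
    """Dot contrast: fixed at 20% in sessions 1-2, ramping to 100% in
    session 3 with the same logistic shape as the coherence gain."""
    if session < 3:
        if not (1 <= trial_index <= n_trials_session):
            raise ValueError("trial_index out of range")
        return 0.2
    g = coherence_gain_schedule(trial_index, n_trials_session, session)
    return 0.2 + 0.8 * g


def default_optimal_map(rng: np.random.Generator | None = None
                        ) -> dict[str, str]:
    """State -> optimal-action bijection; randomized once per subject when
    an RNG is given (e.g. state L -> action B, state R -> action A)."""
    if rng is not None and rng.random() < 0.5:
        return {"L": "B", "R": "A"}
    return {"L": "A", "R": "B"}


def reward_outcome(latent_state: str, action: str, config: TaskConfig,
                   rng: np.random.Generator,
                   optimal_map: Mapping[str, str] | None = None) -> int:
    """Bernoulli reward: p_optimal if the action is optimal for the
    current latent state, p_other otherwise."""
    if latent_state not in STATES or action not in ACTIONS:
        raise ValueError(f"invalid state/action {(latent_state, action)!r}")
    optimal_map = optimal_map or default_optimal_map()
    p = (config.reward_p_optimal if action == optimal_map[latent_state]
         else config.reward_p_other)
    return int(rng.random() < p)


def block_duration(config: TaskConfig) -> float:
    """Total block length: lead-in + trials * trial duration + tail."""
    return (config.block_lead_in
            + config.trials_per_block * config.trial_duration
            + config.block_tail)


def stage1_block_duration(n_trials: int = 20, lead_in: float = 6.0,
                          tail: float = 6.0, event_s: float = 9.0,
                          iti_total: float = 100.0) -> float:
    """Decoder-construction stage block: 20 trials of 9-s events (2 s
    stimulus + 4 s delay + 3 s responses) with variable ITIs balanced to a
    fixed total, bracketed by 6-s fixation periods (1 run = 292 s)."""
    return lead_in + n_trials * event_s + iti_total + tail


def stage1_itis(n_trials: int = 20, total: float = 100.0,
                choices: Sequence[int] = (3, 4, 5, 6),
                rng: np.random.Generator | None = None) -> list[int]:
    """Inter-trial intervals drawn from {3,4,5,6} s, shuffled from a
    balanced multiset summing to the fixed block total."""
    base = list(choices) * (n_trials // len(choices))
    while sum(base) < total:
        base[base.index(min(base))] += 1
    if sum(base) != total or len(base) != n_trials:
        raise ValueError("cannot balance ITIs to the requested total")
    if rng is not None:
        rng.shuffle(base)
    return base


def _draw_likelihood(latent_state: str, scale: float,
                     rng: np.random.Generator) -> float:
    """Decoder likelihood consistent with its categorical output: evidence
    magnitude is half-normal with the given scale, signed toward the
    decoded state."""
    margin = abs(rng.normal(0.0, scale))
    value = 0.5 + margin if latent_state == "R" else 0.5 - margin
    return float(min(1.0, max(0.0, value)))


def run_session(agent, config: TaskConfig, session: int,
                rng: np.random.Generator,
                optimal_map: Mapping[str, str] | None = None,
                subject: str = "S01", group: str = "VC",
                n_blocks: int | None = None) -> list[TrialRecord]:
    """Simulate one session of the closed-loop task with the given agent.

    The agent sees only its (possibly noisy) state percept, the stimulus
    evidence, its own responses and the reward -- never the pattern class.
    Records carry the ground-truth fields for downstream analysis.
    """
    optimal_map = optimal_map or default_optimal_map()
    if n_blocks is None:
        n_blocks = int(config.blocks_per_session[session - 1])
    n_trials_session = n_blocks * config.trials_per_block
    records: list[TrialRecord] = []
    if hasattr(agent, "start_session"):
        agent.start_session()
    t_session = 0
    for block in range(1, n_blocks + 1):
        for trial in range(1, config.trials_per_block + 1):
            t_session += 1
            pattern, latent = sample_latent_state(
                config.state_bias, config.decoder_accuracy, rng)
            likelihood = _draw_likelihood(latent, config.likelihood_scale, rng)
            gain = coherence_gain_schedule(t_session, n_trials_session,
                                           session)
            coh = coherence_from_likelihood(likelihood, gain)
            discrimination, confidence, action = agent.act(
                latent_state=latent, likelihood=likelihood, coherence=coh,
                rng=rng)
            if action not in ACTIONS:
                raise RuntimeError(
                    f"agent returned invalid action {action!r}")
            reward = reward_outcome(latent, action, config, rng, optimal_map)
            agent.learn(reward=reward)
            gen_rpe = getattr(agent, "last_rpe", None)
            records.append(TrialRecord(
                subject=subject, group=group, session=session, block=block,
                trial=trial, pattern_class=pattern, latent_state=latent,
                likelihood=likelihood, coherence=coh,
                discrimination=discrimination, confidence=int(confidence),
                action=action, reward=int(reward),
                optimal_action=optimal_map[latent],
                gen_rpe=float("nan") if gen_rpe is None else float(gen_rpe)))
    return records
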