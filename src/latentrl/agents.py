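"""Behavioural policies for the hidden-state bandit.

Four agent kinds generate choices, confidence and discrimination reports
inside the simulator:

* ``random`` -- uniform action choice, the chance baseline;
* ``wsls`` -- win-stay-lose-switch: repeat the previous action after a
  reward, switch otherwise;
* ``rl_sf`` -- state-free Q-learning: values attach to actions only,
  ``Q(a) <- Q(a) + alpha * (r - Q(a))``;
* ``rl_sd`` -- state-dependent Q-learning: values attach to
  (state, action) pairs, ``Q(s,a) <- Q(s,a) + alpha * (r - Q(s,a))``,
  with partial and stochastic access to the state: on a fraction ``eta``
  of trials the perceived state is the alternative of the decoded one.

Action probabilities follow a softmax (logistic) rule with inverse
temperature ``beta``. Confidence ratings (1-4) are generated from the
magnitude of the stimulus evidence through a gain + Gaussian noise map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .task import ACTIONS, STATES

#: Q-values start at 0.5, the expected value of an uninformed arm under
#: the symmetric 0.8/0.2 reward rule.
Q_INIT = 0.5

#: Reference point for the confidence map: the typical evidence magnitude
#: |L - 0.5| under the default decoder-likelihood scale.
EVIDENCE_REF = 0.10


@dataclass
class AgentParams:
    kind: str = "rl_sd"             # random | wsls | rl_sf | rl_sd
    alpha: float = 0.3              # learning rate, (0, 1)
    beta: float = 5.0               # inverse temperature, [0, 20)
    eta: float = 0.0                # state-perception flip rate, [0, 0.5]
    conf_gain: float = 10.0         # evidence -> confidence gain
    conf_noise: float = 0.5         # SD of confidence noise (rating units)
    discrim_accuracy: float = 0.5   # baseline P(correct discrimination)
    #: if True (default), the same noisy percept drives both the softmax
    #: choice and the value update (the agent acts on what it perceives);
    #: if False, only the update uses the flipped state.
    noise_on_choice: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("random", "wsls", "rl_sf", "rl_sd"):
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 <= self.beta <= 20.0):
            raise ValueError("beta must lie in [0, 20]")
        if not (0.0 <= self.eta <= 0.5):
            raise ValueError("eta must lie in [0, 0.5]")
        if self.conf_gain < 0 or self.conf_noise < 0:
            raise ValueError("confidence parameters must be nonnegative")


def q_update(q: float, alpha: float, r: int) -> tuple[float, float]:
    """Delta-rule value update; returns (new value, prediction error).

    ``rpe = r - q`` and ``q_new = q + alpha * rpe``; only the selected
    (state-contingent, for the state-dependent learner) entry is updated.
    """
    rpe = r - q
    return q + alpha * rpe, rpe


def choice_prob(q_a: float, q_b: float, beta: float) -> float:
    """Softmax probability of choosing action A, ``1/(1+exp(-beta*dq))``.

    Numerically stable for large ``|beta * (q_a - q_b)|``.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    x = beta * (q_a - q_b)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def perceive_state(latent_state: str, eta: float,
                   rng: np.random.Generator) -> str:
    """Noisy state percept: the decoded state, flipped w.p. ``eta``."""
    if not (0.0 <= eta <= 0.5):
        raise ValueError("eta must lie in [0, 0.5]")
    if latent_state not in STATES:
        raise ValueError(f"invalid state {latent_state!r}")
    if eta > 0 and rng.random() < eta:
        return "L" if latent_state == "R" else "R"
    return latent_state


def make_confidence(evidence_mag: float, conf_gain: float, conf_noise: float,
                    rng: np.random.Generator,
                    evidence_ref: float = EVIDENCE_REF) -> int:
    """Map evidence magnitude to a 1-4 rating.

    ``clip(round(2.5 + gain * (|evidence| - ref) + N(0, noise)), 1, 4)``;
    with zero noise the expected rating is nondecreasing in |evidence|.
    """
    raw = 2.5 + conf_gain * (evidence_mag - evidence_ref)
    if conf_noise > 0:
        raw += rng.normal(0.0, conf_noise)
    return int(min(4, max(1, round(raw))))


def _discriminate(latent_state: str, coherence: float, accuracy: float,
                  rng: np.random.Generator) -> str:
    """Perceptual report of the latent state. Baseline accuracy applies
    under random motion; visible coherence pulls accuracy toward 1."""
    boost = min(1.0, abs(coherence) / 0.15)   # visible motion -> easy report
    p_correct = accuracy + (1.0 - accuracy) * boost
    if rng.random() < p_correct:
        return latent_state
    return "L" if latent_state == "R" else "R"


class Agent:
    """Base agent: discrimination + confidence generation, no learning."""

    def __init__(self, params: AgentParams):
        self.params = params
        self.last_action: str | None = None
        self.last_reward: int | None = None
        self._coherence = 0.0

    def start_session(self) -> None:
        self.last_action = None
        self.last_reward = None

    # -- per-trial interface -------------------------------------------
    def act(self, latent_state: str, likelihood: float, coherence: float,
            rng: np.random.Generator) -> tuple[str, int, str]:
        self._coherence = coherence
        discrimination = _discriminate(
            latent_state, coherence, self.params.discrim_accuracy, rng)
        confidence = make_confidence(
            abs(likelihood - 0.5), self.params.conf_gain,
            self.params.conf_noise, rng)
        action = self.choose_action(latent_state, rng)
        self.last_action = action
        return discrimination, confidence, action

    def learn(self, reward: int) -> None:
        self.last_reward = reward

    def choose_action(self, latent_state: str,
                      rng: np.random.Generator) -> str:
        raise NotImplementedError


class RandomAgent(Agent):
    def choose_action(self, latent_state, rng):
        return ACTIONS[int(rng.random() < 0.5)]


class WSLSAgent(Agent):
    """Repeat the same action if the previous trial was rewarded, switch
    otherwise; the first trial of a session is a uniform draw."""

    def choose_action(self, latent_state, rng):
        if self.last_action is None or self.last_reward is None:
            return ACTIONS[int(rng.random() < 0.5)]
        if self.last_reward == 1:
            return self.last_action
        return "B" if self.last_action == "A" else "A"


class QLearnerSF(Agent):
    """State-free Q-learner: one value per action. Values persist across
    sessions (learning carries over); they are fresh per agent."""

    def start_session(self) -> None:
        super().start_session()
        if not hasattr(self, "q"):
            self.q = {a: Q_INIT for a in ACTIONS}
        self.last_rpe: float | None = None

    def choose_action(self, latent_state, rng):
        p_a = choice_prob(self.q["A"], self.q["B"], self.params.beta)
        return "A" if rng.random() < p_a else "B"

    def learn(self, reward: int) -> None:
        super().learn(reward)
        a = self.last_action
        self.q[a], self.last_rpe = q_update(self.q[a], self.params.alpha,
                                            reward)


class QLearnerSD(Agent):
    """State-dependent Q-learner with noisy state access.

    The same per-trial percept (the decoded state, flipped w.p. eta)
    drives both the softmax choice and the subsequent value update: the
    agent acts on what it perceives.
    """

    def start_session(self) -> None:
        super().start_session()
        if not hasattr(self, "q"):
            self.q = {(s, a): Q_INIT for s in STATES for a in ACTIONS}
        self.last_percept: str | None = None
        self.last_rpe: float | None = None

    def choose_action(self, latent_state, rng):
        # visible coherent motion reveals the state: perception noise
        # shrinks as the stimulus becomes informative (control session)
        visibility = min(1.0, abs(self._coherence) / 0.1)
        eta = self.params.eta * (1.0 - visibility)
        s = perceive_state(latent_state, eta, rng)
        self.last_percept = s
        s_choice = s if self.params.noise_on_choice else latent_state
        p_a = choice_prob(self.q[(s_choice, "A")], self.q[(s_choice, "B")],
                          self.params.beta)
        return "A" if rng.random() < p_a else "B"

    def learn(self, reward: int) -> None:
        super().learn(reward)
        key = (self.last_percept, self.last_action)
        self.q[key], self.last_rpe = q_update(self.q[key], self.params.alpha,
                                              reward)


class OracleAgent(Agent):
    """Always selects the optimal action for the decoded state (upper
    reference policy; not fit to data)."""

    def __init__(self, params: AgentParams, optimal_map):
        super().__init__(params)
        self.optimal_map = dict(optimal_map)

    def choose_action(self, latent_state, rng):
        return self.optimal_map[latent_state]


class AntiOracleAgent(OracleAgent):
    """Always selects the non-optimal action (lower reference policy)."""

    def choose_action(self, latent_state, rng):
        a = self.optimal_map[latent_state]
        return "B" if a == "A" else "A"


def make_agent(params: AgentParams, optimal_map=None) -> Agent:
    """Factory for the four fit-able agent kinds."""
    cls = {"random": RandomAgent, "wsls": WSLSAgent,
           "rl_sf": QLearnerSF, "rl_sd": QLearnerSD}.get(params.kind)
    if cls is None:
        raise ValueError(f"unknown agent kind {params.kind!r}")
    agent = cls(params)
    agent.start_session()
    return agent
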