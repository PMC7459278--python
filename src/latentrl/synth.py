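"""Cohort-level synthetic data with known ground truth.

Generates what the downstream analyses assume of the real study: a
cohort of 18 subjects in two groups (decoder in visual cortex, VC, or
prefrontal cortex, PFC), each with three sessions of ~10-12 blocks of 12
trials of the hidden-state bandit, driven by a noisy state-dependent
Q-learner whose parameters are sampled per subject and recorded as
ground truth; an independent decoder-construction-stage discrimination
dataset per subject (for metacognitive ability); and multivoxel pattern
sets in which a sparse subset of voxels carries class signal:

* state-region patterns carry the generating pattern class over the
  first 3 TRs after stimulus onset;
* confidence-region patterns carry a graded confidence signal over
  TRs 7-16, with a session-dependent knob that mixes in an
  anti-|RPE| component (the confidence-|RPE| coupling);
* reward-region patterns carry graded |RPE| signal over the 2 outcome
  TRs.

Voxel noise is independent unit-variance Gaussian per voxel per TR;
informative voxels receive additive class-dependent means. No
haemodynamic response or shift is modelled: synthetic signal is injected
directly into the labelled epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agents import AgentParams, make_agent
from .decoding import train_slr
from .fitting import rpe_trace
from .task import TaskConfig, default_optimal_map, run_session


@dataclass
class VoxelPatternSpec:
    """Geometry and signal strength of one region's pattern set."""

    region: str
    n_voxels: int
    n_informative: int
    effect_size: float = 1.0      # class-mean separation, noise-SD units
    trs_per_trial: int = 22
    signal_trs: tuple = (1, 2, 3)  # 1-based TR indices carrying signal

    def __post_init__(self) -> None:
        if self.n_informative > self.n_voxels:
            raise ValueError("n_informative exceeds n_voxels")
        if any(not (1 <= tr <= self.trs_per_trial)
               for tr in self.signal_trs):
            raise ValueError("signal TRs outside the trial TR range")


def default_pattern_specs(scale: float = 1.0) -> dict[str, VoxelPatternSpec]:
    """Region specs mirroring the study's ROI sizes; ``scale`` shrinks
    voxel counts proportionally for cheaper simulation."""
    def n(x):
        return max(8, int(round(x * scale)))

    return {
        "state": VoxelPatternSpec("state", n(3000), n(70),
                                  signal_trs=(1, 2, 3)),
        "confidence": VoxelPatternSpec("confidence", n(6600), n(40),
                                       signal_trs=tuple(range(7, 17))),
        "rpe": VoxelPatternSpec("rpe", n(3600), n(69),
                                signal_trs=(21, 22)),
    }


@dataclass
class CohortSpec:
    """Study-design parameters of the synthetic cohort."""

    n_subjects: int = 18
    group_split: tuple = (9, 9)               # (VC, PFC)
    n_sessions: int = 3
    blocks_per_session: tuple = (10, 11, 11)
    # agent parameter distributions (truncated normal per subject)
    alpha_mean: float = 0.35
    alpha_sd: float = 0.10
    beta_mean: float = 2.0
    beta_sd: float = 1.0
    eta_mean: float = 0.30
    eta_sd: float = 0.08
    conf_gain_mean: float = 10.0
    conf_noise_mean: float = 0.6
    # decoder-channel fidelity targets per group
    decoder_accuracy: Mapping[str, float] = field(
        default_factory=lambda: {"VC": 0.70, "PFC": 0.655})
    decoder_accuracy_sd: float = 0.02
    # inherent latent-state bias of the decoding channel
    state_bias_mean: float = 0.5
    state_bias_sd: float = 0.08
    # metacognitive efficiency (1 = SDT-ideal confidence)
    metacog_eff_mean: float = 0.75
    metacog_eff_sd: float = 0.15
    # efficiency -> inverse-temperature coupling (beta units per unit
    # efficiency) producing the metacognition/performance association
    metacog_beta_coupling: float = 6.0
    # per-session confidence-|RPE| coupling knob in [0, 1]
    conf_rpe_coupling: tuple = (0.0, 0.3, 0.6)
    stage0_trials: int = 200
    stage0_dprime: float = 1.35   # ~75% correct at threshold coherence
    master_seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_split) != self.n_subjects:
            raise ValueError("group sizes must sum to n_subjects")
        for g, p in self.decoder_accuracy.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"decoder accuracy for {g} out of range")


@dataclass
class VoxelPatternSet:
    region: str
    data: np.ndarray          # (trials, TRs, voxels), float32
    labels: pd.DataFrame      # per-trial labels (session, classes)
    informative: np.ndarray   # indices of signal-carrying voxels
    spec: VoxelPatternSpec

    def epoch_average(self, trs: Sequence[int] | None = None) -> np.ndarray:
        """Trials x voxels matrix averaged over the (1-based) signal
        TRs, the input representation for decoder training."""
        trs = list(self.spec.signal_trs if trs is None else trs)
        idx = [t - 1 for t in trs]
        return self.data[:, idx, :].mean(axis=1)


@dataclass
class SubjectDataset:
    subject: str
    group: str
    params: AgentParams
    optimal_map: dict
    state_bias: float
    decoder_accuracy: float
    metacog_efficiency: float
    seed: int
    trials: pd.DataFrame
    stage0: pd.DataFrame
    patterns: dict = field(default_factory=dict)


def _trunc_normal(rng, mean, sd, lo, hi):
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(min(max(mean, lo + 1e-6), hi - 1e-6))


def simulate_discrimination(n_trials: int, d_prime: float,
                            efficiency: float, rng: np.random.Generator,
                            n_levels: int = 4) -> pd.DataFrame:
    """Equal-variance SDT discrimination data with graded confidence.

    The decision variable is x ~ N(+-d'/2, 1); the response is its sign.
    Confidence reads a second variable x + N(0, s) with
    s = sqrt(1/efficiency^2 - 1): efficiency 1 is the ideal observer
    (confidence from the same evidence sample as the choice), lower
    efficiency degrades the confidence-accuracy correspondence. Ratings
    are quartile bins of the absolute confidence variable.
    """
    if not (0 < efficiency <= 1):
        raise ValueError("efficiency must lie in (0, 1]")
    stim = rng.integers(0, 2, n_trials)            # 0 = L, 1 = R
    x = rng.normal((stim * 2 - 1) * d_prime / 2.0, 1.0)
    resp = (x > 0).astype(int)
    s_meta = np.sqrt(max(0.0, 1.0 / efficiency ** 2 - 1.0))
    x_conf = x + (rng.normal(0.0, s_meta, n_trials) if s_meta > 0 else 0.0)
    mag = np.abs(x_conf)
    edges = np.quantile(mag, np.linspace(0, 1, n_levels + 1)[1:-1])
    conf = np.searchsorted(edges, mag, side="right") + 1
    return pd.DataFrame({
        "stimulus": np.where(stim == 1, "R", "L"),
        "response": np.where(resp == 1, "R", "L"),
        "confidence": conf,
        "correct": (stim == resp).astype(int)})


def generate_subject(spec: CohortSpec, subject: str, group: str,
                     seed: int) -> SubjectDataset:
    """One synthetic subject: sampled ground-truth parameters, three
    simulated sessions, and a decoder-construction-stage discrimination
    dataset. Fully determined by the seed."""
    rng = np.random.default_rng(seed)
    eff = _trunc_normal(rng, spec.metacog_eff_mean, spec.metacog_eff_sd,
                        0.25, 1.0)
    beta = _trunc_normal(
        rng, spec.beta_mean
        + spec.metacog_beta_coupling * (eff - spec.metacog_eff_mean),
        spec.beta_sd, 0.5, 19.5)
    params = AgentParams(
        kind="rl_sd",
        alpha=_trunc_normal(rng, spec.alpha_mean, spec.alpha_sd, 0.05, 0.9),
        beta=beta,
        eta=_trunc_normal(rng, spec.eta_mean, spec.eta_sd, 0.0, 0.45),
        conf_gain=spec.conf_gain_mean,
        conf_noise=spec.conf_noise_mean,
        discrim_accuracy=0.5)
    state_bias = _trunc_normal(rng, spec.state_bias_mean, spec.state_bias_sd,
                               0.2, 0.8)
    dec_acc = _trunc_normal(rng, spec.decoder_accuracy[group],
                            spec.decoder_accuracy_sd, 0.5, 0.95)
    config = TaskConfig(blocks_per_session=spec.blocks_per_session,
                        state_bias=state_bias, decoder_accuracy=dec_acc,
                        rng_seed=seed)
    optimal_map = default_optimal_map(rng)
    agent = make_agent(params, optimal_map)
    records = []
    for session in range(1, spec.n_sessions + 1):
        for rec in run_session(agent, config, session, rng,
                               optimal_map=optimal_map, subject=subject,
                               group=group):
            records.append(rec)
    trials = pd.DataFrame([vars(r) for r in records])
    stage0 = simulate_discrimination(spec.stage0_trials, spec.stage0_dprime,
                                     eff, rng)
    return SubjectDataset(
        subject=subject, group=group, params=params,
        optimal_map=optimal_map, state_bias=state_bias,
        decoder_accuracy=dec_acc, metacog_efficiency=eff, seed=seed,
        trials=trials, stage0=stage0)


def _graded(values: np.ndarray) -> np.ndarray:
    """Center and scale a per-trial quantity to roughly [-1, 1]."""
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    spread = np.median(np.abs(v - med))
    if spread == 0:
        spread = np.std(v) or 1.0
    return np.clip((v - med) / (2 * spread), -1.0, 1.0)


def generate_patterns(dataset: SubjectDataset,
                      pattern_specs: Mapping[str, VoxelPatternSpec],
                      rng: np.random.Generator,
                      conf_rpe_coupling: Sequence[float] = (0.0, 0.3, 0.6),
                      ) -> dict[str, VoxelPatternSet]:
    """Synthesize per-trial multivoxel time courses for one subject.

    Informative voxels receive ``effect_size * level / 2`` at the
    region's signal TRs, where the level is +-1-scaled class or graded
    signal: the pattern class for the state region; graded |RPE| (from
    the generating agent) for the reward region; and for the confidence
    region a mixture ``(1 - kappa) * conf - kappa * rpe`` whose
    session-dependent weight ``kappa`` is the confidence-|RPE| coupling
    knob (0: confidence patterns are independent of |RPE|).
    """
    trials = dataset.trials
    # generating-model |RPE|: replay with the true parameters reproduces
    # the simulator's internal trace
    if "gen_rpe" in trials.columns and trials["gen_rpe"].notna().all():
        rpe = np.abs(trials["gen_rpe"].to_numpy(dtype=float))
    else:
        rpe = rpe_trace(trials, dataset.params.alpha,
                        dataset.params.beta)["abs_rpe"].to_numpy()
    g_conf = _graded(trials["confidence"].to_numpy())
    g_rpe = _graded(rpe)
    state_level = np.where(trials["pattern_class"].to_numpy() == "R",
                           1.0, -1.0)
    session = trials["session"].to_numpy()
    kappa = np.array([conf_rpe_coupling[s - 1] for s in session])
    conf_level = (1.0 - kappa) * g_conf - kappa * g_rpe

    levels = {"state": state_level, "confidence": conf_level, "rpe": g_rpe}
    out: dict[str, VoxelPatternSet] = {}
    n_trials = len(trials)
    for region, pspec in pattern_specs.items():
        data = rng.standard_normal(
            (n_trials, pspec.trs_per_trial, pspec.n_voxels)
        ).astype(np.float32)
        informative = rng.choice(pspec.n_voxels, pspec.n_informative,
                                 replace=False)
        level = levels[region]
        tr_idx = [t - 1 for t in pspec.signal_trs]
        bump = (pspec.effect_size / 2.0) * level
        data[np.ix_(range(n_trials), tr_idx, informative)] += (
            bump[:, None, None].astype(np.float32))
        labels = pd.DataFrame({
            "session": session,
            "pattern_class": trials["pattern_class"].to_numpy(),
            "confidence": trials["confidence"].to_numpy(),
            "conf_high": g_conf >= 0,
            "abs_rpe": rpe,
            "rpe_high": g_rpe >= 0,
            "signal_level": level})
        out[region] = VoxelPatternSet(region=region, data=data,
                                      labels=labels,
                                      informative=np.sort(informative),
                                      spec=pspec)
    return out


def generate_cohort(spec: CohortSpec,
                    pattern_specs: Mapping[str, VoxelPatternSpec]
                    | None = None) -> list[SubjectDataset]:
    """Generate the full cohort; every subject is bit-reproducible from
    the master seed."""
    ss = np.random.SeedSequence(spec.master_seed)
    groups = ["VC"] * spec.group_split[0] + ["PFC"] * spec.group_split[1]
    subjects = []
    for i, group in enumerate(groups):
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(i,))
        seed = int(child.generate_state(1)[0])
        ds = generate_subject(spec, f"S{i + 1:02d}", group, seed)
        if pattern_specs:
            prng = np.random.default_rng(
                np.random.SeedSequence(entropy=ss.entropy,
                                       spawn_key=(i, 1)))
            ds.patterns = generate_patterns(ds, pattern_specs, prng,
                                            spec.conf_rpe_coupling)
        subjects.append(ds)
    return subjects


def cohort_frame(subjects: list[SubjectDataset]) -> pd.DataFrame:
    """Concatenate all subjects' trial tables."""
    return pd.concat([s.trials for s in subjects], ignore_index=True)


def build_association_inputs(subjects: list[SubjectDataset],
                             train_session: int = 1,
                             test_session: int = 3,
                             n_iterations: int = 3,
                             seed: int = 0):
    """Train per-subject confidence and |RPE| decoders on the synthetic
    patterns and package the held-out session for the association
    pipeline.

    The confidence decoder is trained on an independent session's
    confidence-region patterns (mirroring the study's use of the
    decoder-construction stage, where confidence signal is uncontaminated
    by task variables); the |RPE| decoder is trained on the test
    session's outcome-epoch patterns, as in the study.
    """
    from .decoding import SubjectAssociationData

    inputs = []
    for ds in subjects:
        if not ds.patterns:
            raise ValueError(f"subject {ds.subject} has no voxel patterns")
        conf_ps = ds.patterns["confidence"]
        rpe_ps = ds.patterns["rpe"]
        tr_mask = (conf_ps.labels["session"] == train_session).to_numpy()
        te_mask = (conf_ps.labels["session"] == test_session).to_numpy()
        conf_model = train_slr(conf_ps.epoch_average()[tr_mask],
                               conf_ps.labels.loc[tr_mask, "conf_high"],
                               n_iterations=n_iterations, seed=seed)
        rpe_model = train_slr(rpe_ps.epoch_average()[te_mask],
                              rpe_ps.labels.loc[te_mask, "rpe_high"],
                              n_iterations=n_iterations, seed=seed)
        outcome_trs = [t - 1 for t in rpe_ps.spec.signal_trs]
        inputs.append(SubjectAssociationData(
            conf_model=conf_model, rpe_model=rpe_model,
            conf_trs=conf_ps.data[te_mask],
            rpe_patterns=rpe_ps.data[te_mask][:, outcome_trs, :]))
    return inputs


class CalibrationError(RuntimeError):
    pass


def measure_decoding_accuracy(effect_size: float, n_trials: int,
                              n_voxels: int, n_informative: int,
                              seed: int, n_iterations: int = 3) -> float:
    """Cross-validated decoding accuracy on planted-signal patterns at a
    given effect size (single epoch-averaged pattern per trial)."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n_trials) % 2
    X = rng.standard_normal((n_trials, n_voxels))
    informative = rng.choice(n_voxels, n_informative, replace=False)
    X[:, informative] += (effect_size / 2.0) * (labels * 2 - 1)[:, None]
    model = train_slr(X, labels, n_iterations=n_iterations, seed=seed)
    return float(model.cv_accuracy[model.chosen_iteration - 1])


def calibrate_effect_size(target_accuracy: float,
                          n_trials: int = 200, n_voxels: int = 200,
                          n_informative: int = 40, seed: int = 0,
                          tol: float = 0.02, max_iter: int = 16,
                          n_iterations: int = 3, n_reps: int = 3) -> float:
    """Bisection on the planted effect size until the simulated CV
    decoding accuracy is within ``tol`` of the target.

    Each evaluation averages the accuracy over ``n_reps`` noise
    realizations, and the same realizations are reused across effect
    sizes (common random numbers), so the objective is a deterministic,
    near-monotone function of the effect size, bisection is well posed,
    and the result transfers to fresh pattern draws rather than fitting
    one noise realization.
    """
    if not (0.5 < target_accuracy < 1.0):
        raise ValueError("target accuracy must lie in (0.5, 1)")

    def acc(e):
        return float(np.mean([measure_decoding_accuracy(
            e, n_trials, n_voxels, n_informative, seed + 17 * r,
            n_iterations) for r in range(n_reps)]))

    lo, hi = 0.0, 1.0
    a_hi = acc(hi)
    grow = 0
    while a_hi < target_accuracy and grow < 5:
        lo, hi = hi, hi * 2
        a_hi = acc(hi)
        grow += 1
    if a_hi < target_accuracy:
        raise CalibrationError(
            f"accuracy {a_hi:.3f} at effect size {hi} still below target "
            f"{target_accuracy}")
    mid, a_mid = hi, a_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a_mid = acc(mid)
        if abs(a_mid - target_accuracy) <= tol:
            return float(mid)
        if a_mid < target_accuracy:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"no convergence after {max_iter} bisection steps: last effect "
        f"size {mid:.4f} gave accuracy {a_mid:.3f} vs target "
        f"{target_accuracy} (tol {tol})")
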