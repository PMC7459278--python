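# Methods

This note documents the generative model, the fitting and decoding
procedures, the numerical choices, and what the synthetic cohorts do
and do not emulate.

## Task generative model

A trial draws a hidden `pattern_class` (R with probability
`state_bias`) and passes it through a binary channel of fidelity
`decoder_accuracy` to produce the `latent_state` — the decoder output
that defines the reinforcement-learning state. Modelling the channel
directly (rather than simulating decoding of brain activity) reproduces
the two properties the downstream analyses rely on: imperfect
classification (~70%) and an inherent, stable state bias. The decoder
likelihood L is drawn consistently with the decoded class: a
half-normal evidence margin (scale 0.15) signed toward the state,
clipped to [0,1]. Rewards are independent Bernoulli draws, 0.8 for the
state's optimal action and 0.2 otherwise, under a per-subject
state→action bijection randomized once.

Timing: trial events are ITI 6 s, random-dot stimulus 8 s, blank 1 s,
discrimination 1.5 s, confidence 1.5 s — the remaining 4 s of the 22-s
trial is split 2 s action selection / 2 s outcome, the outcome epoch
matching the 2-s window used for |RPE| decoding. A block is 30 s
lead-in + 12 × 22 s + 6 s tail = 300 s. The decoder-construction stage
uses 20-trial blocks of 9-s events with ITIs drawn from {3,...,6} s
balanced to 100 s per block (292 s per run).

In sessions 1–2 the coherence gain is 0 (fully random motion). In
session 3 it follows a logistic ramp with midpoint at 25% of the
session's trials and slope 12/n, which puts the gain above 0.95 by the
50% mark and at plateau thereafter; dot contrast ramps identically from
20% to 100%. These ramp parameters are a design choice (only the
sigmoid shape, the (0,1) interval and the first-half ramp are
prescribed by the paradigm).

## Agents

Four policies generate behaviour: uniform random;
win-stay–lose-switch (repeat after reward, switch otherwise, first
trial uniform, restarting each session); a state-free Q-learner; and a
noisy state-dependent Q-learner. Q-values initialize at 0.5 — the
expected value of an uninformed arm under the symmetric 0.8/0.2 rule —
and persist across sessions in the generating agent (learning carries
over), although fitting resets them per session to match the
per-session fitting convention.

The state-dependent agent perceives the decoded state flipped with
probability η; by default the same per-trial percept drives both the
softmax choice and the value update (the agent acts on what it
perceives). The alternative — noise on the update only — is available
through `AgentParams.noise_on_choice=False` and the matching flag in
the likelihood, since the choice-side behaviour of the noise is
genuinely underdetermined.

In session 3 the agent's effective η shrinks proportionally to stimulus
visibility (|coh|/0.1, capped at 1): once coherent motion reveals the
state, perception noise vanishes. This emulates conscious discovery of
the rule and produces the characteristic session-3 jump in
optimal-action rate without any change to the learning rule.

Confidence is generated as
`clip(round(2.5 + conf_gain·(|L−0.5|−0.10) + N(0, conf_noise)), 1, 4)`;
with zero noise it is nondecreasing in evidence magnitude. The
discrimination report is correct with probability
`acc + (1−acc)·min(1, |coh|/0.15)` — chance-level under random motion
(acc = 0.5), approaching ceiling under visible coherence.

## Synthetic cohort

Defaults emulate the study design: 18 subjects (9 VC / 9 PFC), three
sessions of (10, 11, 11) blocks × 12 trials. Channel fidelity targets
are 0.70 (VC) and 0.655 (PFC) with 0.02 SD; state bias is drawn
N(0.5, 0.08) truncated to [0.2, 0.8]. Agent parameters are truncated
normals per subject: α ~ N(0.35, 0.10), β ~ N(2.0, 1.0),
η ~ N(0.30, 0.08). These spreads were chosen once so the cohort shows
the qualitative behavioural profile of the study population — weak
above-chance learning in the two unconscious sessions (p(opt) ≈
0.55–0.57), chance discrimination there, and a strong session-3 rise —
rather than the much faster learning an unconstrained Q-learner
exhibits.

Each subject also carries a metacognitive-efficiency parameter
m ~ N(0.75, 0.15) on (0.25, 1]: stage-0 discrimination data are
simulated from an equal-variance SDT observer (d′ = 1.35, ≈75%
correct) whose confidence reads the decision variable corrupted by
noise of SD sqrt(1/m²−1), so m = 1 is the ideal observer
(meta-d′ ≈ d′). Efficiency couples to the agent's β (6 β-units per
efficiency unit), which induces the across-subject association between
metacognitive ability and baseline gambling performance.

Voxel patterns are independent unit-variance Gaussian per voxel per TR;
informative voxels receive additive means of ±effect/2 scaled by the
per-trial signal level: the pattern class (state region, TRs 1–3),
graded confidence (confidence region, TRs 7–16), and graded |RPE| from
the generating agent (reward region, the 2 outcome TRs). Graded levels
are median/MAD-standardized and clipped to [−1, 1]. A per-session
coupling knob κ mixes the confidence-region level as
`(1−κ)·conf − κ·|RPE|`; κ = 0 makes the two pattern families
independent and larger κ strengthens the target
(high-confidence–low-|RPE|) association, emulating the
session-1→3 shift. No haemodynamic response, shift, spatial
correlation or scanner noise spectrum is modelled; decoder voxel counts
are scaled down from the ROI sizes for desk-scale runs (the scale
factor is a parameter).

Every subject regenerates bit-for-bit from the cohort master seed; all
per-subject ground truth (parameters, bias, channel fidelity,
efficiency, the state→action map, the seed) is recorded in the dataset
and the cohort manifest.

## Model fitting

Grid points are midpoints of equal subintervals — 50 α-steps on (0,1)
and 50 β-steps on (0,20) by default — so the open-interval endpoints
are never evaluated; noise levels are 100 evenly spaced values on
[0, 0.5] including 0. For the noisy state-dependent model each level is
evaluated over 100 resampling runs (each run redraws the flip sequence
from a per-level RNG substream derived from the fit seed, so results
are bit-reproducible); the reported likelihood at a level is the mean
over runs of the grid-minimized NLL, the selected level minimizes that
mean, and (α̂, β̂) are the argmin of the run-averaged NLL surface at the
selected level. Ties break toward smaller η, then α, then β. The
α-dimension is vectorized through the sequential Q-recursion and the
β-dimension through the softmax loss, so a reduced fit
(25×25 grid, 20 runs × 26 levels, 264 trials) takes ~2 s.

Likelihood evaluation demands chronologically sorted trials and refuses
shuffled input, since the Q-recursion is order-dependent. Degenerate
data (a single action throughout) fit at a likelihood boundary and are
flagged. AIC uses k = 3 (noisy state-dependent) vs k = 2 (state-free);
a per-trial normalized variant 2k + 2·NLL/n is also reported, isolated
in one place, since its exact normalization is a documented assumption.

A property of the resampling estimator worth knowing: random resampled
flip sequences cannot align with the flips a noisy agent actually
experienced, so on data truly generated with percept noise the η = 0
level tends to win and β̂ shrinks (the flipped-state choices look like
decision noise). The estimator separates the two model families
reliably (ΔAIC model selection is clean in both directions) and does
not over-estimate η on noise-free data, but point recovery of (α, β)
under strong generative percept noise is biased — an inherent
limitation of averaging the log-likelihood over random flip sequences
rather than marginalizing the latent flips.

|RPE| traces for the offline analyses replay the noiseless
state-dependent recursion with the fitted (or generating) parameters;
the replayed RPEs equal the simulator's internal values exactly when
the generating parameters are used.

## Behavioural statistics

The WSLS baseline is replayed from each subject's data, starting from
the subject's first action of each session. Because rewards are
action-dependent, the observed reward is only defined on the subject's
own path; the default convention uses the observed reward when the
replayed action matches the subject's and otherwise draws the
counterfactual reward from the 0.8/0.2 rule, averaging p(opt) over 100
seeded replays. The pure observed-reward convention (deterministic,
hand-traceable) is kept as an option. On data produced by an actual
WSLS agent the replay never leaves the subject's path and reproduces
the agent's sequence exactly under either convention.

Latent-state bias is |n_R − n_L|/n over a centred 30-trial window
(truncated at the edges) smoothed by a centred 5-trial moving average
(shrinking at the edges); it is bounded in [0,1] and invariant to
global relabeling. Confidence medians split ties upward ("equal or
above the median is high") everywhere a median split occurs. The
bootstrap contrast resamples each split group at its own size
(500 runs) and reads significance from the 95% percentile interval.
Exact tests: sign test (ties dropped, one-sided = lower tail of the
negative-difference count; two-sided = doubled smaller tail, capped)
and the two-sided exact binomial against 0.5 with the same doubling
convention. Tests against chance use subject-level rates in a
one-sample t-test — the subject-level summary form of an
intercept-only random-effects model; trial-level linear mixed models
are deliberately out of scope. Within a reported family, p-values are
Benjamini–Hochberg corrected.

## Metacognition

meta-d′ is fitted by maximum likelihood under equal-variance SDT: the
type-1 criterion enters the meta-model at a fixed relative position
(c′ = c·meta-d′/d′), a single meta-d′ is fitted jointly with
response-specific type-2 criteria (parameterized as log-increments so
their order is maintained), and the multinomial likelihood of the
response-conditional confidence counts is maximized by Nelder–Mead
with one restart. Every type-2 cell is padded by 1/(2·n_levels) before
fitting (configurable off) so the fit is finite whenever at least two
confidence levels are occupied. Overall (not response-specific) meta-d′
is reported; the response-specific variant would be the natural
extension. Baseline gambling performance for the
metacognition–performance association is the minimum of the session-1
and session-2 optimal-action rates; the association is summarized by
Pearson r and a Huber robust regression slope.

## Decoding and association

Sparse logistic regression is realized as L1-penalized logistic
regression (liblinear), which shares the selection behaviour of the
Bayesian sparse formulation while being simple to verify; the penalty
strength defaults to a single fixed value (C = 1), with an optional
grid chosen by inner 3-fold CV. Iterative selection removes each
round's nonzero-weight voxels and refits on the cumulative support; the
per-iteration held-out accuracies are averaged over stratified k folds
(k ∈ {9,10,11} minimizing n mod k, ties to larger k) and the final
decoder is trained on all data at the accuracy-maximizing iteration
count. Prediction thresholds the logistic output at 0.5, with exactly
0.5 going to class 1. The online state likelihood is the mean of the
three per-TR logistic outputs.

The nine confidence windows are centres 8..16 with the 3-TR window
{t−1, t, t+1} clipped to TRs 7–16 — the only layout giving exactly nine
windows in that range. Window choice maximizes the per-subject χ² and
is re-chosen inside every bootstrap run, so its selection optimism is
reflected in the bootstrap distribution; a fixed-window variant
(`select_window=False`) provides the optimism-free null reading, under
which the per-subject χ² is a 1-df draw at zero coupling. The 2×2 χ²
uses no continuity correction; a table with an empty margin scores 0
and is counted. The confidence decoder for the association is trained
on an independent session's patterns (session 1 by default, standing in
for the decoder-construction stage) because a decoder trained on the
coupled session itself is sign-ambiguous at realistic trial counts.

Effect-size calibration bisects the planted per-voxel effect against
the cross-validated accuracy, holding the noise realizations fixed
across effect sizes (common random numbers) and averaging over several
realizations so the result transfers to fresh draws; non-convergence
raises a diagnostic error. The analysis driver calibrates each region
on actual generated pattern sets, which accounts for epoch averaging
(averaging k TRs shrinks noise by √k) and for the graded signals'
smaller effective amplitude.

## Problem sizes

The tests and drivers run desk-scale versions of every analysis: the
reduced fitting grid (25×25, 20 runs × 26 levels) for cohort fits,
264-trial subjects for recovery and model-selection studies, 2000-trial
observers for meta-d′ properties, 150–300-trial pattern sets with
100–330 voxels for decoding, and 100–300 bootstrap runs for the
association. The full-scale procedure (50×50 grid, 100×100 resampling,
1000 bootstrap runs, unscaled voxel counts) is available through the
same interfaces.

## Known limitations

- In-task confidence tracks stimulus evidence only; trial-level
  coupling between behavioural confidence and |RPE| is not emulated
  (the confidence-binned |RPE| analyses on default cohorts are null by
  construction). The confidence–|RPE| association lives at the pattern
  level, via the coupling knob.
- Point recovery of (α, β) by the resampling grid fit is biased under
  strong generative percept noise (see Model fitting); model *selection*
  is unaffected in the regimes tested.
- Group differences (VC vs PFC) are emulated only through channel
  fidelity and the coupling knob; no anatomy, haemodynamics, or scanner
  noise is modelled, so passing tests speak to the analysis chain, not
  to fMRI preprocessing.
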