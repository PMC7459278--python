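# latentrl

Simulation and analysis of **closed-loop hidden-brain-state
reinforcement learning** — the paradigm in which a real-time multivoxel
decoder classifies a subject's spontaneous brain activity (leftward vs.
rightward motion representations in visual or prefrontal cortex) and
the decoded class silently defines the *state* of a two-armed bandit:
in each state one action pays reward with probability 0.8, the other
with 0.2, and subjects are told nothing about states, decoding, or the
rule. The scientific questions are whether people can learn to exploit
such latent, high-dimensional, unconscious task states, and whether
metacognition (confidence in one's perceptual decisions) supports that
learning.

This package provides everything needed to exercise the full analysis
chain on synthetic cohorts with known ground truth: a generative model
of the task, the behavioural agents, the computational model fits and
their comparison, the behavioural/metacognitive statistics, and the
multivoxel decoding and association analyses. It is an analysis
project: the library lives in `src/latentrl/`, and numbered drivers in
`analysis/` run the study-shaped analyses and write their tables under
`results/`.

## The models at the core

**Q-learning.** Two variants are simulated and fitted. The
state-dependent learner updates the value of the chosen action in the
current latent state s,

    Q(s,a) ← Q(s,a) + α · (r − Q(s,a)),

while the state-free learner tracks action values only,
`Q(a) ← Q(a) + α · (r − Q(a))`. The quantity `r − Q` is the reward
prediction error (RPE); its magnitude |RPE| indexes learning
uncertainty. Choices follow a softmax rule with inverse temperature β,

    P(A) = 1 / (1 + exp(−β · (Q(s,A) − Q(s,B)))).

The *noisy* state-dependent variant assumes partial, stochastic access
to the state: with probability η the perceived state is the alternative
of the decoded one. Because the flip sequence is latent, the model is
evaluated over resampling runs at each of a grid of noise levels (0 to
50%); the level with the best run-averaged likelihood is selected.
Fitting is grid search over α ∈ (0,1) and β ∈ (0,20) minimizing the
negative log-likelihood of choices; models are compared by
AIC = 2k + 2·NLL with k = 3 for the noisy state-dependent model and
k = 2 for the state-free model (ΔAIC = AIC_sd − AIC_sf < 0 favours the
state-dependent account).

**Stimulus coupling.** In the final (control) session the random-dot
coherence is driven by the decoder likelihood L through
`coh = c · arctan(L − 0.5)`, with the gain c ramping logistically over
the first half of the session — the state becomes visible.

**Metacognition.** Discrimination confidence (1–4) enters three ways:
type-2 signal detection (meta-d′, the type-1 sensitivity an SDT-ideal
observer would need to produce the observed confidence–accuracy
correspondence), confidence-binned behavioural rates, and bootstrap
median-split contrasts of |RPE|.

**Decoding.** Binary decoders are sparse (L1-penalized) logistic
regressions with iterative feature selection (selected voxels are
removed and the fit repeated, up to 10 rounds) under adaptive k-fold
cross-validation (k ∈ {9,10,11} chosen to best divide the sample). The
confidence–|RPE| association applies a subject's confidence decoder to
nine 3-TR windows in TRs 7–16, the |RPE| decoder to the outcome epoch,
picks the window with the strongest χ² association per subject,
concatenates predictions across subjects, and bootstraps the pooled
2×2 χ² over resampled trial subsets (1000 runs), tallying *target*
(high-confidence–low-|RPE| and low-confidence–high-|RPE|) versus
*opposite* pairings.

## Worked example

```python
from latentrl.synth import CohortSpec, generate_cohort, cohort_frame
from latentrl.behavior import session_summary, chance_test
from latentrl.fitting import GridSpec, fit_grid, compare_models

cohort = generate_cohort(CohortSpec(n_subjects=6, group_split=(3, 3),
                                    master_seed=11))
summary = session_summary(cohort_frame(cohort))
for sess, g in summary.groupby("session"):
    diff, t, p = chance_test(g["p_opt_action"], 0.5)
    print(f"session {sess}: p(opt action) = "
          f"{g['p_opt_action'].mean():.3f} (chance 0.5, t = {t:.2f}, "
          f"p = {p:.3f})")

grid = GridSpec(n_alpha=25, n_beta=25, n_eta=26, n_runs=20)
s2 = cohort[0].trials.query("session == 2")
fit_sd = fit_grid(s2, "rl_sd_noisy", grid, seed=1)
fit_sf = fit_grid(s2, "rl_sf", grid)
print("delta AIC =", round(compare_models(fit_sd, fit_sf).delta_aic, 1))
```

prints

```
session 1: p(opt action) = 0.564 (chance 0.5, t = 1.64, p = 0.163)
session 2: p(opt action) = 0.629 (chance 0.5, t = 4.52, p = 0.006)
session 3: p(opt action) = 0.687 (chance 0.5, t = 5.25, p = 0.003)
delta AIC = -10.0
```

— the cohort learns weakly above chance in the two "unconscious"
sessions and strongly once the stimulus reveals the state, and for this
subject-session the noisy state-dependent model is favoured (ΔAIC < 0)
over the state-free account.

## Analysis drivers

Each script is a thin narrative driver over the library; all write
under `results/` and accept `--seed`/`--out`.

| script | what it does |
| --- | --- |
| `analysis/01_simulate_cohort.py` | simulate the 18-subject cohort, write behaviour tables and the session summary |
| `analysis/02_fit_learning_models.py` | fit both Q-learning models per subject/session, tabulate ΔAIC |
| `analysis/03_behavioral_statistics.py` | chance tests (FDR-corrected), WSLS replay sign tests, latent-state bias |
| `analysis/04_metacognition.py` | meta-d′ per subject, correlation with baseline performance, |RPE|-by-confidence bootstrap |
| `analysis/05_decoding_calibration.py` | calibrate planted effect sizes to the decoding-accuracy targets, train state/confidence/|RPE| decoders |
| `analysis/06_association.py` | bootstrap χ² association across coupling-knob levels |

The same functionality is exposed as a CLI
(`latentrl simulate | simulate-cohort | fit-rl | behavior-stats |
metacog | decode | associate | run-all`).

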