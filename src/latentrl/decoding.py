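"""Sparse logistic decoding of multivoxel patterns and the
confidence-|RPE| association pipeline.

Binary decoders (state: left vs. right; confidence: high vs. low; |RPE|:
high vs. low) are sparse logistic regressions trained with an iterative
feature-selection scheme: within each cross-validation fold the
L1-penalized fit is repeated up to 10 times, each time removing the
voxels already assigned weights, and the per-iteration held-out
accuracies are averaged over folds; the iteration count with the highest
accuracy is used to train the final decoder on the full dataset. The
number of CV folds adapts between 9 and 11 to best divide the sample.

The association pipeline applies a subject's confidence decoder to nine
3-TR-averaged windows inside TRs 7-16 and the |RPE| decoder to the
outcome epoch, picks the window with the strongest chi-square
association per subject, concatenates predictions across subjects, and
bootstraps the resulting 2x2 chi-square over resampled trial subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score


def choose_k_folds(n_samples: int) -> int:
    """Number of CV folds, adjusted in {9, 10, 11} to be a (close)
    divisor of the sample count; ties go to the larger k."""
    if n_samples < 11:
        raise ValueError("need at least 11 samples for 9-11-fold CV")
    best = None
    for k in (9, 10, 11):
        r = n_samples % k
        if best is None or r <= best[0]:
            best = (r, k)
    return best[1]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class DecoderModel:
    """Sparse linear decoder: nonzero weights on the selected voxels."""

    weights: np.ndarray               # full-length, zeros off-support
    bias: float
    selected_voxels: list             # voxel indices added per iteration
    cv_accuracy: np.ndarray           # mean held-out accuracy per iteration
    chosen_iteration: int             # 1-based argmax of cv_accuracy
    label_map: tuple                  # (class0, class1)

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.weights)

    def to_dict(self) -> dict:
        """JSON-serializable form: voxel indices, weights, bias, CV
        curve."""
        sup = self.support
        return {"n_voxels": int(len(self.weights)),
                "voxels": sup.tolist(),
                "weights": self.weights[sup].tolist(),
                "bias": self.bias,
                "selected_voxels": [list(map(int, it))
                                    for it in self.selected_voxels],
                "cv_accuracy": np.asarray(self.cv_accuracy).tolist(),
                "chosen_iteration": self.chosen_iteration,
                "label_map": [str(c) for c in self.label_map]}

    @classmethod
    def from_dict(cls, d: dict) -> "DecoderModel":
        weights = np.zeros(d["n_voxels"])
        weights[np.asarray(d["voxels"], dtype=int)] = d["weights"]
        return cls(weights=weights, bias=float(d["bias"]),
                   selected_voxels=d["selected_voxels"],
                   cv_accuracy=np.asarray(d["cv_accuracy"]),
                   chosen_iteration=int(d["chosen_iteration"]),
                   label_map=tuple(d["label_map"]))

    def decision(self, patterns: np.ndarray) -> np.ndarray:
        patterns = np.atleast_2d(patterns)
        if patterns.shape[1] != len(self.weights):
            raise ValueError(
                f"pattern has {patterns.shape[1]} voxels, decoder expects "
                f"{len(self.weights)}")
        return patterns @ self.weights + self.bias

    def predict_proba(self, patterns: np.ndarray) -> np.ndarray:
        """P(class1) from the logistic output."""
        return _sigmoid(self.decision(patterns))

    def predict(self, patterns: np.ndarray) -> np.ndarray:
        """Class labels; a likelihood of exactly 0.5 goes to class1."""
        return np.where(self.predict_proba(patterns) >= 0.5,
                        self.label_map[1], self.label_map[0])


def _fit_l1(X: np.ndarray, y01: np.ndarray, C: float) -> LogisticRegression:
    return LogisticRegression(l1_ratio=1, solver="liblinear", C=C,
                              max_iter=2000).fit(X, y01)


def _iterative_selection(X: np.ndarray, y01: np.ndarray, n_iterations: int,
                         C: float):
    """Repeated sparse fits with removal of already-selected voxels.

    Yields, per iteration, the cumulative support and the model refit on
    that support.
    """
    n_vox = X.shape[1]
    remaining = np.arange(n_vox)
    support: list[int] = []
    for _ in range(n_iterations):
        if len(remaining) == 0:
            break
        clf = _fit_l1(X[:, remaining], y01, C)
        picked = remaining[np.flatnonzero(clf.coef_[0])]
        if len(picked) == 0:
            break
        support.extend(picked.tolist())
        remaining = np.setdiff1d(remaining, picked)
        refit = _fit_l1(X[:, support], y01, C)
        yield list(picked), np.array(support), refit


def train_slr(patterns: np.ndarray, labels, n_iterations: int = 10,
              penalty_grid=(1.0,), seed: int = 0) -> DecoderModel:
    """Train a sparse logistic decoder with iterative voxel selection.

    Cross-validation (stratified, k chosen by `choose_k_folds`) scores
    each cumulative iteration on held-out folds; the final decoder is
    trained on all data with the accuracy-maximizing iteration count.
    When several penalty strengths are offered, the strength is chosen
    once by an inner 3-fold CV before the iterative procedure.
    """
    X = np.asarray(patterns, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    y01 = (labels == classes[1]).astype(int)
    n = len(y01)

    if len(penalty_grid) > 1:
        scores = [np.mean(cross_val_score(
            LogisticRegression(l1_ratio=1, solver="liblinear", C=C,
                               max_iter=2000), X, y01, cv=3))
            for C in penalty_grid]
        C = float(penalty_grid[int(np.argmax(scores))])
    else:
        C = float(penalty_grid[0])

    k = choose_k_folds(n)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    acc = np.zeros(n_iterations)
    fold_counts = np.zeros(n_iterations)
    for train_idx, test_idx in cv.split(X, y01):
        for it, (_, support, refit) in enumerate(_iterative_selection(
                X[train_idx], y01[train_idx], n_iterations, C)):
            pred = refit.predict(X[np.ix_(test_idx, support)])
            acc[it] += float((pred == y01[test_idx]).mean())
            fold_counts[it] += 1
    if not fold_counts.any():
        raise RuntimeError("no voxels were ever selected")
    valid = fold_counts > 0
    acc[valid] /= fold_counts[valid]
    chosen = int(np.argmax(np.where(valid, acc, -np.inf))) + 1

    # final model on the entire dataset at the chosen iteration count
    per_iter_picks: list[list[int]] = []
    final_support, final_fit = None, None
    for _, support, refit in _iterative_selection(X, y01, chosen, C):
        per_iter_picks.append(support.tolist())
        final_support, final_fit = support, refit
    if final_fit is None:
        raise RuntimeError("final fit selected no voxels")
    weights = np.zeros(X.shape[1])
    weights[final_support] = final_fit.coef_[0]
    picks = [per_iter_picks[0]] + [
        sorted(set(b) - set(a))
        for a, b in zip(per_iter_picks, per_iter_picks[1:])]
    return DecoderModel(weights=weights, bias=float(final_fit.intercept_[0]),
                        selected_voxels=picks,
                        cv_accuracy=acc[:max(1, int(valid.sum()))],
                        chosen_iteration=chosen,
                        label_map=(classes[0], classes[1]))


def boundary_distance(model: DecoderModel, pattern: np.ndarray) -> float:
    """Signed distance from the classification boundary, ``w . x + b``:
    the sign gives the predicted class, the magnitude the evidence."""
    return float(model.decision(np.atleast_2d(pattern))[0])


def state_likelihood(model: DecoderModel, trial_trs: np.ndarray) -> float:
    """Online state likelihood: the average of the three logistic outputs
    computed from the three TRs after stimulus onset."""
    trial_trs = np.asarray(trial_trs, dtype=float)
    if trial_trs.shape[0] != 3:
        raise ValueError(f"expected 3 TR patterns, got {trial_trs.shape[0]}")
    return float(model.predict_proba(trial_trs).mean())


def chi2_2x2(high_a, high_b) -> float:
    """Pearson chi-square (1 df, no continuity correction) of two binary
    label vectors; a table with an empty margin yields 0."""
    a = np.asarray(high_a, dtype=bool)
    b = np.asarray(high_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("label vectors must have the same length")
    n = len(a)
    table = np.array([[np.sum(~a & ~b), np.sum(~a & b)],
                      [np.sum(a & ~b), np.sum(a & b)]], dtype=float)
    row, col = table.sum(axis=1), table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return 0.0
    expected = np.outer(row, col) / n
    return float(((table - expected) ** 2 / expected).sum())


#: 3-TR confidence windows inside TRs 7-16 (1-based): centers 8..16 with
#: the window {t-1, t, t+1} clipped to the range -- the only layout
#: giving exactly nine windows.
CONF_WINDOWS: tuple[tuple[int, ...], ...] = tuple(
    tuple(tr for tr in (t - 1, t, t + 1) if 7 <= tr <= 16)
    for t in range(8, 17))


@dataclass
class SubjectAssociationData:
    """Per-subject inputs to the association pipeline."""

    conf_model: DecoderModel
    rpe_model: DecoderModel
    conf_trs: np.ndarray      # (trials, n_TRs >= 16, conf voxels), TR 1-based
    rpe_patterns: np.ndarray  # (trials, 2, rpe voxels) outcome epoch


@dataclass
class AssociationResult:
    chi2_distribution: np.ndarray   # one chi-square per bootstrap run
    target_counts: np.ndarray       # highC-low|RPE| + lowC-high|RPE| per run
    opposite_counts: np.ndarray
    chosen_windows: list            # full-data chosen window center per subj
    chi2_observed: float
    n_degenerate: int               # runs with an empty 2x2 margin
    seed: int | None


def _window_predictions(subject: SubjectAssociationData) -> tuple[
        np.ndarray, np.ndarray]:
    """Precompute (windows x trials) confidence 'high' predictions and
    (trials,) |RPE| 'high' predictions for one subject."""
    conf_preds = []
    for window in CONF_WINDOWS:
        idx = [tr - 1 for tr in window]
        avg = subject.conf_trs[:, idx, :].mean(axis=1)
        conf_preds.append(subject.conf_model.predict_proba(avg) >= 0.5)
    rpe_avg = subject.rpe_patterns.mean(axis=1)
    rpe_pred = subject.rpe_model.predict_proba(rpe_avg) >= 0.5
    return np.array(conf_preds), rpe_pred


def _best_window(conf_preds: np.ndarray, rpe_pred: np.ndarray,
                 idx: np.ndarray | None = None) -> int:
    if idx is None:
        idx = slice(None)
    chis = [chi2_2x2(cp[idx], rpe_pred[idx]) for cp in conf_preds]
    return int(np.argmax(chis))


def chi2_association(subjects: list[SubjectAssociationData],
                     n_boot: int = 1000,
                     seed: int | None = 0,
                     select_window: bool = True,
                     fixed_window: int = 4) -> AssociationResult:
    """Bootstrap distribution of the confidence-|RPE| association.

    Per bootstrap run, each subject's trial subset is resampled with
    replacement; the confidence prediction window (of the nine 3-TR
    windows in TRs 7-16) maximizing that subject's chi-square against
    the |RPE| predictions is re-chosen on the resampled trials; the two
    prediction vectors are concatenated over subjects and a 2x2
    chi-square computed, together with the run's tally of target
    (high-confidence-low-|RPE| plus low-confidence-high-|RPE|) and
    opposite pairings. With ``select_window=False`` the fixed window
    index is used throughout (the selection-optimism-free variant).
    """
    rng = np.random.default_rng(seed)
    pre = [_window_predictions(s) for s in subjects]

    def run(indices_per_subject):
        conf_all, rpe_all = [], []
        for (conf_preds, rpe_pred), idx in zip(pre, indices_per_subject):
            w = (_best_window(conf_preds, rpe_pred, idx) if select_window
                 else fixed_window)
            conf_all.append(conf_preds[w][idx])
            rpe_all.append(rpe_pred[idx])
        conf_all = np.concatenate(conf_all)
        rpe_all = np.concatenate(rpe_all)
        chi2 = chi2_2x2(conf_all, rpe_all)
        target = int(np.sum(conf_all & ~rpe_all) + np.sum(~conf_all
                                                          & rpe_all))
        opposite = int(len(conf_all) - target)
        return chi2, target, opposite

    full_idx = [np.arange(len(p[1])) for p in pre]
    chi2_obs, _, _ = run(full_idx)
    chosen = [_best_window(cp, rp) if select_window else fixed_window
              for cp, rp in pre]

    chis = np.empty(n_boot)
    targets = np.empty(n_boot, dtype=int)
    opposites = np.empty(n_boot, dtype=int)
    degenerate = 0
    for b in range(n_boot):
        idxs = [rng.integers(0, len(p[1]), len(p[1])) for p in pre]
        chis[b], targets[b], opposites[b] = run(idxs)
        if chis[b] == 0.0:
            degenerate += 1
    return AssociationResult(
        chi2_distribution=chis, target_counts=targets,
        opposite_counts=opposites, chosen_windows=chosen,
        chi2_observed=chi2_obs, n_degenerate=degenerate, seed=seed)
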