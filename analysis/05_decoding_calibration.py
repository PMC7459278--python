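"""Decoder construction on synthetic multivoxel patterns.

Calibrates each region's planted effect size so that sparse-logistic-
regression decoding of that region's epoch-averaged patterns reaches
the study's cross-validated accuracy targets (state ~70%, confidence
~68.8%, |RPE| ~57.3%) -- the calibration runs on actual generated
pattern sets, so epoch averaging and signal grading are accounted for.
It then trains the three decoders for a small cohort and reports
accuracies and selected-voxel counts. Voxel counts are scaled down from
the study's ROI sizes (the scale factor is reported).
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np

from latentrl.decoding import train_slr
from latentrl.synth import (CohortSpec, default_pattern_specs,
                            generate_cohort, generate_patterns,
                            generate_subject)

ACCURACY_TARGETS = {"state": 0.70, "confidence": 0.688, "rpe": 0.573}
LABEL_COLUMNS = {"state": "pattern_class", "confidence": "conf_high",
                 "rpe": "rpe_high"}


def region_accuracy(effect: float, region: str, pspecs, subjects,
                    seed: int) -> float:
    """CV accuracy of the region decoder at a given planted effect size,
    averaged over calibration subjects (each with its own label
    distribution and graded-signal amplitudes)."""
    spec = {region: pspecs[region]}
    pspecs[region].effect_size = effect
    accs = []
    for r, subject in enumerate(subjects):
        rng = np.random.default_rng(seed + 31 * r)
        ps = generate_patterns(subject, spec, rng)[region]
        model = train_slr(ps.epoch_average(),
                          ps.labels[LABEL_COLUMNS[region]],
                          n_iterations=3, seed=seed + r)
        accs.append(float(model.cv_accuracy[model.chosen_iteration - 1]))
    return float(np.mean(accs))


def calibrate_region(region: str, target: float, pspecs, subjects,
                     seed: int, tol: float = 0.02,
                     max_iter: int = 12) -> float:
    lo, hi = 0.0, 1.0
    while region_accuracy(hi, region, pspecs, subjects, seed) < target:
        lo, hi = hi, hi * 2
        if hi > 32:
            raise RuntimeError(f"{region}: target {target} unreachable")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        acc = region_accuracy(mid, region, pspecs, subjects, seed)
        if abs(acc - target) <= tol:
            return mid
        lo, hi = (mid, hi) if acc < target else (lo, mid)
    return mid


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--scale", type=float, default=0.05,
                    help="voxel-count scale vs the study ROI sizes")
    ap.add_argument("--n-subjects", type=int, default=6)
    args = ap.parse_args()
    warnings.filterwarnings("ignore", category=UserWarning)

    pspecs = default_pattern_specs(scale=args.scale)
    spec = CohortSpec(
        n_subjects=args.n_subjects,
        group_split=(args.n_subjects - args.n_subjects // 2,
                     args.n_subjects // 2),
        blocks_per_session=(6, 6, 6), master_seed=args.seed)
    calib_subjects = [
        generate_subject(spec, f"CAL{i}", grp, args.seed + 999 + i)
        for i, grp in enumerate(("VC", "PFC"))]

    for region, ps in pspecs.items():
        ps.effect_size = calibrate_region(
            region, ACCURACY_TARGETS[region], pspecs, calib_subjects,
            args.seed)
        print(f"{region:<10} target {ACCURACY_TARGETS[region]:.3f} -> "
              f"calibrated effect size {ps.effect_size:.3f} "
              f"({ps.n_informative}/{ps.n_voxels} informative voxels)")

    subjects = generate_cohort(spec, pspecs)
    per_region: dict = {}
    for region, label_col in LABEL_COLUMNS.items():
        accs, n_sel = [], []
        for ds in subjects:
            ps = ds.patterns[region]
            model = train_slr(ps.epoch_average(), ps.labels[label_col],
                              n_iterations=3, seed=ds.seed % (2 ** 31))
            accs.append(float(
                model.cv_accuracy[model.chosen_iteration - 1]))
            n_sel.append(int(len(model.support)))
        per_region[region] = {
            "target": ACCURACY_TARGETS[region],
            "effect_size": round(pspecs[region].effect_size, 4),
            "cv_accuracy_mean": round(float(np.mean(accs)), 4),
            "cv_accuracy_sem": round(float(np.std(accs)
                                           / np.sqrt(len(accs))), 4),
            "selected_voxels_mean": round(float(np.mean(n_sel)), 1),
            "n_voxels": pspecs[region].n_voxels}

    out = {"voxel_scale": args.scale, "n_subjects": args.n_subjects,
           "decoders": per_region}
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "decoding.json").write_text(json.dumps(out, indent=1)
                                            + "\n")

    print(f"\ndecoders over {args.n_subjects} subjects "
          f"(voxel scale {args.scale}):")
    for region, r in per_region.items():
        print(f"  {region:<10} acc {r['cv_accuracy_mean']:.3f} "
              f"+- {r['cv_accuracy_sem']:.3f} SEM (target {r['target']}), "
              f"{r['selected_voxels_mean']:.0f}/{r['n_voxels']} voxels "
              "selected")
    print("\nwrote", args.out / "decoding.json")


if __name__ == "__main__":
    main()
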