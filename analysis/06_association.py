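"""Multivoxel confidence-|RPE| association under increasing coupling.

Runs the bootstrap chi-square pipeline (per-subject window search over
TRs 7-16, concatenation across subjects, 2x2 chi-square of predicted
high/low confidence against predicted high/low |RPE|) on synthetic
cohorts whose confidence-pattern coupling to |RPE| is set to 0, 0.3 and
0.6 -- the generator's emulation of the association strengthening from
the first to the last session. Reports each coupling level's bootstrap
distribution and the target/opposite pairing counts.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np

from latentrl.decoding import chi2_association
from latentrl.synth import (CohortSpec, build_association_inputs,
                            default_pattern_specs, generate_cohort)


def run_level(kappa: float, seed: int, n_subjects: int,
              n_boot: int) -> dict:
    spec = CohortSpec(
        n_subjects=n_subjects,
        group_split=(n_subjects - n_subjects // 2, n_subjects // 2),
        blocks_per_session=(6, 6, 6),
        conf_rpe_coupling=(0.0, 0.0, kappa), master_seed=seed)
    pspecs = default_pattern_specs(scale=0.03)
    for ps in pspecs.values():
        ps.effect_size = 2.0
    subjects = generate_cohort(spec, pspecs)
    inputs = build_association_inputs(subjects, seed=seed)
    res = chi2_association(inputs, n_boot=n_boot, seed=seed)
    return {
        "chi2_mean": round(float(res.chi2_distribution.mean()), 2),
        "chi2_p2_5": round(float(np.percentile(res.chi2_distribution,
                                               2.5)), 2),
        "chi2_p97_5": round(float(np.percentile(res.chi2_distribution,
                                                97.5)), 2),
        "chi2_observed": round(res.chi2_observed, 2),
        "target_mean": round(float(res.target_counts.mean()), 1),
        "opposite_mean": round(float(res.opposite_counts.mean()), 1),
        "chosen_windows": [int(w) for w in res.chosen_windows]}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-subjects", type=int, default=6)
    ap.add_argument("--n-boot", type=int, default=300)
    args = ap.parse_args()
    warnings.filterwarnings("ignore", category=UserWarning)

    levels = {}
    for kappa in (0.0, 0.3, 0.6):
        levels[str(kappa)] = run_level(kappa, args.seed,
                                       args.n_subjects, args.n_boot)
        r = levels[str(kappa)]
        print(f"coupling {kappa:.1f}: bootstrap chi2 mean {r['chi2_mean']}"
              f" [{r['chi2_p2_5']}, {r['chi2_p97_5']}], target "
              f"{r['target_mean']} vs opposite {r['opposite_mean']}")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "association.json").write_text(
        json.dumps(levels, indent=1) + "\n")
    means = [levels[k]["chi2_mean"] for k in ("0.0", "0.3", "0.6")]
    print("\nassociation strength is monotone in the coupling knob:"
          if means[0] < means[1] < means[2] else
          "\nwarning: association strength not monotone at this seed:",
          " -> ".join(str(m) for m in means))
    print("wrote", args.out / "association.json")


if __name__ == "__main__":
    main()
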