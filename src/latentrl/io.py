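"""Data schemas, readers/writers, configuration and the full pipeline.

Behavioural trial tables travel as tab-delimited text with a fixed
header (one row per trial, sorted by subject/session/block/trial);
ground-truth columns from the simulator are carried as extras.
Configuration is YAML mirroring the cohort/task dataclasses; reports are
JSON keyed by (subject, session) with cohort-level summaries, fully
determined by the master seed.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import metacog as mc
from .decoding import chi2_association
from .fitting import GridSpec, compare_models, fit_grid
from .synth import (CohortSpec, SubjectDataset, build_association_inputs,
                    cohort_frame, default_pattern_specs, generate_cohort)

BEHAVIOR_COLUMNS = [
    "subject", "group", "session", "block", "trial", "pattern_class",
    "latent_state", "likelihood", "coherence", "discrimination",
    "confidence", "action", "reward", "optimal_action",
]

_CATEGORICAL = {
    "pattern_class": {"L", "R"},
    "latent_state": {"L", "R"},
    "discrimination": {"L", "R"},
    "action": {"A", "B"},
    "optimal_action": {"A", "B"},
}


class SchemaError(ValueError):
    pass


def validate_behavior(table: pd.DataFrame) -> None:
    """Schema check; raises `SchemaError` naming the first offending row
    (0-based, excluding the header)."""
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    for col, allowed in _CATEGORICAL.items():
        bad = ~table[col].isin(list(allowed))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"row {row}: invalid {col} value "
                f"{table[col].iloc[row]!r} (allowed {sorted(allowed)})")
    conf = table["confidence"]
    bad = ~conf.isin([1, 2, 3, 4])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"row {row}: confidence {conf.iloc[row]!r} "
                          "outside 1..4")
    bad = ~table["reward"].isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"row {row}: reward must be 0/1")
    lik = table["likelihood"].to_numpy(dtype=float)
    bad = (lik < 0) | (lik > 1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(f"row {row}: likelihood {lik[row]} outside [0, 1]")
    keys = table[["subject", "session", "block", "trial"]]
    if keys.duplicated().any():
        row = int(np.flatnonzero(keys.duplicated().to_numpy())[0])
        raise SchemaError(f"row {row}: duplicate (subject, session, block, "
                          "trial) key")
    arr = keys.to_numpy()
    for i in range(len(arr) - 1):
        if tuple(arr[i]) > tuple(arr[i + 1]):
            raise SchemaError(f"row {i + 1}: keys not sorted by "
                              "subject/session/block/trial")


def write_behavior(table: pd.DataFrame, path) -> None:
    validate_behavior(table)
    table.to_csv(path, sep="\t", index=False)


def read_behavior(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t")
    validate_behavior(table)
    return table


def write_patterns_long(data: np.ndarray, path) -> None:
    """Write a (trials, TRs, voxels) array as long-format TSV with
    columns trial, tr, voxel, value (trial 0-based, tr/voxel as in the
    array but tr written 1-based)."""
    n_t, n_tr, n_v = data.shape
    long = pd.DataFrame({
        "trial": np.repeat(np.arange(n_t), n_tr * n_v),
        "tr": np.tile(np.repeat(np.arange(1, n_tr + 1), n_v), n_t),
        "voxel": np.tile(np.arange(n_v), n_t * n_tr),
        "value": data.ravel()})
    long.to_csv(path, sep="\t", index=False)


def read_patterns_long(path) -> np.ndarray:
    """Read a long-format pattern TSV back into a dense
    (trials, TRs, voxels) array."""
    long = pd.read_csv(path, sep="\t")
    required = {"trial", "tr", "voxel", "value"}
    if not required <= set(long.columns):
        raise SchemaError(f"pattern file must have columns {sorted(required)}")
    n_t = int(long["trial"].max()) + 1
    n_tr = int(long["tr"].max())
    n_v = int(long["voxel"].max()) + 1
    if len(long) != n_t * n_tr * n_v:
        raise SchemaError("pattern file is not a complete dense grid")
    data = np.empty((n_t, n_tr, n_v), dtype=np.float32)
    idx = (long["trial"].to_numpy() * n_tr
           + (long["tr"].to_numpy() - 1)) * n_v + long["voxel"].to_numpy()
    data.ravel()[idx] = long["value"].to_numpy()
    return data


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_cohort(subjects: list[SubjectDataset], out_dir) -> None:
    """Materialize a cohort: one behaviour TSV per subject, long-format
    TSVs per pattern region, and a manifest with seeds and ground
    truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for ds in subjects:
        sdir = out / f"subject_{ds.subject}"
        sdir.mkdir(exist_ok=True)
        write_behavior(ds.trials, sdir / "behavior.tsv")
        ds.stage0.to_csv(sdir / "stage0_discrimination.tsv", sep="\t",
                         index=False)
        for region, ps in ds.patterns.items():
            write_patterns_long(ps.data, sdir / f"patterns_{region}.tsv")
        manifest[ds.subject] = {
            "group": ds.group, "seed": int(ds.seed),
            "alpha": ds.params.alpha, "beta": ds.params.beta,
            "eta": ds.params.eta, "state_bias": ds.state_bias,
            "decoder_accuracy": ds.decoder_accuracy,
            "metacog_efficiency": ds.metacog_efficiency,
            "optimal_map": ds.optimal_map}
    with open(out / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def run_pipeline(config: dict | None = None, seed: int = 0,
                 out_dir=None) -> dict:
    """Full synthetic analysis: simulate a cohort, fit both learning
    models per subject and session, compute the behavioural and
    metacognitive statistics, train decoders on the synthetic patterns
    and run the bootstrap association. Deterministic given the seed.

    The default configuration is scaled for desk use: a reduced fitting
    grid and reduced voxel counts (see docs). Pass a config dict (or the
    YAML equivalent) to override.
    """
    cfg = {
        "n_subjects": 6, "group_split": None,
        "grid": {"n_alpha": 25, "n_beta": 25, "n_eta": 26, "n_runs": 20},
        "pattern_scale": 0.04, "effect_size": 2.0,
        "n_boot": 200, "decode": True,
    }
    cfg.update(config or {})
    n_sub = int(cfg["n_subjects"])
    split = cfg["group_split"] or (n_sub - n_sub // 2, n_sub // 2)
    spec = CohortSpec(n_subjects=n_sub, group_split=tuple(split),
                      master_seed=seed)
    pattern_specs = None
    if cfg["decode"]:
        pattern_specs = default_pattern_specs(scale=float(
            cfg["pattern_scale"]))
        for ps in pattern_specs.values():
            ps.effect_size = float(cfg["effect_size"])
    subjects = generate_cohort(spec, pattern_specs)
    frame = cohort_frame(subjects)

    report: dict = {"seed": seed, "config_hash": config_hash(cfg),
                    "n_subjects": n_sub, "subjects": {}}
    grid = GridSpec(n_alpha=cfg["grid"]["n_alpha"],
                    n_beta=cfg["grid"]["n_beta"],
                    n_eta=cfg["grid"]["n_eta"],
                    n_runs=cfg["grid"]["n_runs"])
    summary = bh.session_summary(frame)
    for ds in subjects:
        sub_rep = {"group": ds.group, "sessions": {}}
        for session, g in ds.trials.groupby("session"):
            fit_sd = fit_grid(g, "rl_sd_noisy", grid, seed=ds.seed)
            fit_sf = fit_grid(g, "rl_sf", grid)
            cmpres = compare_models(fit_sd, fit_sf)
            row = summary[(summary["subject"] == ds.subject)
                          & (summary["session"] == session)].iloc[0]
            sub_rep["sessions"][int(session)] = {
                "p_opt_action": row["p_opt_action"],
                "p_correct_discrimination":
                    row["p_correct_discrimination"],
                "wsls_p_opt": row["wsls_p_opt"],
                "state_bias_mean": row["state_bias_mean"],
                "alpha_hat": fit_sd.alpha_hat, "beta_hat": fit_sd.beta_hat,
                "eta_hat": fit_sd.eta_hat,
                "delta_aic": cmpres.delta_aic,
                "delta_aic_normalized": cmpres.delta_aic_normalized,
            }
        counts = mc.type2_counts(ds.stage0["stimulus"],
                                 ds.stage0["response"],
                                 ds.stage0["confidence"])
        fit = mc.fit_meta_d(counts)
        sub_rep["meta_d"] = fit.meta_d
        sub_rep["d_prime"] = fit.d_prime
        report["subjects"][ds.subject] = sub_rep

    # cohort-level tests per session (FDR-corrected as one family)
    pvals, sess_stats = [], {}
    for session in sorted(frame["session"].unique()):
        rates = summary[summary["session"] == session]["p_opt_action"]
        mean_diff, t, p = bh.chance_test(rates, 0.5)
        sess_stats[int(session)] = {"p_opt_minus_chance": mean_diff,
                                    "t": t, "p": p}
        pvals.append(p)
    for (s, adj) in zip(sess_stats, bh.fdr_bh(pvals)):
        sess_stats[s]["p_fdr"] = float(adj)
    report["chance_tests"] = sess_stats

    meta_ds = [report["subjects"][s.subject]["meta_d"] for s in subjects]
    baseline = mc.baseline_performance(summary)
    baseline = [baseline[s.subject] for s in subjects]
    try:
        r, slope, p = mc.metacog_vs_baseline(meta_ds, baseline)
        report["metacog_vs_baseline"] = {"pearson_r": r,
                                         "robust_slope": slope, "p": p}
    except ValueError as exc:
        report["metacog_vs_baseline"] = {"error": str(exc)}

    if cfg["decode"]:
        assoc_subjects = build_association_inputs(subjects, seed=seed)
        assoc = chi2_association(assoc_subjects, n_boot=int(cfg["n_boot"]),
                                 seed=seed)
        report["association"] = {
            "chi2_mean": float(assoc.chi2_distribution.mean()),
            "chi2_p2_5": float(np.percentile(assoc.chi2_distribution, 2.5)),
            "chi2_p97_5": float(np.percentile(assoc.chi2_distribution,
                                              97.5)),
            "chi2_observed": assoc.chi2_observed,
            "target_mean": float(assoc.target_counts.mean()),
            "opposite_mean": float(assoc.opposite_counts.mean()),
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_behavior(frame, out / "behavior.tsv")
        summary.to_csv(out / "session_summary.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report
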