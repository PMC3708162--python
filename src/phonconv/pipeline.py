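"""Pipeline orchestration: synth -> measure -> slopes -> stats.

Each stage persists plain CSV/JSON intermediates so every step is
independently inspectable, validates its input schema on load, and logs
counts in and out.  A manifest with SHA-256 checksums is written per run so
artifacts are verifiably regenerable from config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, stats
from .acoustics import measure_corpus, measurements_from_simulation
from .config import AUDIO, ORACLE, RunConfig
from .design import ExperimentDesign
from .simulate import TRIAL_COLUMNS, full_study_profiles, simulate_experiment

log = logging.getLogger("phonconv")

MEASUREMENT_COLUMNS = [
    "experiment", "subject_id", "trial_index", "seg_start", "seg_end",
    "peak_time", "f0_hz", "f1_hz", "valid", "invalid_reason",
]
SLOPE_COLUMNS = ["experiment", "subject_id", "measure", "contrast", "slope",
                 "intercept", "n_points", "outlier"]


class SchemaError(ValueError):
    """A stage input is missing required columns."""


def _check_schema(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing columns {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _update_manifest(outdir: Path, *paths: Path) -> None:
    manifest_path = outdir / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    for p in paths:
        manifest[str(p.relative_to(outdir))] = _sha256(p)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _designs(config: RunConfig) -> list[ExperimentDesign]:
    return [
        ExperimentDesign(task, n_subjects=config.n_subjects, error_rate=config.error_rate)
        for task in config.tasks
    ]


def _profile_kwargs(config: RunConfig) -> dict:
    kwargs: dict = {"noise_sd": (config.noise_sd_f0, config.noise_sd_f1)}
    gm = {}
    if config.gain_converge is not None:
        gm["converge"] = config.gain_converge
    if config.gain_after is not None:
        gm["after"] = config.gain_after
    if gm:
        kwargs["gain_means"] = gm
    if config.gain_sd is not None:
        kwargs["gain_sds"] = {"converge": config.gain_sd, "after": config.gain_sd}
    return kwargs


def run_synth(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Generate the corpus: trial table, ground truth, optional WAV audio."""
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    designs = _designs(config)
    profiles = full_study_profiles(designs, config.seed, **_profile_kwargs(config))
    result = simulate_experiment(
        designs, profiles, seed=config.seed, variant=config.bark_variant,
        render_audio=config.render_audio,
        audio_dir=out / "audio" if config.render_audio else None,
        sample_rate=config.sample_rate, duration=config.duration,
        level=config.level_db,
    )
    trials_path = out / "trials.csv"
    truth_path = out / "ground_truth.csv"
    result.trials.to_csv(trials_path, index=False)
    result.ground_truth.to_csv(truth_path, index=False)
    config.to_yaml(out / "config.yaml")
    _update_manifest(out, trials_path, truth_path, out / "config.yaml")
    spoken = int((result.trials["response_kind"] == "spoken").sum())
    log.info("synth: %d trials (%d spoken) across %d experiments -> %s",
             len(result.trials), spoken, len(designs), out)
    return out


def load_trials(outdir: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(outdir) / "trials.csv", keep_default_na=False,
                     na_values=[""], dtype={"speaker_id": str, "audio_path": str})
    df["speaker_id"] = df["speaker_id"].fillna("")
    df["audio_path"] = df["audio_path"].fillna("")
    _check_schema(df, TRIAL_COLUMNS, "trial table")
    return df


def run_measure(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Measure the corpus (oracle or audio mode); resumable on re-run."""
    out = Path(outdir if outdir is not None else config.outdir)
    trials = load_trials(out)
    meas_path = out / "measurements.csv"

    if config.measurement_mode == ORACLE:
        measurements = measurements_from_simulation(trials)
        report = None
    else:
        done = pd.DataFrame(columns=MEASUREMENT_COLUMNS)
        if meas_path.exists():
            done = pd.read_csv(meas_path)
            _check_schema(done, MEASUREMENT_COLUMNS, "existing measurements")
        keys = ["experiment", "subject_id", "trial_index"]
        todo = trials.merge(done[keys].assign(_done=True), on=keys, how="left")
        todo = todo[todo["_done"].isna()].drop(columns="_done")
        log.info("measure: %d trials already measured, %d to do", len(done), len(todo))
        fresh, report = measure_corpus(
            todo, out / "audio", sample_rate=config.sample_rate,
        )
        frames = [df for df in (done, fresh) if len(df)]
        measurements = (
            pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=MEASUREMENT_COLUMNS)
        )
        measurements = measurements.sort_values(
            ["experiment", "subject_id", "trial_index"]
        ).reset_index(drop=True)

    measurements.to_csv(meas_path, index=False)
    written = [meas_path]
    if report is not None:
        excl = out / "exclusion_report.json"
        excl.write_text(report.to_json())
        written.append(excl)
    _update_manifest(out, *written)
    log.info("measure: %d rows, %d valid -> %s", len(measurements),
             int(measurements["valid"].sum()), meas_path)
    return meas_path


def run_slopes(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Medians, outlier flags, correlation points, per-subject slopes."""
    out = Path(outdir if outdir is not None else config.outdir)
    trials = load_trials(out)
    measurements = pd.read_csv(out / "measurements.csv")
    _check_schema(measurements, MEASUREMENT_COLUMNS, "measurements")

    medians = metrics.compute_subblock_medians(
        measurements, trials, variant=config.bark_variant,
        min_valid=config.min_valid_trials,
    )
    n_subjects = trials.groupby("experiment")["subject_id"].nunique().min()
    if n_subjects >= 3:
        medians = metrics.flag_median_outliers(medians, k=config.outlier_k)
    else:
        log.info("slopes: <3 subjects per experiment, median outlier pass skipped")

    points = pd.concat(
        [
            metrics.build_correlation_points(
                medians, trials, contrast, variant=config.bark_variant
            )
            for contrast in metrics.CONTRASTS
        ],
        ignore_index=True,
    )
    slopes = metrics.fit_all_slopes(points, trials)
    if n_subjects >= 3:
        slopes = metrics.flag_slope_outliers(slopes, k=config.outlier_k)
    else:
        log.info("slopes: <3 subjects per experiment, slope outlier pass skipped")

    medians.to_csv(out / "medians.csv", index=False)
    points.to_csv(out / "points.csv", index=False)
    slopes_path = out / "slopes.csv"
    slopes.to_csv(slopes_path, index=False)

    accounting = {
        "utterances": {
            c: metrics.count_contrast_utterances(trials, c) for c in metrics.CONTRASTS
        },
        "medians": {
            "defined": int(medians["median_bark"].notna().sum()),
            "undefined": int(medians["median_bark"].isna().sum()),
            "outliers": int(medians["outlier"].sum()),
        },
        "points": {
            c: int((points["contrast"] == c).sum()) for c in metrics.CONTRASTS
        },
        "slopes": {
            "fitted": len(slopes),
            "outliers": int(slopes["outlier"].sum()),
        },
    }
    (out / "accounting.json").write_text(json.dumps(accounting, indent=2))
    _update_manifest(out, out / "medians.csv", out / "points.csv", slopes_path,
                     out / "accounting.json")
    log.info("slopes: %d medians (%d flagged), %d points, %d slopes (%d flagged)",
             len(medians), accounting["medians"]["outliers"], len(points),
             len(slopes), accounting["slopes"]["outliers"])
    return slopes_path


def run_stats(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Group inference battery over the slope table."""
    out = Path(outdir if outdir is not None else config.outdir)
    slopes = pd.read_csv(out / "slopes.csv")
    _check_schema(slopes, SLOPE_COLUMNS + ["congruency"], "slopes")
    report = stats.run_full_inference(slopes, alpha=config.alpha)
    results_path = out / "results.json"
    results_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "results.txt").write_text(_format_report(report))
    _update_manifest(out, results_path, out / "results.txt")
    log.info("stats: %d ANOVA families, %d t-test families, %d correlations -> %s",
             len(report["anova"]), len(report["t_tests"]),
             len(report["correlations"]), results_path)
    return results_path


def run_all(config: RunConfig, outdir: str | Path | None = None) -> Path:
    out = run_synth(config, outdir)
    run_measure(config, out)
    run_slopes(config, out)
    return run_stats(config, out)


def _format_report(report: dict) -> str:
    lines = ["group inference report", "=" * 40]
    for key, tab in sorted(report["anova"].items()):
        lines.append(f"\nANOVA  {key}  (n={tab['n_retained']})")
        for name, eff in tab["effects"].items():
            lines.append(
                f"  {name:18s} F({eff['df_num']}, {eff['df_den']}) = "
                f"{eff['F']:.2f}, p = {eff['p']:.4g}"
            )
    for key, family in sorted(report["t_tests"].items()):
        lines.append(f"\nt-tests vs 0  {key}")
        for task, t in family.items():
            lines.append(
                f"  {task:15s} mean = {t['mean']:+.3f}, t({t['df']}) = "
                f"{t['t']:.2f}, one-tailed p = {t['p_one_tailed']:.4g}"
            )
    lines.append("\ncorrelations")
    for key, c in sorted(report["correlations"].items()):
        lines.append(
            f"  {key:40s} r = {c['r']:+.2f}, slope = {c['fitted_slope']:+.2f}, "
            f"p = {c['p']:.4g} (n = {c['n']})"
        )
    return "\n".join(lines) + "\n"
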