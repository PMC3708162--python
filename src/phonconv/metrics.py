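"""Convergence metrics: sub-block medians, outlier pruning, slopes.

The core statistic is a per-subject regression slope.  For each subject,
block and vowel, productions are summarized by their median F0 and F1 in
bark; for the convergence contrast each (block, vowel) cell contributes a
point

    x = bark(target) - median(baseline orthographic sub-block)
    y = median(acoustic sub-block) - median(baseline orthographic sub-block)

and for the after-effect contrast y uses the post-exposure orthographic
sub-block instead.  Nine points (3 blocks x 3 vowels) per subject and
measure are fitted by OLS; the slope estimates the fraction of the
target-baseline distance covered.

Outlier handling follows a single-shot +/- 2 SD rule, applied first to the
medians (within a pooling cell across participants) and then to the slopes
(within experiment x measure x contrast).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import bark
from .design import ACOUSTIC, ACOUSTIC_CUE, BASELINE_ORTHO, ORTHOGRAPHIC_CUE, POST_ORTHO
from .targets import SpeakerTarget, TARGET_BANK, get_target

MEASURES = ("f0", "f1")
CONVERGENCE = "convergence"
AFTER_EFFECT = "after_effect"
CONTRASTS = (CONVERGENCE, AFTER_EFFECT)

# analysis roles (after expanding the shared boundary sub-blocks)
ROLE_BASELINE = "baseline"
ROLE_ACOUSTIC = "acoustic"
ROLE_POST = "post"

MIN_VALID_TRIALS = 2
OUTLIER_K = 2.0
MEDIAN_POOLING = ("experiment", "measure", "vowel", "block_index", "role")
SLOPE_GROUPING = ("experiment", "measure", "contrast")


def join_measurements(measurements: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Join measurement rows to their trial metadata."""
    keys = ["experiment", "subject_id", "trial_index"]
    meta = trials.drop(columns=["sim_f0_hz", "sim_f1_hz"], errors="ignore")
    return measurements.merge(meta, on=keys, how="left", validate="one_to_one")


def compute_subblock_medians(
    measurements: pd.DataFrame,
    trials: pd.DataFrame,
    variant: str = bark.AS_PRINTED,
    min_valid: int = MIN_VALID_TRIALS,
) -> pd.DataFrame:
    """Median bark F0/F1 per (subject, analysis sub-block, vowel, measure).

    The shared boundary sub-blocks are expanded: a stored post-exposure
    orthographic sub-block of block k also appears as the baseline of block
    k+1.  Cells with fewer than ``min_valid`` valid trials get an undefined
    (NaN) median with a reason.

    Returns a long DataFrame with columns experiment, subject_id,
    block_index, role (baseline|acoustic|post), vowel, measure, median_bark,
    n_valid_trials, outlier (initialized False), undefined_reason.
    """
    joined = join_measurements(measurements, trials)
    n_blocks = int(trials["block_index"].max())
    valid = joined[joined["valid"]].copy()
    valid["bark_f0"] = bark.hz_to_bark(valid["f0_hz"].to_numpy(), variant)
    valid["bark_f1"] = bark.hz_to_bark(valid["f1_hz"].to_numpy(), variant)

    group_keys = ["experiment", "subject_id", "block_index", "sub_block_role", "vowel"]
    agg = valid.groupby(group_keys).agg(
        median_f0=("bark_f0", "median"),
        median_f1=("bark_f1", "median"),
        n_valid_trials=("bark_f0", "size"),
    )
    # every stored sub-block cell of the design, including all-omission ones
    spoken_like = joined[joined["invalid_reason"] != "key_press"]
    cells = spoken_like[group_keys].drop_duplicates().set_index(group_keys)
    agg = cells.join(agg).reset_index()
    agg["n_valid_trials"] = agg["n_valid_trials"].fillna(0).astype(int)
    low = agg["n_valid_trials"] < min_valid
    agg.loc[low, ["median_f0", "median_f1"]] = np.nan

    rows = []
    for r in agg.itertuples():
        stored_role = r.sub_block_role
        targets = []
        if stored_role == BASELINE_ORTHO:
            targets.append((r.block_index, ROLE_BASELINE))
        elif stored_role == ACOUSTIC:
            targets.append((r.block_index, ROLE_ACOUSTIC))
        elif stored_role == POST_ORTHO:
            targets.append((r.block_index, ROLE_POST))
            if r.block_index < n_blocks:
                targets.append((r.block_index + 1, ROLE_BASELINE))
        else:
            raise ValueError(f"unknown stored sub-block role {stored_role!r}")
        for block, role in targets:
            for measure, med in (("f0", r.median_f0), ("f1", r.median_f1)):
                rows.append(
                    {
                        "experiment": r.experiment,
                        "subject_id": r.subject_id,
                        "block_index": block,
                        "role": role,
                        "vowel": r.vowel,
                        "measure": measure,
                        "median_bark": med,
                        "n_valid_trials": r.n_valid_trials,
                        "outlier": False,
                        "undefined_reason": "" if np.isfinite(med) else "too_few_valid_trials",
                    }
                )
    return pd.DataFrame(rows)


def flag_median_outliers(
    medians: pd.DataFrame,
    k: float = OUTLIER_K,
    pooling: Sequence[str] = MEDIAN_POOLING,
) -> pd.DataFrame:
    """Flag medians outside mean +/- k SD within each pooling cell.

    The SD is the sample SD over the participants contributing to the cell;
    a zero-SD cell flags nothing (no value *exceeds* the bound).  Cells with
    fewer than three defined medians cannot support an SD criterion and
    raise ``ValueError``.
    """
    out = medians.copy()
    out["outlier"] = False
    for key, grp in out.groupby(list(pooling)):
        vals = grp["median_bark"].dropna()
        if len(vals) == 0:
            continue
        if len(vals) < 3:
            raise ValueError(
                f"median pooling cell {dict(zip(pooling, key))} has only "
                f"{len(vals)} defined values; need >= 3 for the SD criterion"
            )
        m, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            continue
        idx = grp.index[(grp["median_bark"] - m).abs() > k * sd]
        out.loc[idx, "outlier"] = True
    return out


def block_speaker_map(trials: pd.DataFrame) -> pd.DataFrame:
    """Per (experiment, subject, block) model speaker, from acoustic trials."""
    acoustic = trials[trials["cue"] == ACOUSTIC_CUE]
    m = acoustic[["experiment", "subject_id", "block_index", "speaker_id"]].drop_duplicates()
    counts = m.groupby(["experiment", "subject_id", "block_index"]).size()
    if (counts > 1).any():
        raise ValueError("a block maps to more than one model speaker")
    return m


def subject_metadata(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject labels (gender, congruency, persona) from the trial table."""
    cols = ["experiment", "subject_id", "subject_gender", "speaker_set", "congruency",
            "persona_id"]
    cols = [c for c in cols if c in trials.columns]
    return trials[cols].drop_duplicates()


def build_correlation_points(
    medians: pd.DataFrame,
    trials: pd.DataFrame,
    contrast: str,
    target_bank: Iterable[SpeakerTarget] = TARGET_BANK,
    variant: str = bark.AS_PRINTED,
) -> pd.DataFrame:
    """Correlation points (x, y) in bark per subject, measure, block, vowel.

    x is the target-minus-baseline distance; y is the production change of
    the contrast's numerator sub-block (acoustic for convergence, post-
    exposure orthographic for the after-effect) relative to the same
    baseline.  Points whose constituent medians are undefined or flagged
    are dropped (pairwise, per block x vowel).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    y_role = ROLE_ACOUSTIC if contrast == CONVERGENCE else ROLE_POST
    bank = list(target_bank)
    spk = block_speaker_map(trials).set_index(["experiment", "subject_id", "block_index"])

    usable = medians[~medians["outlier"] & medians["median_bark"].notna()]
    cell_keys = ["experiment", "subject_id", "block_index", "vowel", "measure"]
    wide = usable.pivot_table(
        index=cell_keys, columns="role", values="median_bark", aggfunc="first"
    ).reset_index()
    rows = []
    for r in wide.itertuples():
        base = getattr(r, ROLE_BASELINE, np.nan)
        yval = getattr(r, y_role, np.nan)
        if not (np.isfinite(base) and np.isfinite(yval)):
            continue
        try:
            speaker = spk.loc[(r.experiment, r.subject_id, r.block_index), "speaker_id"]
        except KeyError:
            raise ValueError(
                f"no model speaker known for {r.experiment}/{r.subject_id} "
                f"block {r.block_index}"
            )
        tgt = get_target(bank, speaker, r.vowel)
        tgt_bark = bark.hz_to_bark(tgt.f0 if r.measure == "f0" else tgt.f1, variant)
        rows.append(
            {
                "experiment": r.experiment,
                "subject_id": r.subject_id,
                "measure": r.measure,
                "contrast": contrast,
                "block_index": r.block_index,
                "vowel": r.vowel,
                "x": tgt_bark - base,
                "y": yval - base,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["experiment", "subject_id", "measure", "contrast",
                 "block_index", "vowel", "x", "y"],
    )


@dataclass(frozen=True)
class SlopeEstimate:
    """Per-subject OLS slope for one measure and contrast."""

    subject_id: str
    measure: str
    contrast: str
    slope: float
    intercept: float
    n_points: int
    outlier: bool = False


def fit_subject_slope(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    subject_id: str = "",
    measure: str = "",
    contrast: str = "",
) -> SlopeEstimate:
    """OLS line (with intercept) through a subject's correlation points.

    Requires at least two points with at least two distinct x values.
    """
    if isinstance(points, pd.DataFrame):
        x = points["x"].to_numpy(float)
        y = points["y"].to_numpy(float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 2:
        raise ValueError("need at least 2 points to fit a slope")
    if np.ptp(x) == 0:
        raise ValueError("slope undefined: all x values identical")
    slope, intercept = np.polyfit(x, y, 1)
    return SlopeEstimate(
        subject_id=subject_id, measure=measure, contrast=contrast,
        slope=float(slope), intercept=float(intercept), n_points=len(x),
    )


def fit_all_slopes(points: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Fit per-subject slopes for every (experiment, subject, measure, contrast).

    Subjects whose remaining points cannot support a fit (fewer than two, or
    degenerate x) are skipped.  Output carries the subject metadata needed by
    the group statistics (congruency, persona).
    """
    meta = subject_metadata(trials)
    rows = []
    keys = ["experiment", "subject_id", "measure", "contrast"]
    for key, grp in points.groupby(keys):
        exp, subj, measure, contrast = key
        if len(grp) < 2 or np.ptp(grp["x"].to_numpy()) == 0:
            continue
        est = fit_subject_slope(grp, subj, measure, contrast)
        rows.append(
            {
                "experiment": exp,
                "subject_id": subj,
                "measure": measure,
                "contrast": contrast,
                "slope": est.slope,
                "intercept": est.intercept,
                "n_points": est.n_points,
                "outlier": False,
            }
        )
    slopes = pd.DataFrame(
        rows, columns=["experiment", "subject_id", "measure", "contrast",
                       "slope", "intercept", "n_points", "outlier"],
    )
    return slopes.merge(meta, on=["experiment", "subject_id"], how="left")


def flag_slope_outliers(
    slopes: pd.DataFrame,
    k: float = OUTLIER_K,
    grouping: Sequence[str] = SLOPE_GROUPING,
) -> pd.DataFrame:
    """Flag slopes outside mean +/- k SD within each analysis group.

    Single pass; a zero-SD group flags nothing.  Groups smaller than three
    cannot support the criterion and raise ``ValueError``.
    """
    out = slopes.copy()
    out["outlier"] = False
    for key, grp in out.groupby(list(grouping)):
        if len(grp) < 3:
            raise ValueError(
                f"slope group {dict(zip(grouping, key))} has only {len(grp)} "
                "members; need >= 3 for the SD criterion"
            )
        m, sd = grp["slope"].mean(), grp["slope"].std(ddof=1)
        if sd == 0:
            continue
        idx = grp.index[(grp["slope"] - m).abs() > k * sd]
        out.loc[idx, "outlier"] = True
    return out


def count_contrast_utterances(trials: pd.DataFrame, contrast: str) -> int:
    """Number of distinct spoken utterances feeding a contrast's points.

    Convergence consumes the baseline orthographic and acoustic sub-blocks
    of the production and imitation experiments; the after-effect consumes
    every orthographic-cued utterance of all experiments (each boundary
    sub-block is both a post-exposure and a baseline, counted once).
    """
    spoken = trials[trials["response_kind"] == "spoken"]
    n_blocks = int(trials["block_index"].max())
    if contrast == CONVERGENCE:
        spoken = spoken[spoken["experiment"].isin(["production", "imitation"])]
        is_baseline = (spoken["sub_block_role"] == BASELINE_ORTHO) | (
            (spoken["sub_block_role"] == POST_ORTHO) & (spoken["block_index"] < n_blocks)
        )
        return int((is_baseline | (spoken["sub_block_role"] == ACOUSTIC)).sum())
    if contrast == AFTER_EFFECT:
        return int((spoken["cue"] == ORTHOGRAPHIC_CUE).sum())
    raise ValueError(f"unknown contrast {contrast!r}")


def points_accounting(points: pd.DataFrame, n_subjects: int, n_measures: int = 2,
                      n_contrasts: int = 1, max_points: int = 9) -> dict:
    """Count conservation report: points present vs the 9-per-set maximum."""
    expected = max_points * n_subjects * n_measures * n_contrasts
    present = len(points)
    return {
        "expected_if_unpruned": expected,
        "present": present,
        "lost": expected - present,
    }
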