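"""Synthetic subjects and trial corpora with known ground-truth gains.

The behavioral model is linear in the bark analysis space.  Each subject
carries a per-vowel production baseline and two gains:

* ``gain_converge`` — the fraction of the target-minus-baseline distance the
  subject covers while producing with the acoustic target present;
* ``gain_after`` — the fraction retained afterwards, i.e. the shift of the
  post-exposure orthographic productions.

Because the post-exposure orthographic sub-block of block k doubles as the
baseline of block k+1, the after-effect persists: the subject's operative
baseline is a running state, updated after each exposure block as

    s_{k+1} = s_k + gain_after * (T_k - s_k)          (in bark)

and productions are ``state + gain * (target - state) + noise`` with the
role-dependent gain (``gain_converge`` under acoustic cues, zero under
orthographic ones — the after-effect is already in the state).  Under this
model the per-subject regression slopes of both contrasts equal the
generative gains exactly when noise is zero, for every block.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import bark
from .audio_io import write_wav
from .design import (
    ACOUSTIC,
    ACOUSTIC_CUE,
    BASELINE_ORTHO,
    CATEGORIZATION,
    IMITATION,
    ORTHOGRAPHIC_CUE,
    POST_ORTHO,
    PRODUCTION,
    ExperimentDesign,
    SubjectAssignment,
    subblock_sequence,
    subject_assignments,
)
from .synth import VOWEL_F23, FORMANT_BANDWIDTHS, synthesize_vowel
from .targets import FEMALE, MALE, TARGET_BANK, SpeakerTarget, VOWELS, get_target

SPOKEN = "spoken"
KEY_PRESS = "key_press"
OMISSION = "omission"

#: Median produced F0/F1 (Hz) per (task, gender, vowel) across real
#: participant populations; used as population means for simulated baselines.
POPULATION_MEDIANS: Mapping[tuple[str, str, str], tuple[float, float]] = {
    (PRODUCTION, FEMALE, "i"): (225, 277),
    (PRODUCTION, FEMALE, "e"): (220, 416),
    (PRODUCTION, FEMALE, "E"): (214, 613),
    (PRODUCTION, MALE, "i"): (128, 277),
    (PRODUCTION, MALE, "e"): (125, 372),
    (PRODUCTION, MALE, "E"): (123, 508),
    (IMITATION, FEMALE, "i"): (221, 295),
    (IMITATION, FEMALE, "e"): (216, 417),
    (IMITATION, FEMALE, "E"): (211, 610),
    (IMITATION, MALE, "i"): (124, 270),
    (IMITATION, MALE, "e"): (120, 366),
    (IMITATION, MALE, "E"): (119, 522),
    (CATEGORIZATION, FEMALE, "i"): (222, 276),
    (CATEGORIZATION, FEMALE, "e"): (215, 407),
    (CATEGORIZATION, FEMALE, "E"): (210, 607),
    (CATEGORIZATION, MALE, "i"): (130, 269),
    (CATEGORIZATION, MALE, "e"): (126, 365),
    (CATEGORIZATION, MALE, "E"): (125, 545),
}

#: Group mean gains per task and measure (F0, F1): the convergence and
#: after-effect magnitudes the simulator reproduces by default.
DEFAULT_GAIN_MEANS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    PRODUCTION: {"converge": (0.08, 0.04), "after": (0.07, 0.06)},
    IMITATION: {"converge": (0.48, 0.13), "after": (0.23, 0.04)},
    CATEGORIZATION: {"converge": (0.0, 0.0), "after": (0.07, 0.04)},
}

#: Between-subject SDs of the gains, per task and measure (F0, F1), sized so
#: group t statistics land near the observed ones.
DEFAULT_GAIN_SDS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    PRODUCTION: {"converge": (0.10, 0.07), "after": (0.12, 0.11)},
    IMITATION: {"converge": (0.32, 0.15), "after": (0.22, 0.10)},
    CATEGORIZATION: {"converge": (0.0, 0.0), "after": (0.10, 0.10)},
}

#: Default within-subject trial noise SD (F0, F1) in as-printed bark units —
#: about 3 Hz of F0 scatter at 200 Hz and 20 Hz of F1 scatter at 400 Hz.
DEFAULT_NOISE_SD = (0.004, 0.012)

#: Between-subject baseline scatter (Hz): global F0 shift, global F1 shift,
#: extra per-vowel F1 jitter.
BASELINE_F0_SD = 15.0
BASELINE_F1_SD = 40.0
BASELINE_F1_VOWEL_SD = 10.0


def _pair(value) -> tuple[float, float]:
    """Broadcast a scalar gain/noise to a per-measure (F0, F1) pair."""
    if np.isscalar(value):
        return (float(value), float(value))
    a, b = value
    return (float(a), float(b))


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth parameters of one simulated participant."""

    subject_id: str
    persona_id: str
    gender: str
    baseline: Mapping[str, tuple[float, float]]  # vowel -> (F0 Hz, F1 Hz)
    gain_converge: tuple[float, float]           # (F0, F1), bark-space
    gain_after: tuple[float, float]
    noise_sd: tuple[float, float]                # (F0, F1), bark units >= 0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if set(self.baseline) != set(VOWELS):
            raise ValueError("baseline must be defined for all three vowels")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def make_profiles(
    design: ExperimentDesign,
    seed_seq: np.random.SeedSequence,
    gain_means: Mapping[str, tuple[float, float]] | None = None,
    gain_sds: Mapping[str, tuple[float, float]] | None = None,
    noise_sd=DEFAULT_NOISE_SD,
    error_rate: float | None = None,
    reuse_personas: Sequence[SubjectProfile] = (),
) -> list[SubjectProfile]:
    """Draw a subject population for one experiment.

    Baselines are drawn around the population medians for the task and gender;
    gains are Gaussian with the task's mean and SD (override via ``gain_means``
    / ``gain_sds`` with keys "converge" and "after").  ``reuse_personas``
    re-uses the baselines (not the gains) of previously drawn profiles, for
    the subgroup that participates in two experiments.
    """
    means = dict(DEFAULT_GAIN_MEANS[design.task])
    if gain_means:
        means.update({k: _pair(v) for k, v in gain_means.items()})
    sds = dict(DEFAULT_GAIN_SDS[design.task])
    if gain_sds:
        sds.update({k: _pair(v) for k, v in gain_sds.items()})
    err = design.effective_error_rate if error_rate is None else error_rate
    noise = _pair(noise_sd)

    assignments = subject_assignments(design)
    reuse_by_gender: dict[str, list[SubjectProfile]] = {FEMALE: [], MALE: []}
    for p in reuse_personas:
        reuse_by_gender[p.gender].append(p)

    profiles = []
    children = seed_seq.spawn(len(assignments))
    for assign, child in zip(assignments, children):
        rng = np.random.default_rng(child)
        pool = reuse_by_gender[assign.gender]
        if pool:
            source = pool.pop(0)
            baseline = dict(source.baseline)
            persona = source.persona_id
        else:
            f0_shift = rng.normal(0.0, BASELINE_F0_SD)
            f1_shift = rng.normal(0.0, BASELINE_F1_SD)
            baseline = {}
            for v in VOWELS:
                f0_med, f1_med = POPULATION_MEDIANS[(design.task, assign.gender, v)]
                f0_v = f0_med + f0_shift
                f1_v = f1_med + f1_shift + rng.normal(0.0, BASELINE_F1_VOWEL_SD)
                # keep F1 safely above F0 so productions stay synthesizable
                baseline[v] = (f0_v, max(f1_v, 1.25 * f0_v))
            persona = assign.subject_id
        gc = tuple(rng.normal(m, s) for m, s in zip(means["converge"], sds["converge"]))
        ga = tuple(rng.normal(m, s) for m, s in zip(means["after"], sds["after"]))
        profiles.append(
            SubjectProfile(
                subject_id=assign.subject_id,
                persona_id=persona,
                gender=assign.gender,
                baseline=baseline,
                gain_converge=gc,
                gain_after=ga,
                noise_sd=noise,
                error_rate=err,
            )
        )
    return profiles


def simulate_production(
    profile: SubjectProfile,
    vowel: str,
    cue: str,
    target: SpeakerTarget | None,
    contrast_role: str,
    rng: np.random.Generator,
    variant: str = bark.AS_PRINTED,
    baseline_hz: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Produce one (F0, F1) pair in Hz for a single trial.

    The production model acts in bark space: produced = baseline +
    g * (target - baseline) + noise, with g = ``gain_converge`` for
    acoustic-cue trials, 0 for orthographic trials (the after-effect is
    carried by the running baseline passed via ``baseline_hz``).

    ``baseline_hz`` overrides the profile's static baseline; the experiment
    simulator passes the subject's current adapted state here.
    """
    if cue == ACOUSTIC_CUE and target is None:
        raise ValueError("acoustic-cue trial requires a target")
    base_hz = baseline_hz if baseline_hz is not None else profile.baseline[vowel]
    base = np.array([bark.hz_to_bark(h, variant) for h in base_hz])
    if cue == ACOUSTIC_CUE:
        gains = np.array(profile.gain_converge)
    elif contrast_role == POST_ORTHO and baseline_hz is None:
        # Standalone use (no running state): apply the after-effect directly.
        gains = np.array(profile.gain_after)
    else:
        gains = np.zeros(2)
    if target is not None:
        tgt = np.array(
            [bark.hz_to_bark(target.f0, variant), bark.hz_to_bark(target.f1, variant)]
        )
        produced = base + gains * (tgt - base)
    else:
        produced = base.copy()
    produced = produced + rng.normal(0.0, profile.noise_sd, size=2)
    produced = np.maximum(produced, 1e-6)  # bark is non-negative
    return (
        bark.bark_to_hz(produced[0], variant),
        bark.bark_to_hz(produced[1], variant),
    )


@dataclass
class SimulationResult:
    trials: pd.DataFrame
    ground_truth: pd.DataFrame
    audio: dict[str, np.ndarray] | None = None


TRIAL_COLUMNS = [
    "experiment", "subject_id", "subject_gender", "persona_id", "speaker_set",
    "congruency", "block_index", "speaker_id", "sub_block_role", "trial_index",
    "cue", "vowel", "response_kind", "audio_path", "sim_f0_hz", "sim_f1_hz",
]


def _render(sim_f0: float, sim_f1: float, vowel: str, sample_rate: float,
            duration: float, level: float) -> np.ndarray:
    f2, f3 = VOWEL_F23[vowel]
    b1, b2, b3 = FORMANT_BANDWIDTHS
    return synthesize_vowel(
        sim_f0, [(sim_f1, b1), (f2, b2), (f3, b3)],
        duration=duration, sample_rate=sample_rate, level=level,
    )


def simulate_experiment(
    designs: Sequence[ExperimentDesign],
    profiles: Mapping[str, Sequence[SubjectProfile]],
    seed: int | np.random.SeedSequence,
    variant: str = bark.AS_PRINTED,
    target_bank: Iterable[SpeakerTarget] = TARGET_BANK,
    render_audio: bool = False,
    audio_dir: str | Path | None = None,
    sample_rate: int = 44100,
    duration: float = 0.25,
    level: float = 75.0,
) -> SimulationResult:
    """Run the full trial generator for one or more experiments.

    Parameters
    ----------
    designs : sequence of ExperimentDesign
    profiles : mapping task -> list of SubjectProfile (one per subject)
    seed : int or SeedSequence
        Master seed; every subject gets an independent child stream, so the
        corpus is reproducible and insensitive to the order of experiments.
    render_audio : bool
        If True, synthesize audio for every spoken trial (in memory, or to
        ``audio_dir`` as WAV files if given).

    Returns
    -------
    SimulationResult
        ``trials`` has one row per stored trial (shared boundary sub-blocks
        appear once); ``ground_truth`` records each subject's true gains and
        baselines; ``audio`` maps trial audio_path -> waveform when audio was
        rendered in memory.
    """
    bank = list(target_bank)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    audio: dict[str, np.ndarray] = {}
    out_dir = Path(audio_dir) if audio_dir is not None else None

    # One child seed per (experiment, subject), derived independently of
    # iteration order by spawning per design in task order.
    for design in designs:
        task_profiles = list(profiles[design.task])
        assigns = subject_assignments(design)
        if len(task_profiles) != len(assigns):
            raise ValueError(
                f"{design.task}: {len(task_profiles)} profiles for {len(assigns)} design slots"
            )
        subj_seeds = np.random.SeedSequence(
            entropy=master.entropy, spawn_key=(hash_task(design.task),)
        ).spawn(len(assigns))
        for assign, profile, sseq in zip(assigns, task_profiles, subj_seeds):
            if profile.subject_id != assign.subject_id:
                raise ValueError(
                    f"profile {profile.subject_id} does not match slot {assign.subject_id}"
                )
            rows_s, audio_s = _simulate_subject(
                design, assign, profile, bank, np.random.default_rng(sseq), variant,
                render_audio, out_dir, sample_rate, duration, level,
            )
            rows.extend(rows_s)
            audio.update(audio_s)
            truth_rows.append(_truth_row(design.task, assign, profile))

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return SimulationResult(trials=trials, ground_truth=truth,
                            audio=audio if (render_audio and out_dir is None) else None)


def hash_task(task: str) -> int:
    """Stable small integer per task for seed derivation."""
    return {PRODUCTION: 1, IMITATION: 2, CATEGORIZATION: 3}[task]


def _truth_row(task: str, assign: SubjectAssignment, p: SubjectProfile) -> dict:
    row = {
        "experiment": task,
        "subject_id": p.subject_id,
        "persona_id": p.persona_id,
        "gender": p.gender,
        "speaker_set": assign.speaker_set,
        "congruency": assign.congruency,
        "gain_converge_f0": p.gain_converge[0],
        "gain_converge_f1": p.gain_converge[1],
        "gain_after_f0": p.gain_after[0],
        "gain_after_f1": p.gain_after[1],
        "noise_sd_f0": p.noise_sd[0],
        "noise_sd_f1": p.noise_sd[1],
        "error_rate": p.error_rate,
    }
    for v in VOWELS:
        row[f"baseline_f0_{v}"] = p.baseline[v][0]
        row[f"baseline_f1_{v}"] = p.baseline[v][1]
    return row


def _simulate_subject(
    design: ExperimentDesign,
    assign: SubjectAssignment,
    profile: SubjectProfile,
    bank: list[SpeakerTarget],
    rng: np.random.Generator,
    variant: str,
    render_audio: bool,
    out_dir: Path | None,
    sample_rate: int,
    duration: float,
    level: float,
) -> tuple[list[dict], dict[str, np.ndarray]]:
    rows: list[dict] = []
    audio: dict[str, np.ndarray] = {}
    # Running adapted baseline, per vowel, in bark (F0, F1).
    state = {
        v: np.array(
            [bark.hz_to_bark(profile.baseline[v][0], variant),
             bark.hz_to_bark(profile.baseline[v][1], variant)]
        )
        for v in VOWELS
    }
    gains_c = np.array(profile.gain_converge)
    gains_a = np.array(profile.gain_after)
    trial_index = 0

    for sb in subblock_sequence(design):
        speaker = assign.block_speakers[sb.block_index - 1]
        order = [v for _ in range(sb.repeats) for v in VOWELS]
        order = [order[i] for i in rng.permutation(len(order))]
        for vowel in order:
            trial_index += 1
            is_acoustic = sb.cue == ACOUSTIC_CUE
            target = get_target(bank, speaker, vowel) if is_acoustic else None
            if is_acoustic and design.task == CATEGORIZATION:
                response = KEY_PRESS
            elif rng.random() < profile.error_rate:
                response = OMISSION
            else:
                response = SPOKEN
            sim_f0 = sim_f1 = np.nan
            path = ""
            if response == SPOKEN:
                base = state[vowel]
                if is_acoustic:
                    tgt = np.array(
                        [bark.hz_to_bark(target.f0, variant),
                         bark.hz_to_bark(target.f1, variant)]
                    )
                    mean = base + gains_c * (tgt - base)
                else:
                    mean = base
                produced = mean + rng.normal(0.0, profile.noise_sd, size=2)
                produced = np.maximum(produced, 1e-6)
                sim_f0 = bark.bark_to_hz(produced[0], variant)
                sim_f1 = bark.bark_to_hz(produced[1], variant)
                if render_audio:
                    path = f"{design.task}/{profile.subject_id}/t{trial_index:04d}.wav"
                    wave = _render(sim_f0, sim_f1, vowel, sample_rate, duration, level)
                    if out_dir is not None:
                        write_wav(out_dir / path, wave, sample_rate)
                    else:
                        audio[path] = wave
            rows.append(
                {
                    "experiment": design.task,
                    "subject_id": profile.subject_id,
                    "subject_gender": profile.gender,
                    "persona_id": profile.persona_id,
                    "speaker_set": assign.speaker_set,
                    "congruency": assign.congruency,
                    "block_index": sb.block_index,
                    "speaker_id": speaker if is_acoustic else "",
                    "sub_block_role": sb.role,
                    "trial_index": trial_index,
                    "cue": sb.cue,
                    "vowel": vowel,
                    "response_kind": response,
                    "audio_path": path,
                    "sim_f0_hz": sim_f0,
                    "sim_f1_hz": sim_f1,
                }
            )
        # After each exposure block, the perceptual recalibration shifts the
        # operative baseline; the following orthographic sub-block (stored as
        # post_ortho, re-used as the next baseline) is produced at that state.
        if sb.cue == ACOUSTIC_CUE:
            for vowel in VOWELS:
                tgt_v = get_target(bank, speaker, vowel)
                tgt = np.array(
                    [bark.hz_to_bark(tgt_v.f0, variant), bark.hz_to_bark(tgt_v.f1, variant)]
                )
                state[vowel] = state[vowel] + gains_a * (tgt - state[vowel])
    return rows, audio


def full_study_profiles(
    designs: Sequence[ExperimentDesign],
    seed: int | np.random.SeedSequence,
    overlap_subgroup: int = 12,
    **kwargs,
) -> dict[str, list[SubjectProfile]]:
    """Profiles for a multi-experiment study.

    The first ``overlap_subgroup`` imitation-task personas (six female, six
    male with default counterbalancing) re-use production-task baselines, with
    independently drawn gains — the subgroup that performed both tasks.
    """
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out: dict[str, list[SubjectProfile]] = {}
    for design in designs:
        child = np.random.SeedSequence(
            entropy=master.entropy, spawn_key=(100 + hash_task(design.task),)
        )
        reuse: list[SubjectProfile] = []
        if design.task == IMITATION and PRODUCTION in out and overlap_subgroup:
            half = overlap_subgroup // 2
            by_gender = {FEMALE: [], MALE: []}
            for p in out[PRODUCTION]:
                by_gender[p.gender].append(p)
            reuse = by_gender[FEMALE][:half] + by_gender[MALE][:half]
        out[design.task] = make_profiles(design, child, reuse_personas=reuse, **kwargs)
    return out
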