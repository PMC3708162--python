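"""Acoustic measurement chain: segmentation, peak intensity, F0 and F1.

The chain mirrors a standard semi-automatic vowel measurement protocol:

1. segment each recording into vowel stretches by a short-time intensity and
   duration criterion;
2. locate the intensity peak within the segment;
3. measure F0 (autocorrelation with parabolic lag interpolation) and F1
   (LPC candidate + harmonic-amplitude resonance refinement) over a window
   of +/- 25 ms around the peak.

F1 estimation needs care at high F0: the spectrum is only observed at
multiples of F0, so plain LPC root-picking is biased toward the strongest
harmonic (errors approaching F0/2 for F0 near 300 Hz).  The refinement stage
therefore measures per-harmonic amplitudes and fits an explicit resonance
model to them — a discrete-all-pole-style estimator; see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, signal

SEG_FRAME = 0.010       # s, RMS frame for segmentation/intensity
SEG_HOP = 0.005         # s
SILENCE_THRESHOLD_DB = -25.0  # relative to utterance peak intensity
MIN_VOICED = 0.080      # s
MIN_PAUSE = 0.150       # s
HALF_WINDOW = 0.025     # s, measurement half-window around the peak
F0_SEARCH = (75.0, 400.0)     # Hz
VOICING_THRESHOLD = 0.45      # normalized autocorrelation peak
F1_RANGE = (150.0, 1100.0)    # Hz
BANDWIDTH_CEILING = 400.0     # Hz, LPC candidate filter
PREEMPHASIS = 0.97
LPC_RATE = 10000.0      # Hz, analysis rate for LPC
REFINE_BAND_CAP = 1800.0      # Hz, harmonic-fit band limit
SKIRT_BANDWIDTH = 150.0       # Hz, higher-pole skirt bandwidth (fixed)
ERROR_LIMIT = 0.10      # participant exclusion threshold


class DegenerateSegmentError(ValueError):
    """Segment too short for the requested frame."""


class WindowError(ValueError):
    """Measurement window outside the waveform."""


@dataclass(frozen=True)
class Segment:
    """A detected vowel stretch with its intensity-peak time (seconds)."""

    start: float
    end: float
    peak_time: float

    def __post_init__(self) -> None:
        if not self.start < self.peak_time < self.end:
            raise ValueError("peak_time must lie strictly inside the segment")


@dataclass
class VowelMeasurement:
    """Per-utterance measurement outcome."""

    trial_ref: str
    segment: Segment | None = None
    f0: float | None = None
    f1: float | None = None
    invalid_reason: str = "none"  # omission | no_segment | unvoiced | formant_failure | none

    @property
    def valid(self) -> bool:
        return self.f0 is not None and self.f1 is not None


def _frame_rms(x: np.ndarray, fs: float, frame: float, hop: float) -> tuple[np.ndarray, np.ndarray]:
    """Short-time RMS and frame-center times."""
    nf = int(round(frame * fs))
    nh = max(int(round(hop * fs)), 1)
    if len(x) < nf:
        return np.array([]), np.array([])
    starts = np.arange(0, len(x) - nf + 1, nh)
    sq = np.concatenate([[0.0], np.cumsum(x.astype(float) ** 2)])
    rms = np.sqrt((sq[starts + nf] - sq[starts]) / nf)
    centers = (starts + nf / 2.0) / fs
    return rms, centers


def segment_utterance(
    x: np.ndarray,
    fs: float,
    silence_threshold: float = SILENCE_THRESHOLD_DB,
    min_voiced: float = MIN_VOICED,
    min_pause: float = MIN_PAUSE,
    frame: float = SEG_FRAME,
    hop: float = SEG_HOP,
) -> list[Segment]:
    """Detect vowel stretches by intensity and duration.

    A frame is active when its RMS exceeds ``silence_threshold`` dB relative
    to the loudest frame.  Active runs separated by sub-threshold gaps
    shorter than ``min_pause`` are merged; runs shorter than ``min_voiced``
    are dropped.  Silence-only input yields an empty list.
    """
    if len(x) == 0:
        raise ValueError("empty waveform")
    rms, centers = _frame_rms(x, fs, frame, hop)
    if len(rms) == 0 or np.max(rms) <= 0:
        return []
    db = 20.0 * np.log10(np.maximum(rms, 1e-12) / np.max(rms))
    active = db > silence_threshold

    # runs of active frames
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(active):
        if active[i]:
            j = i
            while j + 1 < len(active) and active[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs separated by short pauses
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and (centers[run[0]] - centers[merged[-1][1]]) < min_pause:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    segments = []
    half = frame / 2.0
    for i0, i1 in merged:
        start = max(centers[i0] - half, 0.0)
        end = min(centers[i1] + half, len(x) / fs)
        if end - start >= min_voiced:
            peak = locate_peak_intensity(x, fs, start, end, frame=frame, hop=hop)
            segments.append(Segment(start=start, end=end, peak_time=peak))
    return segments


def locate_peak_intensity(
    x: np.ndarray,
    fs: float,
    start: float,
    end: float,
    frame: float = SEG_FRAME,
    hop: float = SEG_HOP,
) -> float:
    """Center time of the maximal short-time-RMS frame inside [start, end].

    Ties break to the earliest frame, which keeps the result deterministic
    for constant-amplitude vowels.
    """
    i0 = int(round(start * fs))
    i1 = int(round(end * fs))
    i0 = max(i0, 0)
    i1 = min(i1, len(x))
    seg = x[i0:i1]
    if len(seg) < int(round(frame * fs)):
        raise DegenerateSegmentError(
            f"segment of {len(seg) / fs:.4f}s shorter than the {frame}s analysis frame"
        )
    rms, centers = _frame_rms(seg, fs, frame, hop)
    return start + centers[int(np.argmax(rms))]


def _window(x: np.ndarray, fs: float, center: float, half_window: float) -> np.ndarray:
    i0 = int(round((center - half_window) * fs))
    i1 = int(round((center + half_window) * fs))
    if i0 < 0 or i1 > len(x):
        raise WindowError(
            f"window [{center - half_window:.3f}, {center + half_window:.3f}]s "
            f"outside waveform of {len(x) / fs:.3f}s"
        )
    return x[i0:i1]


def extract_f0(
    x: np.ndarray,
    fs: float,
    center: float,
    half_window: float = HALF_WINDOW,
    search_range: tuple[float, float] = F0_SEARCH,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> float | None:
    """Autocorrelation F0 over the +/- ``half_window`` window around ``center``.

    Returns None (unvoiced) when the peak normalized autocorrelation in the
    candidate lag range falls below ``voicing_threshold``.
    """
    w = _window(x, fs, center, half_window).astype(float)
    w = w - w.mean()
    if not np.any(w):
        return None
    r = signal.correlate(w, w, mode="full")[len(w) - 1:]
    lag_lo = int(np.floor(fs / search_range[1]))
    lag_hi = min(int(np.ceil(fs / search_range[0])), len(r) - 2)
    if lag_lo < 1 or lag_lo >= lag_hi:
        return None
    i = int(np.argmax(r[lag_lo:lag_hi + 1])) + lag_lo
    if r[0] <= 0 or r[i] / r[0] < voicing_threshold:
        return None
    a, b, c = r[i - 1], r[i], r[i + 1]
    denom = a - 2 * b + c
    delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
    lag = i + float(np.clip(delta, -0.5, 0.5))
    f0 = fs / lag
    if not search_range[0] <= f0 <= search_range[1]:
        return None
    return float(f0)


def _lpc_burg(x: np.ndarray, order: int) -> np.ndarray:
    """Burg-method LPC coefficients [1, a1..ap]."""
    f = x.astype(float).copy()
    b = x.astype(float).copy()
    a = np.array([1.0])
    for _ in range(order):
        f_, b_ = f[1:], b[:-1]
        den = np.dot(f_, f_) + np.dot(b_, b_)
        k = -2.0 * np.dot(f_, b_) / den if den > 0 else 0.0
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([[0.0], a[::-1]])
        f, b = f_ + k * b_, b_ + k * f_
    return a


def _lpc_candidates(w: np.ndarray, fs: float) -> list[tuple[float, float]]:
    """Formant candidates (freq, bandwidth) from pre-emphasized windowed LPC."""
    # decimate to the LPC analysis rate
    if fs == 44100:
        xd, fsd = signal.resample_poly(w, 100, 441), 10000.0
    else:
        dec = max(int(round(fs / LPC_RATE)), 1)
        xd, fsd = (signal.decimate(w, dec), fs / dec) if dec > 1 else (w.copy(), fs)
    xd = np.append(xd[0], xd[1:] - PREEMPHASIS * xd[:-1])
    xd = xd * np.hanning(len(xd))
    order = 2 + int(round(fsd / 1000.0))
    a = _lpc_burg(xd, order)
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) / (2.0 * np.pi) * fsd
    bws = -fsd / np.pi * np.log(np.maximum(np.abs(roots), 1e-12))
    return sorted((f, b) for f, b in zip(freqs, bws) if b < BANDWIDTH_CEILING and f > 50.0)


def _harmonic_amplitudes(
    w: np.ndarray, fs: float, f0: float, fmax: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-harmonic peak amplitudes from a zero-padded Hann spectrum."""
    n_fft = int(2 ** np.ceil(np.log2(len(w) * 16)))
    spec = np.abs(np.fft.rfft(w * np.hanning(len(w)), n_fft))
    fax = np.fft.rfftfreq(n_fft, 1.0 / fs)
    freqs, amps = [], []
    k = 1
    while k * f0 < fmax:
        sel = (fax > k * f0 - f0 / 3.0) & (fax < k * f0 + f0 / 3.0)
        if not np.any(sel):
            break
        idx = int(np.argmax(spec[sel])) + int(np.flatnonzero(sel)[0])
        freqs.append(fax[idx])
        amps.append(spec[idx])
        k += 1
    return np.array(freqs), np.array(amps)


def _resonance_logmag(f: np.ndarray, fc: float, bw: float) -> np.ndarray:
    """Log magnitude of a single conjugate-pole resonance (continuous form)."""
    return -0.5 * np.log(((f - fc) ** 2 + (bw / 2) ** 2) * ((f + fc) ** 2 + (bw / 2) ** 2))


def _refine_f1(
    w: np.ndarray,
    fs: float,
    f1_init: float,
    b1_init: float,
    f0: float,
    f1_range: tuple[float, float],
) -> float | None:
    """Fit tilt + F1 resonance + higher-pole skirt to harmonic amplitudes.

    The source spectrum is flattened by a +6 dB/oct correction; the fitted
    model is ``c0 + c1 f + logmag(F1, B1) + 2 logmag(Fh, 150)`` over
    harmonics below min(1.8 kHz, max(3 F1, F1 + 4 F0)).
    """
    fmax = min(REFINE_BAND_CAP, max(3.0 * f1_init, f1_init + 4.0 * f0))
    f, amps = _harmonic_amplitudes(w, fs, f0, fmax)
    if len(f) < 4:
        return None
    la = np.log(np.maximum(amps, 1e-15)) + np.log(f)
    basis = np.vstack([np.ones_like(f), f / 1000.0]).T

    def residuals(p):
        fc, log_bw, fh = p
        r = la - _resonance_logmag(f, fc, np.exp(log_bw)) \
            - 2.0 * _resonance_logmag(f, fh, SKIRT_BANDWIDTH)
        coef, *_ = np.linalg.lstsq(basis, r, rcond=None)
        return r - basis @ coef

    lo = [f1_range[0], np.log(20.0), 1400.0]
    hi = [f1_range[1], np.log(500.0), 4000.0]
    p0 = [float(np.clip(f1_init, *f1_range)), np.log(np.clip(b1_init, 50.0, 300.0)), 2300.0]
    try:
        fit = optimize.least_squares(residuals, p0, bounds=(lo, hi))
    except Exception:
        return None
    return float(fit.x[0]) if fit.success or fit.status > 0 else None


def extract_f1(
    x: np.ndarray,
    fs: float,
    center: float,
    half_window: float = HALF_WINDOW,
    f1_range: tuple[float, float] = F1_RANGE,
    refine: bool = True,
) -> float | None:
    """First-formant frequency over the window around ``center``.

    LPC (Burg, pre-emphasis, Hann window, order 2 + rate/1000 at 10 kHz)
    provides candidate resonances; candidates with bandwidth above the
    ceiling are discarded and the lowest candidate inside ``f1_range`` is
    selected.  When the window is voiced, the candidate is refined against
    the measured harmonic amplitudes (see module docstring); set
    ``refine=False`` for the raw LPC estimate.  Returns None when no
    candidate qualifies.
    """
    w = _window(x, fs, center, half_window).astype(float)
    if not np.any(w):
        return None
    cands = [c for c in _lpc_candidates(w, fs) if f1_range[0] <= c[0] <= f1_range[1]]
    if not cands:
        return None
    f1_lpc, b1_lpc = cands[0]
    if not refine:
        return float(f1_lpc)
    f0 = extract_f0(x, fs, center, half_window)
    if f0 is None:
        return float(f1_lpc)
    refined = _refine_f1(w, fs, f1_lpc, b1_lpc, f0, f1_range)
    return float(refined) if refined is not None else float(f1_lpc)


@dataclass
class ExclusionReport:
    """Per-subject error accounting with the participant error limit."""

    error_limit: float = ERROR_LIMIT
    per_subject: dict[str, dict] = field(default_factory=dict)

    @property
    def excluded_subjects(self) -> list[str]:
        return sorted(s for s, d in self.per_subject.items() if d["error_fraction"] > self.error_limit)

    def to_json(self) -> str:
        return json.dumps(
            {
                "error_limit": self.error_limit,
                "excluded_subjects": self.excluded_subjects,
                "per_subject": self.per_subject,
            },
            indent=2,
        )


def measure_corpus(
    trials: pd.DataFrame,
    audio: "dict[str, np.ndarray] | str | Path",
    sample_rate: int = 44100,
    error_limit: float = ERROR_LIMIT,
    segment_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Measure every spoken trial of a corpus.

    Parameters
    ----------
    trials : DataFrame
        Trial table (schema of :mod:`phonconv.simulate`).
    audio : mapping path -> waveform, or a directory containing the WAV files.

    Returns
    -------
    (measurements, report)
        ``measurements`` has one row per spoken-or-omitted trial with columns
        experiment, subject_id, trial_index, seg_start, seg_end, peak_time,
        f0_hz, f1_hz, valid, invalid_reason.  ``report`` carries per-subject
        error fractions and flags subjects above ``error_limit``.
    """
    from .audio_io import read_wav

    seg_kwargs = segment_kwargs or {}
    rows = []
    for t in trials.itertuples():
        if t.response_kind == KEY_PRESS_KIND:
            continue
        rec = {
            "experiment": t.experiment,
            "subject_id": t.subject_id,
            "trial_index": t.trial_index,
            "seg_start": np.nan,
            "seg_end": np.nan,
            "peak_time": np.nan,
            "f0_hz": np.nan,
            "f1_hz": np.nan,
            "valid": False,
            "invalid_reason": "none",
        }
        if t.response_kind == OMISSION_KIND:
            rec["invalid_reason"] = "omission"
            rows.append(rec)
            continue
        if isinstance(audio, (str, Path)):
            path = Path(audio) / t.audio_path
            if not path.exists():
                raise FileNotFoundError(
                    f"missing audio for trial {t.experiment}/{t.subject_id}/{t.trial_index}: {path}"
                )
            wave, fs = read_wav(path)
        else:
            if t.audio_path not in audio:
                raise FileNotFoundError(
                    f"missing audio for trial {t.experiment}/{t.subject_id}/{t.trial_index}"
                )
            wave, fs = audio[t.audio_path], sample_rate
        segments = segment_utterance(wave, fs, **seg_kwargs)
        if not segments:
            rec["invalid_reason"] = "no_segment"
            rows.append(rec)
            continue
        seg = max(segments, key=lambda s: s.end - s.start)
        rec["seg_start"], rec["seg_end"], rec["peak_time"] = seg.start, seg.end, seg.peak_time
        # clip the measurement window to the segment (rarely binding for
        # steady 250 ms vowels)
        half = min(HALF_WINDOW, seg.peak_time - seg.start, seg.end - seg.peak_time)
        f0 = extract_f0(wave, fs, seg.peak_time, half_window=half)
        if f0 is None:
            rec["invalid_reason"] = "unvoiced"
            rows.append(rec)
            continue
        f1 = extract_f1(wave, fs, seg.peak_time, half_window=half)
        if f1 is None:
            rec["invalid_reason"] = "formant_failure"
            rows.append(rec)
            continue
        rec.update(f0_hz=f0, f1_hz=f1, valid=True)
        rows.append(rec)

    measurements = pd.DataFrame(rows)
    report = ExclusionReport(error_limit=error_limit)
    for (exp, subj), grp in measurements.groupby(["experiment", "subject_id"]):
        n = len(grp)
        n_err = int((~grp["valid"]).sum())
        report.per_subject[subj] = {
            "experiment": exp,
            "n_trials": n,
            "n_errors": n_err,
            "error_fraction": n_err / n if n else 0.0,
        }
    return measurements, report


def measurements_from_simulation(trials: pd.DataFrame) -> pd.DataFrame:
    """Oracle measurements taken directly from the generator's Hz values.

    This bypasses audio rendering and the estimation chain: the measured
    (F0, F1) equal the simulated production values.  It is the reference path
    for parameter-recovery studies, where estimation error would otherwise
    confound the recovery of behavioral gains.
    """
    spoken_or_missing = trials[trials["response_kind"] != KEY_PRESS_KIND]
    out = pd.DataFrame(
        {
            "experiment": spoken_or_missing["experiment"],
            "subject_id": spoken_or_missing["subject_id"],
            "trial_index": spoken_or_missing["trial_index"],
            "seg_start": np.nan,
            "seg_end": np.nan,
            "peak_time": np.nan,
            "f0_hz": spoken_or_missing["sim_f0_hz"],
            "f1_hz": spoken_or_missing["sim_f1_hz"],
            "valid": spoken_or_missing["response_kind"] == SPOKEN_KIND,
            "invalid_reason": np.where(
                spoken_or_missing["response_kind"] == SPOKEN_KIND, "none", "omission"
            ),
        }
    )
    return out.reset_index(drop=True)


# local aliases to avoid importing simulate (cycle)
SPOKEN_KIND = "spoken"
KEY_PRESS_KIND = "key_press"
OMISSION_KIND = "omission"
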