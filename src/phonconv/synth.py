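"""Source-filter vowel synthesis.

Steady vowels are generated as a band-limited sawtooth glottal source at F0
passed through a cascade of second-order all-pole resonators (one per
formant), then scaled to a target level.  The output is deterministic given
its arguments, which makes synthesized corpora byte-reproducible.

The level convention follows digital audio practice: ``level`` is dB relative
to a configurable full-scale reference, with a full-scale sine defined as
``FULL_SCALE_SINE_DB`` (96 dB by default).  The conventional "75 dB" stimulus
scaling therefore lands 21 dB below full scale.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal

from .targets import VOWELS, SpeakerTarget

#: dB value assigned to a full-scale (amplitude 1.0) sine.
FULL_SCALE_SINE_DB = 96.0

#: Vowel-typical higher formants (F2, F3) in Hz.  Only F0/F1 vary per speaker;
#: fixed higher formants give the spectrum a realistic shape for LPC analysis.
VOWEL_F23: Mapping[str, tuple[float, float]] = {
    "i": (2300.0, 3000.0),
    "e": (2100.0, 2800.0),
    "E": (1900.0, 2600.0),
}

#: Default formant bandwidths (F1, F2, F3) in Hz — typical adult values.
FORMANT_BANDWIDTHS = (60.0, 90.0, 120.0)

#: Band-limit of the sawtooth source as a fraction of Nyquist.
SOURCE_BANDLIMIT = 0.9

#: Onset/offset raised-cosine ramps (s).  Natural vowels have gradual
#: attacks; without the ramp the resonators' ring-up transient can carry the
#: intensity peak, dragging the measurement window onto the vowel edge.
ONSET_RAMP = 0.020
OFFSET_RAMP = 0.010


class SynthesisError(ValueError):
    """Invalid synthesis parameters."""


def _resonator_coeffs(fc: float, bw: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Second-order all-pole resonator normalized to unit gain at ``fc``."""
    r = np.exp(-np.pi * bw / fs)
    theta = 2.0 * np.pi * fc / fs
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    _, h = signal.freqz([1.0], a, worN=[theta], fs=2.0 * np.pi)
    return np.array([1.0 / abs(h[0])]), a


def db_to_rms(level_db: float) -> float:
    """Target RMS for a level in dB under the full-scale-sine convention."""
    return (1.0 / np.sqrt(2.0)) * 10.0 ** ((level_db - FULL_SCALE_SINE_DB) / 20.0)


def synthesize_vowel(
    f0: float,
    formants: Sequence[tuple[float, float]],
    duration: float = 0.25,
    sample_rate: float = 44100.0,
    level: float = 75.0,
) -> np.ndarray:
    """Synthesize a steady vowel.

    Parameters
    ----------
    f0 : float
        Fundamental frequency in Hz, ``0 < f0 < formants[0][0]``.
    formants : sequence of (center_hz, bandwidth_hz)
        Resonances in ascending center-frequency order.
    duration : float
        Signal duration in seconds (> 0).
    sample_rate : float
        Sampling rate in Hz; must be at least twice the highest formant.
    level : float
        Output level in dB (see module docstring for the reference).

    Returns
    -------
    ndarray
        Mono float waveform of ``round(duration * sample_rate)`` samples.
    """
    if duration <= 0:
        raise SynthesisError("duration must be positive")
    if f0 <= 0:
        raise SynthesisError("f0 must be positive")
    centers = [fc for fc, _ in formants]
    if sorted(centers) != list(centers):
        raise SynthesisError("formants must be sorted by ascending center frequency")
    if formants and f0 >= centers[0]:
        raise SynthesisError(f"f0 {f0} Hz must lie below the first formant {centers[0]} Hz")
    if formants and sample_rate < 2.0 * max(centers):
        raise SynthesisError(
            f"sample rate {sample_rate} Hz aliases the highest formant {max(centers)} Hz"
        )

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    n_harm = int(np.floor(SOURCE_BANDLIMIT * (sample_rate / 2.0) / f0))
    n_harm = max(n_harm, 1)
    # Band-limited sawtooth: sum of harmonics with 1/k amplitudes.
    k = np.arange(1, n_harm + 1)
    x = (np.sin(2.0 * np.pi * np.outer(t, k * f0)) / k).sum(axis=1)

    for fc, bw in formants:
        b, a = _resonator_coeffs(fc, bw, sample_rate)
        x = signal.lfilter(b, a, x)

    n_on = min(int(round(ONSET_RAMP * sample_rate)), n // 2)
    n_off = min(int(round(OFFSET_RAMP * sample_rate)), n // 2)
    if n_on:
        x[:n_on] *= 0.5 * (1.0 - np.cos(np.pi * np.arange(n_on) / n_on))
    if n_off:
        x[-n_off:] *= 0.5 * (1.0 + np.cos(np.pi * np.arange(n_off) / n_off))

    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = x * (db_to_rms(level) / rms)
    peak = np.max(np.abs(x))
    if peak > 0.99:  # headroom guard for 16-bit export
        x = x * (0.99 / peak)
    return x


def target_formants(target: SpeakerTarget) -> list[tuple[float, float]]:
    """Formant list (F1 from the bank; vowel-typical F2/F3) for a target."""
    f2, f3 = VOWEL_F23[target.vowel]
    b1, b2, b3 = FORMANT_BANDWIDTHS
    return [(target.f1, b1), (f2, b2), (f3, b3)]


def make_target_stimuli(
    target_bank: Iterable[SpeakerTarget],
    sample_rate: float = 44100.0,
    duration: float = 0.25,
    level: float = 75.0,
) -> dict[tuple[str, str], np.ndarray]:
    """Synthesize the whole stimulus bank.

    Returns a map ``(speaker_id, vowel) -> waveform``.  The bank must be
    complete: every speaker present must carry all three vowels.
    """
    bank = list(target_bank)
    by_speaker: dict[str, set[str]] = {}
    for tgt in bank:
        by_speaker.setdefault(tgt.speaker_id, set()).add(tgt.vowel)
    for spk, vs in by_speaker.items():
        missing = set(VOWELS) - vs
        if missing:
            raise SynthesisError(f"speaker {spk} missing vowels {sorted(missing)}")

    out = {}
    for tgt in bank:
        out[(tgt.speaker_id, tgt.vowel)] = synthesize_vowel(
            tgt.f0, target_formants(tgt), duration=duration, sample_rate=sample_rate,
            level=level,
        )
    return out
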