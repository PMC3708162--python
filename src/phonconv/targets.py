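"""Model-speaker target bank: six speakers x three French front unrounded vowels.

The bank holds the acoustic characterization of the recorded model speakers
used as acoustic targets: per speaker and vowel, the fundamental frequency F0
and first formant F1 in Hz. Three speakers are female (S1-S3) and three male
(S4-S6); they were chosen to span largely distinct F0 ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

#: Vowel labels in X-SAMPA: "i" = /i/, "e" = /e/, "E" = /ɛ/.
VOWELS = ("i", "e", "E")

FEMALE = "female"
MALE = "male"


@dataclass(frozen=True)
class SpeakerTarget:
    """One model-speaker vowel target.

    Attributes
    ----------
    speaker_id : str
        "S1".."S6".
    gender : str
        "female" or "male".
    vowel : str
        One of :data:`VOWELS`.
    f0 : float
        Fundamental frequency in Hz.
    f1 : float
        First formant frequency in Hz.
    """

    speaker_id: str
    gender: str
    vowel: str
    f0: float
    f1: float

    def __post_init__(self) -> None:
        if not 75 <= self.f0 <= 400:
            raise ValueError(f"f0 {self.f0} Hz outside plausible range [75, 400]")
        if not 200 <= self.f1 <= 800:
            raise ValueError(f"f1 {self.f1} Hz outside plausible range [200, 800]")
        if self.gender not in (FEMALE, MALE):
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.vowel not in VOWELS:
            raise ValueError(f"unknown vowel {self.vowel!r}")


def _bank() -> tuple[SpeakerTarget, ...]:
    rows = [
        # speaker, gender, vowel, f0, f1
        ("S1", FEMALE, "i", 210, 285),
        ("S2", FEMALE, "i", 251, 269),
        ("S3", FEMALE, "i", 288, 301),
        ("S1", FEMALE, "e", 190, 389),
        ("S2", FEMALE, "e", 248, 399),
        ("S3", FEMALE, "e", 290, 453),
        ("S1", FEMALE, "E", 187, 693),
        ("S2", FEMALE, "E", 249, 577),
        ("S3", FEMALE, "E", 284, 668),
        ("S4", MALE, "i", 137, 278),
        ("S5", MALE, "i", 120, 248),
        ("S6", MALE, "i", 103, 247),
        ("S4", MALE, "e", 139, 390),
        ("S5", MALE, "e", 120, 324),
        ("S6", MALE, "e", 98, 228),
        ("S4", MALE, "E", 132, 510),
        ("S5", MALE, "E", 121, 440),
        ("S6", MALE, "E", 100, 538),
    ]
    return tuple(SpeakerTarget(s, g, v, float(f0), float(f1)) for s, g, v, f0, f1 in rows)


#: The default target bank (6 speakers x 3 vowels).
TARGET_BANK: tuple[SpeakerTarget, ...] = _bank()

FEMALE_SPEAKERS = ("S1", "S2", "S3")
MALE_SPEAKERS = ("S4", "S5", "S6")


def get_target(bank: Iterable[SpeakerTarget], speaker_id: str, vowel: str) -> SpeakerTarget:
    """Look up one (speaker, vowel) entry; raise ``KeyError`` if absent."""
    for t in bank:
        if t.speaker_id == speaker_id and t.vowel == vowel:
            return t
    raise KeyError(f"no target for speaker {speaker_id!r}, vowel {vowel!r}")


def bank_frame(bank: Iterable[SpeakerTarget] = TARGET_BANK) -> pd.DataFrame:
    """Target bank as a DataFrame (speaker_id, gender, vowel, f0_hz, f1_hz)."""
    return pd.DataFrame(
        [
            {
                "speaker_id": t.speaker_id,
                "gender": t.gender,
                "vowel": t.vowel,
                "f0_hz": t.f0,
                "f1_hz": t.f1,
            }
            for t in bank
        ]
    )


def bank_from_frame(df: pd.DataFrame) -> tuple[SpeakerTarget, ...]:
    """Inverse of :func:`bank_frame` (e.g. for a user-supplied target CSV)."""
    return tuple(
        SpeakerTarget(r.speaker_id, r.gender, r.vowel, float(r.f0_hz), float(r.f1_hz))
        for r in df.itertuples()
    )


def validate_bank(bank: Iterable[SpeakerTarget]) -> None:
    """Check completeness (6 speakers x 3 vowels) and gender F0 separation.

    Female speakers must have higher F0 than every male speaker for each vowel,
    which holds for the default bank and is assumed by the congruency design.
    """
    bank = list(bank)
    speakers = sorted({t.speaker_id for t in bank})
    for s in speakers:
        vs = sorted(t.vowel for t in bank if t.speaker_id == s)
        if vs != sorted(VOWELS):
            raise ValueError(f"speaker {s} does not have exactly one entry per vowel")
    for v in VOWELS:
        female_f0 = [t.f0 for t in bank if t.vowel == v and t.gender == FEMALE]
        male_f0 = [t.f0 for t in bank if t.vowel == v and t.gender == MALE]
        if female_f0 and male_f0 and min(female_f0) <= max(male_f0):
            raise ValueError(f"female/male F0 ranges overlap for vowel {v!r}")


def mean_f1_by_gender(bank: Iterable[SpeakerTarget] = TARGET_BANK) -> pd.DataFrame:
    """Cross-speaker mean F1 per (gender, vowel), in Hz."""
    df = bank_frame(bank)
    return df.groupby(["gender", "vowel"], sort=False)["f1_hz"].mean().reset_index()


def mean_f0_by_speaker(bank: Iterable[SpeakerTarget] = TARGET_BANK) -> pd.Series:
    """Mean F0 across vowels per speaker, in Hz."""
    df = bank_frame(bank)
    return df.groupby("speaker_id")["f0_hz"].mean()
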