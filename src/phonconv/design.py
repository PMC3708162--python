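"""Experimental design: blocks, sub-blocks, counterbalancing, trial counts.

Each experiment runs three blocks, one model speaker per block.  A block is
a run of three sub-blocks: orthographic cues (baseline), acoustic cues
(exposure), orthographic cues again (post-exposure).  The post-exposure
orthographic sub-block of block k is shared with block k+1, where it serves
as that block's baseline — it is produced and stored once.

Sub-block storage layout per subject (roles as stored):

    O0 (baseline_ortho, block 1) | A1 (acoustic, block 1) | O1 (post_ortho, block 1)
    | A2 (acoustic, block 2) | O2 (post_ortho, block 2)
    | A3 (acoustic, block 3) | O3 (post_ortho, block 3)

The analysis layer re-reads O1 as the baseline of block 2 and O2 as the
baseline of block 3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .targets import FEMALE, FEMALE_SPEAKERS, MALE, MALE_SPEAKERS, VOWELS

PRODUCTION = "production"
IMITATION = "imitation"
CATEGORIZATION = "categorization"
TASKS = (PRODUCTION, IMITATION, CATEGORIZATION)

BASELINE_ORTHO = "baseline_ortho"
ACOUSTIC = "acoustic"
POST_ORTHO = "post_ortho"

ORTHOGRAPHIC_CUE = "orthographic"
ACOUSTIC_CUE = "acoustic"

SAME = "same"
DIFFERENT = "different"

#: Mean per-participant error percentages observed per task, used as the
#: generator's default omission rates.
DEFAULT_ERROR_RATES = {PRODUCTION: 0.028, IMITATION: 0.012, CATEGORIZATION: 0.012}


@dataclass(frozen=True)
class ExperimentDesign:
    """Design parameters of one experiment (one task, one subject group)."""

    task: str
    n_subjects: int = 24
    n_blocks: int = 3
    ortho_repeats: int = 5     # per vowel per orthographic sub-block
    acoustic_repeats: int = 10  # per vowel per acoustic sub-block
    share_boundary_subblock: bool = True
    error_rate: float | None = None  # None -> task default

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_subjects % 4 != 0:
            raise ValueError("n_subjects must be divisible by 4 for counterbalancing")

    @property
    def effective_error_rate(self) -> float:
        return DEFAULT_ERROR_RATES[self.task] if self.error_rate is None else self.error_rate

    @property
    def ortho_subblock_size(self) -> int:
        return len(VOWELS) * self.ortho_repeats

    @property
    def acoustic_subblock_size(self) -> int:
        return len(VOWELS) * self.acoustic_repeats

    def n_ortho_subblocks(self) -> int:
        if self.share_boundary_subblock:
            return self.n_blocks + 1
        return 2 * self.n_blocks

    def spoken_per_subject(self) -> int:
        """Closed-form spoken-utterance count for one subject."""
        ortho = self.n_ortho_subblocks() * self.ortho_subblock_size
        acoustic = self.n_blocks * self.acoustic_subblock_size
        if self.task == CATEGORIZATION:
            return ortho  # acoustic trials are key presses
        return ortho + acoustic

    def keypress_per_subject(self) -> int:
        if self.task == CATEGORIZATION:
            return self.n_blocks * self.acoustic_subblock_size
        return 0

    def spoken_total(self) -> int:
        return self.n_subjects * self.spoken_per_subject()


def full_study_designs() -> tuple[ExperimentDesign, ExperimentDesign, ExperimentDesign]:
    """The complete three-experiment design: 3 tasks x 24 subjects."""
    return tuple(ExperimentDesign(task) for task in TASKS)


@dataclass(frozen=True)
class SubjectAssignment:
    """Counterbalancing slot of one subject within an experiment."""

    subject_id: str
    gender: str
    speaker_set: str                 # gender of the model speakers heard
    block_speakers: tuple[str, ...]  # speaker per block, a permutation
    congruency: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "congruency", SAME if self.gender == self.speaker_set else DIFFERENT
        )


def subject_assignments(design: ExperimentDesign) -> list[SubjectAssignment]:
    """Assign gender, speaker set, and block order to each subject.

    The four gender x speaker-set cells each hold ``n_subjects / 4`` subjects;
    block orders cycle through all 3! speaker permutations within each cell, so
    with 24 subjects each cell of six sees every permutation exactly once.
    """
    prefix = design.task[0].upper()
    per_cell = design.n_subjects // 4
    cells = [
        (FEMALE, FEMALE), (FEMALE, MALE), (MALE, FEMALE), (MALE, MALE),
    ]
    out: list[SubjectAssignment] = []
    idx = 0
    for gender, speaker_set in cells:
        speakers = FEMALE_SPEAKERS if speaker_set == FEMALE else MALE_SPEAKERS
        perms = list(itertools.permutations(speakers))
        for j in range(per_cell):
            idx += 1
            out.append(
                SubjectAssignment(
                    subject_id=f"{prefix}{idx:02d}",
                    gender=gender,
                    speaker_set=speaker_set,
                    block_speakers=perms[j % len(perms)],
                )
            )
    return out


@dataclass(frozen=True)
class SubBlockSpec:
    """One stored sub-block: its block, role, cue, and repeat count."""

    block_index: int
    role: str    # baseline_ortho | acoustic | post_ortho (storage role)
    cue: str     # orthographic | acoustic
    repeats: int


def subblock_sequence(design: ExperimentDesign) -> list[SubBlockSpec]:
    """Stored sub-blocks of one subject, in presentation order."""
    seq: list[SubBlockSpec] = []
    for k in range(1, design.n_blocks + 1):
        if k == 1 or not design.share_boundary_subblock:
            seq.append(SubBlockSpec(k, BASELINE_ORTHO, ORTHOGRAPHIC_CUE, design.ortho_repeats))
        seq.append(SubBlockSpec(k, ACOUSTIC, ACOUSTIC_CUE, design.acoustic_repeats))
        seq.append(SubBlockSpec(k, POST_ORTHO, ORTHOGRAPHIC_CUE, design.ortho_repeats))
    return seq
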