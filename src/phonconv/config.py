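"""Run configuration: one dataclass, YAML round-trip, snapshot per run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from . import bark
from .design import TASKS

ORACLE = "oracle"   # measurements taken from the generator's Hz values
AUDIO = "audio"     # measurements re-estimated from rendered WAV audio


@dataclass
class RunConfig:
    """Every tunable of a pipeline run, with defaults reproducing the full
    three-experiment study design."""

    seed: int = 0
    outdir: str = "runs/default"
    bark_variant: str = bark.AS_PRINTED

    # design
    tasks: tuple[str, ...] = TASKS
    n_subjects: int = 24
    error_rate: float | None = None    # None -> per-task defaults

    # behavioral generator
    noise_sd_f0: float = 0.004         # bark (generation/analysis space)
    noise_sd_f1: float = 0.012
    gain_converge: float | None = None  # None -> per-task defaults
    gain_after: float | None = None
    gain_sd: float | None = None

    # synthesis
    sample_rate: int = 44100
    duration: float = 0.25
    level_db: float = 75.0
    render_audio: bool = False

    # measurement
    measurement_mode: str = ORACLE

    # analysis
    outlier_k: float = 2.0
    min_valid_trials: int = 2
    ss_type: int = 2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.bark_variant not in bark.VARIANTS:
            raise ValueError(f"unknown bark variant {self.bark_variant!r}")
        if self.measurement_mode not in (ORACLE, AUDIO):
            raise ValueError(f"unknown measurement mode {self.measurement_mode!r}")
        self.tasks = tuple(self.tasks)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = asdict(self)
        d["tasks"] = list(d["tasks"])
        path.write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
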