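"""WAV file I/O (PCM 16-bit mono) on top of scipy.io.wavfile."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile


def write_wav(path: str | Path, x: np.ndarray, sample_rate: int) -> None:
    """Write a float waveform in [-1, 1] as 16-bit PCM mono."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clipped = np.clip(np.asarray(x, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(sample_rate), (clipped * 32767.0).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file as a float mono waveform in [-1, 1] plus sample rate."""
    sr, data = wavfile.read(Path(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(np.int16).max)
    else:
        data = data.astype(float)
    return data, int(sr)
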