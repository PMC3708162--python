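"""Bark frequency scaling.

Two variants of the critical-band (bark) transform are provided:

``as_printed``
    ``bark(f) = arctan(0.00076 f) + 3.5 arctan((f / 7500)^2)``.
    This is the expression as printed in the source analysis; note it lacks
    the factor 13 on the first term that the Zwicker & Fastl formulation
    carries, so its output is roughly 13x smaller over the speech range.

``zwicker_standard``
    ``bark(f) = 13 arctan(0.00076 f) + 3.5 arctan((f / 7500)^2)``, the
    conventional Zwicker & Fastl approximation.

Both are strictly increasing with ``bark(0) = 0``, so either defines a valid
analysis space; slope metrics computed uniformly in one space estimate the
generative gain defined in that same space.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

AS_PRINTED = "as_printed"
ZWICKER_STANDARD = "zwicker_standard"
VARIANTS = (AS_PRINTED, ZWICKER_STANDARD)


def hz_to_bark(f, variant: str = AS_PRINTED):
    """Convert frequency in Hz to bark.

    Parameters
    ----------
    f : float or array_like
        Frequency in Hz, must be >= 0.
    variant : {"as_printed", "zwicker_standard"}

    Returns
    -------
    float or ndarray
    """
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative frequency")
    if variant == AS_PRINTED:
        c1 = 1.0
    elif variant == ZWICKER_STANDARD:
        c1 = 13.0
    else:
        raise ValueError(f"unknown bark variant {variant!r}")
    out = c1 * np.arctan(0.00076 * arr) + 3.5 * np.arctan((arr / 7500.0) ** 2)
    return float(out) if np.isscalar(f) or arr.ndim == 0 else out


def bark_to_hz(b, variant: str = AS_PRINTED):
    """Inverse bark transform by monotone root bracketing.

    Values below ``bark(0) = 0`` are a domain error.
    """
    def inv(one: float) -> float:
        if one < 0:
            raise ValueError("bark value below 0 has no frequency preimage")
        if one == 0:
            return 0.0
        hi = 24000.0
        if hz_to_bark(hi, variant) < one:
            raise ValueError(f"bark value {one} beyond the audible mapping range")
        return brentq(lambda f: hz_to_bark(f, variant) - one, 0.0, hi, xtol=1e-9)

    if np.isscalar(b) or np.asarray(b).ndim == 0:
        return inv(float(b))
    return np.array([inv(float(x)) for x in np.asarray(b, dtype=float).ravel()]).reshape(
        np.asarray(b).shape
    )
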