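"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np

#: Relative tolerance used to break near-ties when locating a response peak.
#: Saturated (amplitude-capped) responses have a flat plateau at their maximum;
#: treating samples within this fraction of the maximum as ties and taking the
#: earliest makes the peak location well defined for noise-free data while
#: being inconsequential for noisy data.
PEAK_TIE_RTOL = 1e-3


def earliest_peak(values: np.ndarray, rtol: float = PEAK_TIE_RTOL) -> int:
    """Index of the earliest sample within ``rtol`` (relative) of the maximum.

    Parameters
    ----------
    values
        1-D array; the maximum must be positive for the relative tolerance to
        be meaningful (callers enforce this via their own validity rules).
    rtol
        Relative tie tolerance. ``0`` reproduces a plain ``argmax`` with
        earliest-wins tie-breaking.
    """
    values = np.asarray(values, dtype=float)
    vmax = np.max(values)
    thresh = vmax - rtol * abs(vmax)
    return int(np.flatnonzero(values >= thresh)[0])


def check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
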