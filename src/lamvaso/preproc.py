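"""Quality control and signal conditioning.

Framewise displacement from rigid motion parameters, run averaging, temporal
upsampling to the stimulus-onset grid, BOLD-contamination correction by
dynamic division (BOCO), and temporal-SNR / 1-over-CV maps.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .io import VolumeSeries

#: Nominal head radius used to convert rotations to arc length (mm).
DEFAULT_HEAD_RADIUS_MM = 50.0

#: Relative magnitude below which a BOLD divisor is considered dead.
BOCO_GUARD_REL = 1e-6


def framewise_displacement(
    trace: np.ndarray, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement (mm) between consecutive volumes.

    FD_t = sum |d translation_i| + r * sum |d rotation_i|, with rotations in
    radians converted to arc length on a sphere of radius ``head_radius_mm``.
    Returns an array of length n-1 (empty for a single volume).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion trace must have shape (n_volumes, 6)")
    if not np.all(np.isfinite(trace)):
        raise ValueError("motion trace contains non-finite values")
    if trace.shape[0] < 2:
        return np.empty(0)
    d = np.diff(trace, axis=0)
    return np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)


def flag_high_motion(fd_series: np.ndarray, threshold_mm: float) -> np.ndarray:
    """Indices of volumes displaced by more than ``threshold_mm``.

    Index i refers to the (i+1)-th volume of the series, i.e. the volume
    displaced with respect to its predecessor.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold must be positive")
    return np.flatnonzero(np.asarray(fd_series) > threshold_mm)


def average_runs(series_list: list[VolumeSeries]) -> VolumeSeries:
    """Voxelwise arithmetic mean of runs with identical grids and contrast."""
    if not series_list:
        raise ValueError("need at least one run")
    first = series_list[0]
    for s in series_list[1:]:
        if s.data.shape != first.data.shape:
            raise ValueError("run shapes differ")
        if s.contrast != first.contrast:
            raise ValueError("contrast tags differ")
        if abs(s.dt_s - first.dt_s) > 1e-12:
            raise ValueError("sampling intervals differ")
    mean = np.mean([s.data for s in series_list], axis=0)
    return first.with_data(mean)


def upsample_temporal(
    series: VolumeSeries, factor: int = 4, kind: str = "linear"
) -> VolumeSeries:
    """Temporally upsample by an integer factor.

    Original samples are preserved at stride ``factor``; values between are
    interpolated (``kind``: "linear" or "cubic"); the tail beyond the last
    original sample is held at the edge value.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return series
    n = series.n_volumes
    t_old = np.arange(n, dtype=float)
    t_new = np.arange(n * factor, dtype=float) / factor
    t_eval = np.clip(t_new, 0.0, n - 1.0)  # edge-hold extrapolation
    data = series.data
    if kind == "linear":
        flat = data.reshape(-1, n)
        out = np.empty((flat.shape[0], n * factor), dtype=float)
        for i in range(flat.shape[0]):
            out[i] = np.interp(t_eval, t_old, flat[i])
        out = out.reshape(data.shape[:-1] + (n * factor,))
    elif kind == "cubic":
        out = CubicSpline(t_old, data, axis=-1)(t_eval)
    else:
        raise ValueError("kind must be 'linear' or 'cubic'")
    return series.with_data(out, dt_s=series.dt_s / factor)


def boco(nulled: VolumeSeries, bold: VolumeSeries) -> VolumeSeries:
    """BOLD-contamination correction: divide nulled by BOLD volume-by-volume.

    Both series must be on the same temporal grid; if the BOLD series is one
    volume short its first volume is duplicated (prepended) to match.  Voxels
    whose BOLD magnitude falls below ``BOCO_GUARD_REL`` times their temporal
    mean magnitude yield NaN rather than infinities.
    """
    b = bold.data
    if b.shape[-1] == nulled.data.shape[-1] - 1:
        b = np.concatenate([b[..., :1], b], axis=-1)
    if b.shape != nulled.data.shape:
        raise ValueError("nulled and BOLD grids do not match")
    guard = BOCO_GUARD_REL * np.mean(np.abs(b), axis=-1, keepdims=True)
    divisor = np.where(np.abs(b) <= guard, np.nan, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = nulled.data / divisor
    return VolumeSeries(ratio, "vaso", nulled.dt_s, nulled.t0_s)


def tsnr(series: VolumeSeries) -> np.ndarray:
    """Temporal SNR map: voxelwise temporal mean over temporal sd.

    Zero-variance voxels are flagged as NaN.
    """
    if series.n_volumes < 2:
        raise ValueError("need at least two volumes")
    mean = series.data.mean(axis=-1)
    sd = series.data.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sd > 0, mean / sd, np.nan)
    return out


def t1w_from_cv(nulled: VolumeSeries, bold: VolumeSeries) -> np.ndarray:
    """T1-weighted image as 1 / coefficient-of-variation of both series.

    Computed voxelwise on the concatenated nulled and BOLD time courses;
    scale-invariant by construction.  Zero-variance voxels yield NaN.
    """
    if nulled.data.shape[:-1] != bold.data.shape[:-1]:
        raise ValueError("nulled and BOLD grids do not match")
    concat = np.concatenate([nulled.data, bold.data], axis=-1)
    mean = concat.mean(axis=-1)
    sd = concat.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sd > 0, mean / sd, np.nan)
    return out
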