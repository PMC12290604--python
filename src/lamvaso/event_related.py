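"""Event-related averaging of jittered trials.

The five analysis steps, in the order they are applied:

1. extract each trial from stimulus onset until the end of its rest period,
   on the temporally upsampled grid;
2. average trials of one stimulus duration onto the effective sampling grid,
   interleaving jitters (each time point averages the trials whose native,
   non-interpolated sample lands on it; sample counts are reported);
3. compute the voxel baseline from the first and final 30 s of each run;
4. convert to percent signal change (100 * signal / baseline) and invert the
   sign for VASO so a CBV increase is positive;
5. stitch the segment covered only by long-ITI runs onto the common segment
   by removing their junction offset, then zero the first time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .acquisition import StimulusDesign, Trial
from .io import VolumeSeries


@dataclass
class TrialWindow:
    """One extracted trial on the upsampled grid.

    ``values`` has time as its last axis, length ``duration + ITI`` in
    samples; samples past the end of the run are NaN (``truncated``).
    ``native_phase`` gives the window sample offset at which the series has
    native (non-interpolated) samples, recurring every ``factor`` samples.
    """

    values: np.ndarray
    duration_s: float
    jitter_index: int
    onset_index: int
    native_phase: int
    factor: int
    truncated: bool = False

    @property
    def n_samples(self) -> int:
        return self.values.shape[-1]

    def native_sample_indices(self) -> np.ndarray:
        return np.arange(self.native_phase, self.n_samples, self.factor)


@dataclass
class EventRelatedAverage:
    """Per-duration average time course on the effective sampling grid."""

    time_s: np.ndarray
    value: np.ndarray  # (..., L)
    n: np.ndarray  # trials contributing per time point
    duration_s: float
    contrast: str
    segment: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U10"))
    zeroed: bool = False

    def __post_init__(self) -> None:
        if self.segment.size == 0:
            self.segment = np.full(self.time_s.shape, "short", dtype="U10")


def extract_trials(
    series: VolumeSeries,
    design: StimulusDesign | list[Trial],
    run: int = 0,
    upsample_factor: int = 4,
) -> list[TrialWindow]:
    """Extract one window per trial, onset through end of the rest period.

    ``series`` must be on the upsampled stimulus-onset grid (sampling
    interval equal to the jitter block).  Trials extending past the end of
    the run are truncated (NaN padded) and flagged.
    """
    trials = design if isinstance(design, list) else design.runs[run]
    dt = series.dt_s
    n = series.n_volumes
    windows = []
    for tr in trials:
        offset = (tr.onset_s - series.t0_s) / dt
        i0 = int(round(offset))
        if abs(offset - i0) > 1e-6:
            raise ValueError(
                f"trial onset {tr.onset_s} s is not on the series grid"
            )
        length = int(round((tr.duration_s + tr.iti_s) / dt))
        i1 = i0 + length
        vals = np.full(series.data.shape[:-1] + (length,), np.nan)
        avail = max(0, min(i1, n) - i0)
        if avail > 0:
            vals[..., :avail] = series.data[..., i0:i0 + avail]
        windows.append(
            TrialWindow(
                values=vals,
                duration_s=tr.duration_s,
                jitter_index=tr.jitter_index,
                onset_index=i0,
                native_phase=(-i0) % upsample_factor,
                factor=upsample_factor,
                truncated=avail < length,
            )
        )
    return windows


def average_trials(
    windows: list[TrialWindow],
    dt_s: float,
    contrast: str,
    interleave: bool = True,
) -> dict[float, EventRelatedAverage]:
    """Average trial windows per stimulus duration.

    With ``interleave=True`` (default) each time point of the average uses
    only the trials whose native sample falls on it, so jittered trials are
    interleaved onto the effective grid without interpolation error; with
    ``interleave=False`` every trial contributes its (possibly interpolated)
    sample at every time point.  Truncated samples contribute only where
    available; ``n`` records the per-time-point trial count.
    """
    if not windows:
        return {}
    out: dict[float, EventRelatedAverage] = {}
    for dur in sorted({w.duration_s for w in windows}):
        group = [w for w in windows if w.duration_s == dur]
        length = max(w.n_samples for w in group)
        lead_shape = group[0].values.shape[:-1]
        acc = np.zeros(lead_shape + (length,))
        cnt = np.zeros(length)
        for w in group:
            use = np.zeros(w.n_samples, dtype=bool)
            if interleave:
                use[w.native_sample_indices()] = True
            else:
                use[:] = True
            valid = use & np.all(np.isfinite(w.values.reshape(-1, w.n_samples)), axis=0)
            acc[..., :w.n_samples][..., valid] += w.values[..., valid]
            cnt[:w.n_samples][valid] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cnt > 0, acc / cnt, np.nan)
        out[dur] = EventRelatedAverage(
            time_s=np.arange(length) * dt_s,
            value=mean,
            n=cnt,
            duration_s=dur,
            contrast=contrast,
        )
    return out


def baseline(run_series_list: list[VolumeSeries], window_s: float = 30.0) -> np.ndarray:
    """Voxelwise baseline: mean of the first and final ``window_s`` of each run."""
    if not run_series_list:
        raise ValueError("need at least one run")
    chunks = []
    for s in run_series_list:
        k = int(window_s / s.dt_s)
        if s.n_volumes < 2 * k:
            raise ValueError("run shorter than twice the baseline window")
        chunks.append(s.data[..., :k])
        chunks.append(s.data[..., -k:])
    return np.concatenate(chunks, axis=-1).mean(axis=-1)


def percent_signal_change(
    era: EventRelatedAverage,
    baseline_map: np.ndarray | float,
    contrast: str | None = None,
) -> EventRelatedAverage:
    """Percent signal change: 100 * signal / baseline; VASO sign-inverted.

    A CBV increase lowers the blood-nulled signal, so VASO signal changes are
    multiplied by -1 for comparability with BOLD.  Non-positive or non-finite
    baseline voxels are excluded (NaN).
    """
    contrast = contrast or era.contrast
    base = np.asarray(baseline_map, dtype=float)
    with np.errstate(invalid="ignore"):
        base = np.where(np.isfinite(base) & (base > 0), base, np.nan)
    value = 100.0 * era.value / base[..., None]
    if contrast == "vaso":
        value = -value
    return replace(era, value=value, contrast=contrast)


def stitch_iti(
    era_short: EventRelatedAverage, era_long: EventRelatedAverage
) -> EventRelatedAverage:
    """Attach the long-ITI-only tail to the short-covered segment.

    The constant offset between the first long-only time point and the last
    short-covered time point is subtracted from the long-only samples, which
    leaves those two time points equal; short-covered samples are untouched.
    """
    ls = era_short.value.shape[-1]
    if era_long.value.shape[-1] <= ls:
        raise ValueError("long-ITI average does not extend past the short one")
    offset = np.asarray(era_long.value[..., ls] - era_short.value[..., ls - 1])
    tail = era_long.value[..., ls:] - offset[..., None]
    value = np.concatenate([era_short.value, tail], axis=-1)
    n = np.concatenate([era_short.n, era_long.n[ls:]])
    segment = np.concatenate(
        [np.full(ls, "short", dtype="U10"),
         np.full(era_long.value.shape[-1] - ls, "long_only", dtype="U10")]
    )
    return EventRelatedAverage(
        time_s=era_long.time_s,
        value=value,
        n=n,
        duration_s=era_short.duration_s,
        contrast=era_short.contrast,
        segment=segment,
    )


def zero_first(era: EventRelatedAverage) -> EventRelatedAverage:
    """Normalize so the first time point is exactly zero."""
    if era.value.shape[-1] == 0:
        raise ValueError("empty event-related average")
    return replace(era, value=era.value - era.value[..., :1], zeroed=True)
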