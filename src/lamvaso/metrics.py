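"""Headline statistics: time to peak and vessel/gray-matter peak ratios."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import PEAK_TIE_RTOL, earliest_peak
from .event_related import EventRelatedAverage


@dataclass(frozen=True)
class TTPResult:
    ttp_s: float
    peak_value_pct: float
    valid: bool


def _peak_span(values: np.ndarray) -> tuple[int, int] | None:
    """Above-zero span: first sample > 0 to the first subsequent sample < 0.

    Returns ``None`` when the series never rises above zero; the span is
    truncated at the end of the series when the signal never falls below
    zero again.
    """
    pos = np.flatnonzero(values > 0)
    if pos.size == 0:
        return None
    i1 = int(pos[0])
    neg = np.flatnonzero(values[i1:] < 0)
    i2 = i1 + int(neg[0]) if neg.size else values.size
    return i1, i2


def time_to_peak(
    era: EventRelatedAverage, tie_rtol: float = PEAK_TIE_RTOL
) -> TTPResult:
    """Time to peak of a zeroed event-related average.

    The peak is the highest signal change between the initial deflection
    above zero and the subsequent fall below zero (end of the window when the
    signal never falls below zero).  Samples within ``tie_rtol`` (relative)
    of the maximum are treated as ties and the earliest wins, which keeps the
    peak location well defined for saturated responses whose maximum is a
    plateau.  Series that never rise above zero are flagged invalid.
    """
    values = np.asarray(era.value, dtype=float)
    if values.ndim != 1:
        raise ValueError("time_to_peak expects a single (1-D) time course")
    span = _peak_span(values)
    if span is None:
        return TTPResult(np.nan, np.nan, False)
    i1, i2 = span
    rel = earliest_peak(values[i1:i2], tie_rtol)
    idx = i1 + rel
    return TTPResult(float(era.time_s[idx]), float(values[i1:i2].max()), True)


def peak_ratio(
    era_vessel: EventRelatedAverage, era_gm: EventRelatedAverage
) -> float:
    """Peak signal change in vessel-dominated voxels over that in gray matter.

    Peaks are located with the same above-zero span rule as the time-to-peak
    metric.  NaN when either peak is missing or the gray-matter peak is not
    positive.
    """
    p_v = time_to_peak(era_vessel)
    p_g = time_to_peak(era_gm)
    if not (p_v.valid and p_g.valid) or p_g.peak_value_pct <= 0:
        return float("nan")
    return p_v.peak_value_pct / p_g.peak_value_pct


def ttp_table(
    eras: dict[tuple[str, str, float], EventRelatedAverage]
) -> pd.DataFrame:
    """TTP/peak table from (contrast, roi, duration) -> ERA mappings."""
    rows = []
    for (contrast, roi, dur), era in sorted(eras.items()):
        res = time_to_peak(era)
        rows.append(
            {
                "contrast": contrast,
                "roi": roi,
                "duration_s": dur,
                "ttp_s": res.ttp_s,
                "peak_pct": res.peak_value_pct,
                "valid": res.valid,
            }
        )
    return pd.DataFrame(rows)


def ratio_table(
    eras: dict[tuple[str, str, float], EventRelatedAverage],
    vessel_roi: str = "vessel",
    gm_roi: str = "gm",
) -> pd.DataFrame:
    """Vessel/GM peak ratio per (contrast, duration)."""
    rows = []
    keys = sorted({(c, d) for (c, r, d) in eras if r == vessel_roi})
    for contrast, dur in keys:
        ratio = peak_ratio(
            eras[(contrast, vessel_roi, dur)], eras[(contrast, gm_roi, dur)]
        )
        rows.append({"contrast": contrast, "duration_s": dur, "ratio": ratio})
    return pd.DataFrame(rows)


def summarize(
    ttp: pd.DataFrame | None = None,
    ratios: pd.DataFrame | None = None,
    fd_series: np.ndarray | None = None,
    tsnr_map: np.ndarray | None = None,
    ground_truth: dict | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Machine-readable report of all QC and result tables.

    Deterministic (sorted keys, no timestamps) so repeated runs on identical
    inputs produce byte-identical JSON.  When ``out_dir`` is given, writes
    ``report.json`` plus TSV copies of the tables.
    """
    report: dict = {}
    if ttp is not None and len(ttp):
        report["ttp"] = ttp.to_dict(orient="records")
    if ratios is not None and len(ratios):
        report["peak_ratios"] = ratios.to_dict(orient="records")
    if fd_series is not None:
        fd = np.asarray(fd_series, dtype=float)
        report["motion"] = {
            "n_pairs": int(fd.size),
            "fd_mean_mm": float(fd.mean()) if fd.size else None,
            "fd_max_mm": float(fd.max()) if fd.size else None,
        }
    if tsnr_map is not None:
        vals = np.asarray(tsnr_map, dtype=float)
        vals = vals[np.isfinite(vals)]
        report["tsnr"] = {
            "median": float(np.median(vals)) if vals.size else None,
            "mean": float(vals.mean()) if vals.size else None,
        }
    if ground_truth is not None:
        report["ground_truth"] = ground_truth
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        if ttp is not None and len(ttp):
            ttp.to_csv(out / "ttp.tsv", sep="\t", index=False)
        if ratios is not None and len(ratios):
            ratios.to_csv(out / "peak_ratios.tsv", sep="\t", index=False)
    return report
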