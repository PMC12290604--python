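"""End-to-end convenience pipelines over the library modules.

These functions wire the stages together the way a participant-level
analysis runs: simulate (or load) interleaved nulled/BOLD runs, average runs,
upsample to the stimulus-onset grid, BOLD-correct, extract ROI time courses,
compute event-related averages in percent signal change, and summarize time
to peak and vessel/GM peak ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import AcquisitionScheme, StimulusDesign, make_design
from .event_related import (
    EventRelatedAverage,
    average_trials,
    baseline,
    extract_trials,
    percent_signal_change,
    zero_first,
)
from .geometry import GeometryLabels, build_geometry
from .io import VolumeSeries
from .metrics import ratio_table, ttp_table
from .preproc import average_runs, boco, upsample_temporal
from .responses import CompartmentModel
from .simulate import COMPARTMENT_CODES, SimulatedRun, simulate_run


@dataclass
class Participant:
    geometry: GeometryLabels
    design: StimulusDesign
    acq: AcquisitionScheme
    model: CompartmentModel
    runs: list[SimulatedRun]


def simulate_participant(
    n_runs: int = 4,
    iti_class: str = "long",
    seed: int = 0,
    model: CompartmentModel | None = None,
    geometry: GeometryLabels | None = None,
    acq: AcquisitionScheme | None = None,
) -> Participant:
    """Simulate one participant: geometry, design, and all runs."""
    acq = acq or AcquisitionScheme()
    geometry = geometry if geometry is not None else build_geometry(seed=seed)
    model = model or CompartmentModel(seed=seed)
    design = make_design(acq, n_runs=n_runs, iti_class=iti_class, seed=seed)
    runs = [
        simulate_run(geometry, design, acq, model, run=r, seed=seed * 1009 + r)
        for r in range(n_runs)
    ]
    return Participant(geometry, design, acq, model, runs)


def default_rois(participant: Participant) -> dict[str, np.ndarray]:
    """Analysis ROIs: whole GM, vessel voxels, and the GM compartments."""
    cmap = participant.runs[0].truth.compartment_map
    rois: dict[str, np.ndarray] = {
        "gm": participant.geometry.gm_mask,
        "vessel": participant.geometry.vessel_mask,
    }
    for name in ("gm_deep", "gm_middle", "gm_superficial"):
        rois[name] = cmap == COMPARTMENT_CODES[name]
    return rois


def roi_course(series: VolumeSeries, mask: np.ndarray) -> VolumeSeries:
    """ROI-mean time course (voxel average at every sample)."""
    data = series.data[mask.astype(bool)].mean(axis=0)
    return VolumeSeries(data, series.contrast, series.dt_s, series.t0_s)


def analyze_participant(
    participant: Participant,
    rois: dict[str, np.ndarray] | None = None,
    upsample_factor: int | None = None,
    interleave: bool = True,
) -> dict:
    """Run-average, upsample, BOLD-correct, and event-average per ROI.

    Returns a dict with ``eras`` keyed by (contrast, roi, duration),
    ``ttp`` and ``ratios`` data frames.
    """
    acq = participant.acq
    design = participant.design
    factor = upsample_factor or acq.n_jitters
    rois = rois or default_rois(participant)

    nulled = average_runs([r.nulled for r in participant.runs])
    bold = average_runs([r.bold for r in participant.runs])
    nulled_up = upsample_temporal(nulled, factor)
    bold_up = upsample_temporal(bold, factor)
    vaso = boco(nulled_up, bold_up)

    eras: dict[tuple[str, str, float], EventRelatedAverage] = {}
    for contrast, series in (("vaso", vaso), ("bold", bold_up)):
        for roi_name, mask in rois.items():
            course = roi_course(series, mask)
            windows = extract_trials(course, design, run=0,
                                     upsample_factor=factor)
            by_dur = average_trials(windows, series.dt_s, contrast,
                                    interleave=interleave)
            base = baseline([course])
            for dur, era in by_dur.items():
                era = percent_signal_change(era, base)
                era = zero_first(era)
                eras[(contrast, roi_name, dur)] = era

    ttp = ttp_table(eras)
    ratios = ratio_table(eras) if "vessel" in rois and "gm" in rois else pd.DataFrame()
    return {"eras": eras, "ttp": ttp, "ratios": ratios, "vaso": vaso}
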