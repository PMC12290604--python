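"""Generative simulator for interleaved blood-nulled / BOLD time series.

Signal model per voxel and acquisition cycle i (compartment c of the voxel):

    S_bold(i)   = S0 * (1 + delta_c(t_bold,i))
    S_nulled(i) = S0 * (1 - v_c(t_null,i)) * (1 + g * delta_c(t_bold,i))

where v is the CBV response (a CBV increase *lowers* the blood-nulled
signal), delta the BOLD response, and g the contamination gain.  The
multiplicative T2* contamination within one cycle is modelled as a single
per-cycle factor evaluated at that cycle's BOLD readout, so that dividing the
nulled by the BOLD series volume-by-volume removes it exactly in the
noise-free limit.  Nulled volumes are sampled at block 2 of the cycle, BOLD
volumes at block 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .acquisition import AcquisitionScheme, StimulusDesign, Trial
from .geometry import LABELS, GeometryLabels
from .io import VolumeSeries
from .responses import (
    COMPARTMENTS,
    CompartmentModel,
    ResponseParams,
    compartment_response,
)

COMPARTMENT_CODES = {name: i + 1 for i, name in enumerate(COMPARTMENTS)}


def compartment_map(geometry: GeometryLabels) -> np.ndarray:
    """Assign each voxel its generative compartment (0 = none).

    Gray matter is split into deep/middle/superficial terciles of the
    analytic equivolume depth; vessel voxels keep their own compartment.
    """
    cmap = np.zeros(geometry.volume.shape, dtype=np.int16)
    depth = geometry.analytic_equivolume_depth()
    gm = geometry.gm_mask
    cmap[gm & (depth < 1 / 3)] = COMPARTMENT_CODES["gm_deep"]
    cmap[gm & (depth >= 1 / 3) & (depth < 2 / 3)] = COMPARTMENT_CODES["gm_middle"]
    cmap[gm & (depth >= 2 / 3)] = COMPARTMENT_CODES["gm_superficial"]
    cmap[geometry.vessel_mask] = COMPARTMENT_CODES["vessel"]
    return cmap


def superposed_response(
    trials: list[Trial],
    model: CompartmentModel,
    compartment: str,
    contrast: str,
    t: np.ndarray,
) -> np.ndarray:
    """Sum of single-trial responses of one compartment at times ``t``."""
    p = model.get(compartment, contrast)
    total = np.zeros(np.shape(t), dtype=float)
    for tr in trials:
        total += p.response(np.asarray(t, float) - tr.onset_s, tr.duration_s)
    return total


@dataclass
class GroundTruth:
    """Everything the generator knows, for recovery audits."""

    compartment_map: np.ndarray
    trials: list[Trial]
    model: CompartmentModel
    acq: AcquisitionScheme
    peaks: dict  # (contrast, compartment, duration) -> {"ttp_s", "peak_pct"}

    def era_curve(self, compartment: str, contrast: str, duration_s: float,
                  n_samples: int) -> np.ndarray:
        """Noise-free zeroed percent-change ERA the pipeline should recover.

        Averages the superposed (carryover-included) compartment response over
        the trials of one duration on the effective sampling grid, zeroed at
        stimulus onset — the exact quantity the event-related analysis
        estimates.  CBV curves are returned on the inverted (positive) scale.
        """
        dt = self.acq.effective_dt_s
        tw = np.arange(n_samples) * dt
        sel = [tr for tr in self.trials if tr.duration_s == duration_s]
        curves = []
        for tr in sel:
            v = superposed_response(self.trials, self.model, compartment,
                                    contrast, tw + tr.onset_s)
            curves.append(100.0 * (v - v[0]))
        return np.mean(curves, axis=0)

    def to_dict(self) -> dict:
        params = {
            c: {
                k: {
                    "amplitude": p.amplitude,
                    "mean_s": p.mean_s,
                    "sd_s": p.sd_s,
                    "delay_s": p.delay_s,
                    "ceiling": None if math.isinf(p.ceiling) else p.ceiling,
                }
                for k, p in d.items()
            }
            for c, d in self.model.params.items()
        }
        return {
            "model": {
                "params": params,
                "bold_contamination_gain": self.model.bold_contamination_gain,
                "noise_sd": self.model.noise_sd,
                "s0": self.model.s0,
            },
            "peaks": {
                f"{k[0]}/{k[1]}/{k[2]:g}s": v for k, v in self.peaks.items()
            },
        }


@dataclass
class SimulatedRun:
    nulled: VolumeSeries
    bold: VolumeSeries
    motion: np.ndarray  # (n_volumes, 6): translations mm, rotations rad
    truth: GroundTruth


def _analytic_peaks(model: CompartmentModel, durations: list[float]) -> dict:
    peaks = {}
    for contrast in ("cbv", "bold"):
        for comp in COMPARTMENTS:
            for d in durations:
                curve = compartment_response(d, model, comp, contrast,
                                             np.array([0.0]))
                peaks[(contrast, comp, d)] = {
                    "ttp_s": curve.peak_time_s,
                    "peak_pct": 100.0 * curve.peak_value,
                }
    return peaks


def simulate_run(
    geometry: GeometryLabels,
    design: StimulusDesign,
    acq: AcquisitionScheme,
    model: CompartmentModel,
    run: int = 0,
    seed: int | None = None,
    motion_step_mm: float = 0.02,
    motion_step_rad: float = 2e-4,
    motion_spikes: dict[int, float] | None = None,
) -> SimulatedRun:
    """Simulate one run of interleaved nulled/BOLD volumes.

    Motion is a slow random walk recorded as a parameter trace only — the
    synthetic data are generated in aligned space (registration is external
    to this pipeline).  ``motion_spikes`` maps volume index to an abrupt
    translation jump in mm, for motion-QC tests.

    The random seed defaults to ``model.seed + run`` so multi-run simulations
    are reproducible yet mutually independent.
    """
    if seed is None:
        seed = model.seed + run
    rng = np.random.default_rng(seed)
    trials = design.runs[run]
    n = int(math.ceil(design.run_duration_s[run] / acq.cycle_s))
    t_null = np.arange(n) * acq.cycle_s + acq.nulled_offset_s
    t_bold = np.arange(n) * acq.cycle_s + acq.bold_offset_s

    cmap = compartment_map(geometry)
    nulled = np.full(geometry.volume.shape + (n,), model.s0, dtype=np.float64)
    bold = np.full(geometry.volume.shape + (n,), model.s0, dtype=np.float64)
    g = model.bold_contamination_gain
    for comp, code in COMPARTMENT_CODES.items():
        mask = cmap == code
        if not mask.any():
            continue
        v = superposed_response(trials, model, comp, "cbv", t_null)
        delta = superposed_response(trials, model, comp, "bold", t_bold)
        nulled[mask] = model.s0 * (1.0 - v) * (1.0 + g * delta)
        bold[mask] = model.s0 * (1.0 + delta)
    if model.noise_sd > 0:
        nulled += rng.normal(0.0, model.noise_sd, size=nulled.shape)
        bold += rng.normal(0.0, model.noise_sd, size=bold.shape)

    motion = np.cumsum(
        rng.normal(0.0, 1.0, size=(n, 6))
        * np.array([motion_step_mm] * 3 + [motion_step_rad] * 3),
        axis=0,
    )
    if motion_spikes:
        for vol, jump_mm in motion_spikes.items():
            motion[vol:, 0] += jump_mm

    durations = sorted({tr.duration_s for tr in trials})
    truth = GroundTruth(
        compartment_map=cmap,
        trials=list(trials),
        model=model,
        acq=acq,
        peaks=_analytic_peaks(model, durations),
    )
    return SimulatedRun(
        nulled=VolumeSeries(nulled, "nulled", acq.cycle_s, acq.nulled_offset_s),
        bold=VolumeSeries(bold, "bold", acq.cycle_s, acq.bold_offset_s),
        motion=motion,
        truth=truth,
    )


def model_from_yaml(path: str | Path) -> CompartmentModel:
    """Load a :class:`CompartmentModel` from a YAML config file.

    Schema::

        s0: 1000.0
        noise_sd: 66.7
        bold_contamination_gain: 1.0
        seed: 0
        compartments:
          gm_middle:
            cbv: {amplitude: 0.022, mean_s: 5.0, sd_s: 2.5, delay_s: 0.0}
            bold: {amplitude: 0.025, mean_s: 5.5, sd_s: 2.75}
          ...

    Omitted compartments/contrasts keep the package defaults; a ``ceiling``
    key of ``null`` (or absence) means no saturation.
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    model = CompartmentModel()
    for comp, contrasts in (cfg.get("compartments") or {}).items():
        for contrast, kw in contrasts.items():
            kw = dict(kw)
            if kw.get("ceiling") is None:
                kw["ceiling"] = math.inf
            model.params.setdefault(comp, {})[contrast] = ResponseParams(**kw)
    for key in ("bold_contamination_gain", "noise_sd", "s0", "seed"):
        if key in cfg:
            setattr(model, key, cfg[key])
    return model
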