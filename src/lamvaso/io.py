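"""Containers and file I/O (NIfTI volumes, TSV tables, JSON reports)."""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

CONTRAST_TAGS = ("nulled", "bold", "vaso")

MOTION_COLUMNS = [
    "trans_x_mm",
    "trans_y_mm",
    "trans_z_mm",
    "rot_x_rad",
    "rot_y_rad",
    "rot_z_rad",
]


@dataclass
class VolumeSeries:
    """A 4D scalar field with a contrast tag and a sampling interval.

    ``t0_s`` is the offset of the first sample within the acquisition cycle
    (block 2 for nulled, block 4 for BOLD volumes); the BOLD-corrected VASO
    series inherits the nulled timing.
    """

    data: np.ndarray  # (..., T), time last
    contrast: str
    dt_s: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.contrast not in CONTRAST_TAGS:
            raise ValueError(f"contrast must be one of {CONTRAST_TAGS}")
        if self.dt_s <= 0:
            raise ValueError("sampling interval must be positive")
        self.data = np.asarray(self.data)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + self.dt_s * np.arange(self.n_volumes)

    def with_data(self, data: np.ndarray, **changes) -> "VolumeSeries":
        return replace(self, data=data, **changes)

    def to_nifti(self, path: str | Path, voxel_size_mm: float = 0.9) -> None:
        if self.data.ndim != 4:
            raise ValueError("only 4D series can be written to NIfTI")
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)
        img.header["pixdim"][4] = self.dt_s
        img.header["toffset"] = self.t0_s
        img.header.set_xyzt_units(xyz="mm", t="sec")
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, contrast: str) -> "VolumeSeries":
        img = nib.load(str(path))
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float64),
            contrast=contrast,
            dt_s=float(img.header["pixdim"][4]),
            t0_s=float(img.header["toffset"]),
        )


def save_labels(volume: np.ndarray, path: str | Path,
                voxel_size_mm: float = 0.9) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.int16), affine), str(path))


def load_labels(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.int16)


def save_map(volume: np.ndarray, path: str | Path,
             voxel_size_mm: float = 0.9) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def save_motion(trace: np.ndarray | pd.DataFrame, path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(trace), columns=MOTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def load_motion(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df[MOTION_COLUMNS].to_numpy(dtype=float)


def save_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def load_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
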