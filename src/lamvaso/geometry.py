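"""Synthetic layered-cortex geometry.

The ground-truth geometry is a gray-matter annulus (a curved cortical ribbon
with known analytic equivolume depth) embedded in CSF around a white-matter
core, with optional vessel "tubes" sitting in the CSF immediately outside the
gray-matter surface — mimicking pial vessels draining the activated patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABELS = {"background": 0, "csf": 1, "gm": 2, "wm": 3, "vessel": 4}


class GeometryError(ValueError):
    """Raised when a requested geometry cannot be constructed."""


@dataclass
class GeometryLabels:
    """Label volume plus the generative parameters that produced it."""

    volume: np.ndarray  # integer labels, see LABELS
    annulus_radii: tuple[float, float]  # inner (WM/GM), outer (GM/CSF), voxels
    center: tuple[float, float]  # in-plane center, voxel units
    voxel_size_mm: float = 0.9
    vessel_voxels: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))
    roi_center: tuple[int, int, int] | None = None
    roi_radius_mm: float | None = None

    @property
    def gm_mask(self) -> np.ndarray:
        return self.volume == LABELS["gm"]

    @property
    def vessel_mask(self) -> np.ndarray:
        return self.volume == LABELS["vessel"]

    def radius_map(self) -> np.ndarray:
        """In-plane distance of each voxel center from the annulus axis."""
        nx, ny = self.volume.shape[:2]
        x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        r2d = np.hypot(x - self.center[0], y - self.center[1])
        return np.repeat(r2d[:, :, None], self.volume.shape[2], axis=2)

    def analytic_equivolume_depth(self) -> np.ndarray:
        """Closed-form equivolume depth on the annulus (NaN outside GM)."""
        r_in, r_out = self.annulus_radii
        r = self.radius_map()
        depth = (r**2 - r_in**2) / (r_out**2 - r_in**2)
        return np.where(self.gm_mask, np.clip(depth, 0.0, 1.0), np.nan)


def build_geometry(
    grid_shape: tuple[int, int, int] = (40, 40, 10),
    annulus_radii: tuple[float, float] = (10.0, 16.0),
    n_vessels: int = 4,
    seed: int = 0,
    vessel_radius_vox: float = 0.9,
    voxel_size_mm: float = 0.9,
) -> GeometryLabels:
    """Build a labelled annulus geometry.

    Parameters
    ----------
    grid_shape
        Volume shape in voxels; the annulus is extruded along the third axis.
    annulus_radii
        Inner (WM/GM) and outer (GM/CSF) boundary radii in voxel units.
    n_vessels
        Number of vessel tubes placed in CSF just outside the GM surface,
        running along the extrusion axis.
    vessel_radius_vox
        In-plane radius of each vessel tube.

    Raises
    ------
    GeometryError
        If the annulus (plus a one-voxel CSF margin) does not fit the grid.
    """
    r_in, r_out = annulus_radii
    if not (0 < r_in < r_out):
        raise GeometryError("annulus radii must satisfy 0 < inner < outer")
    if n_vessels < 0:
        raise GeometryError("n_vessels must be >= 0")
    nx, ny, nz = grid_shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    # require the outer radius plus vessel margin to fit inside the grid
    margin = 2.0 + vessel_radius_vox
    if r_out + margin > min(cx, cy, nx - 1 - cx, ny - 1 - cy):
        raise GeometryError("annulus does not fit in the grid")

    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r2d = np.hypot(x - cx, y - cy)
    plane = np.full((nx, ny), LABELS["csf"], dtype=np.int16)
    plane[r2d < r_in] = LABELS["wm"]
    plane[(r2d >= r_in) & (r2d < r_out)] = LABELS["gm"]
    volume = np.repeat(plane[:, :, None], nz, axis=2)

    rng = np.random.default_rng(seed)
    vessel_voxels: list[tuple[int, int, int]] = []
    if n_vessels > 0:
        # evenly spread angles with a random common rotation: vessels sit in
        # CSF adjacent to the GM outer boundary and run along z (tube-like)
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        angles = theta0 + 2.0 * np.pi * np.arange(n_vessels) / n_vessels
        r_v = r_out + vessel_radius_vox  # just outside the GM surface
        for th in angles:
            vx = cx + r_v * np.cos(th)
            vy = cy + r_v * np.sin(th)
            d2d = np.hypot(x - vx, y - vy)
            sel = (d2d <= vessel_radius_vox) & (r2d >= r_out)
            for i, j in np.argwhere(sel):
                for k in range(nz):
                    volume[i, j, k] = LABELS["vessel"]
                    vessel_voxels.append((i, j, k))

    return GeometryLabels(
        volume=volume,
        annulus_radii=(float(r_in), float(r_out)),
        center=(cx, cy),
        voxel_size_mm=voxel_size_mm,
        vessel_voxels=np.array(vessel_voxels, dtype=int).reshape(-1, 3),
    )
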