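"""Fractional-occupancy density grids for a tracked atom.

Each frame of an aligned trajectory increments the voxel containing the
atom (nearest-voxel binning on half-open intervals ``[low, high)``, no
kernel smoothing); values are counts divided by the frame count, so a
single-atom grid sums to exactly 1. A contour at fractional occupancy ``c``
over a trajectory of length ``L`` corresponds to a total residence time of
at least ``c × L`` in any voxel inside the contour — e.g. a 0.05% contour on
an 89 ns trajectory marks voxels occupied for at least ~45 ps in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, SelectionError
from .io import Trajectory

DEFAULT_SPACING = 0.5  # Å per voxel edge


@dataclass
class DensityGrid:
    """3-D voxel grid of fractional occupancy."""

    origin: np.ndarray  # Å, position of the low corner of voxel (0,0,0)
    spacing: float  # Å per voxel edge (isotropic)
    counts: np.ndarray  # 3 ints
    values: np.ndarray  # (nx, ny, nz) fractional occupancy
    n_frames: int

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.counts = np.asarray(self.counts, dtype=int).reshape(3)
        self.values = np.asarray(self.values, dtype=float).reshape(tuple(self.counts))
        if not self.spacing > 0:
            raise ParameterError("voxel spacing must be > 0 Å")

    def voxel_centers(self) -> np.ndarray:
        """Centers of all voxels, shape ``(nx, ny, nz, 3)``."""
        axes = [
            self.origin[k] + (np.arange(self.counts[k]) + 0.5) * self.spacing
            for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def centroid(self) -> np.ndarray:
        """Occupancy-weighted centroid of the grid, in Å."""
        total = self.values.sum()
        if total <= 0:
            raise ParameterError("cannot take the centroid of an empty grid")
        centers = self.voxel_centers().reshape(-1, 3)
        return (self.values.reshape(-1, 1) * centers).sum(axis=0) / total


def accumulate_density(traj: Trajectory, atom_selection: str,
                       spacing: float = DEFAULT_SPACING) -> DensityGrid:
    """Bin one atom's positions over all frames into a fractional-occupancy grid.

    The grid spans the atom's bounding box padded by 2 voxels on every side.
    ``atom_selection`` must resolve to exactly one atom.
    """
    if not spacing > 0:
        raise ParameterError("voxel spacing must be > 0 Å")
    idx = traj.topology.select(atom_selection)
    if len(idx) != 1:
        raise SelectionError(
            f"selection {atom_selection!r} resolved to {len(idx)} atoms, expected 1"
        )
    pos = traj.coords[:, int(idx[0]), :]
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    origin = lo - 2.0 * spacing
    counts = np.floor((hi - origin) / spacing).astype(int) + 3  # +2 pad, +1 inclusive
    bins = np.floor((pos - origin) / spacing).astype(int)
    flat = np.ravel_multi_index(bins.T, tuple(counts))
    hist = np.bincount(flat, minlength=int(np.prod(counts))).reshape(tuple(counts))
    return DensityGrid(
        origin=origin,
        spacing=float(spacing),
        counts=counts,
        values=hist / traj.n_frames,
        n_frames=traj.n_frames,
    )


def contour_mask(grid: DensityGrid, threshold: float) -> tuple[np.ndarray, int]:
    """Boolean mask of voxels with occupancy ``>= threshold`` and its voxel count.

    The comparison is inclusive so a voxel exactly at the contour level (the
    "at least" residence-time semantics) is inside the contour.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError("contour threshold must be in (0, 1]")
    mask = grid.values >= threshold
    return mask, int(mask.sum())


@dataclass(frozen=True)
class ResidenceTime:
    """Minimum total residence time implied by an occupancy contour."""

    ps: float
    ps_rounded_up: int


def occupancy_to_residence(threshold: float, traj_length_ns: float) -> ResidenceTime:
    """Convert a fractional-occupancy contour level to a residence time.

    A voxel at fractional occupancy ``threshold`` over a trajectory of
    ``traj_length_ns`` nanoseconds was occupied for at least
    ``threshold × traj_length_ns × 1000`` ps in total.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError("occupancy threshold must be in (0, 1]")
    if not traj_length_ns > 0:
        raise ParameterError("trajectory length must be > 0 ns")
    ps = threshold * traj_length_ns * 1000.0
    return ResidenceTime(ps=ps, ps_rounded_up=int(math.ceil(ps)))
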