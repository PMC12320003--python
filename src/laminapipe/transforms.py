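"""Shared motion/deformation containers and rigid-transform algebra.

Conventions (fixed package-wide):

* A :class:`DisplacementField` ``f`` on a target grid means pullback
  resampling: ``out[i] = in[i + f[i]]`` — each output voxel samples the input
  at its index plus the stored shift, in **source-grid voxel units**.  When the
  target grid differs from the source grid (upsampling), the grid change is
  baked into the shifts, so the identity map on a 2x grid stores ``i/2 - i``.
* Rigid parameters are ``(tx, ty, tz)`` in mm and ``(rx, ry, rz)`` in degrees,
  intrinsic rotations applied x -> y -> z about the volume centre.  The
  parameters describe the mapping that carries a frame onto the reference:
  resampling the frame with :func:`rigid_to_field` of those parameters aligns
  it to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "DisplacementField",
    "RigidMotion",
    "rigid_matrix",
    "rigid_to_field",
    "matrix_to_field",
    "pe_shift_field",
]


@dataclass
class DisplacementField:
    """Per-voxel 3-vector shifts (voxel units) on a reference grid."""

    shifts: np.ndarray  # (nx, ny, nz, 3)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        if self.shifts.ndim != 4 or self.shifts.shape[3] != 3:
            raise ValueError("shifts must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("displacement field has non-finite values")

    @property
    def grid(self) -> tuple:
        return self.shifts.shape[:3]

    @classmethod
    def zero(cls, grid) -> "DisplacementField":
        return cls(np.zeros(tuple(grid) + (3,)))

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Linearly interpolate the field at fractional grid points (N, 3)."""
        pts = np.asarray(points, dtype=np.float64)
        out = np.empty_like(pts)
        for c in range(3):
            out[:, c] = map_coordinates(
                self.shifts[..., c], pts.T, order=1, mode="nearest"
            )
        return out

    def mapping(self, points: np.ndarray) -> np.ndarray:
        """Apply the full map ``p -> p + f(p)`` at fractional points."""
        return points + self.sample(points)

    def max_abs(self) -> float:
        return float(np.abs(self.shifts).max())

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.shifts.copy())


@dataclass
class RigidMotion:
    """Per-frame 6-DOF rigid parameters plus per-slice phase-encode shifts.

    ``per_frame`` is (T, 6): translations mm, rotations degrees.
    ``per_slice_pe_shift`` is (T, n_slices) voxel shifts along the PE axis
    (the slice-dependent translation the 2D stage corrects).  The reference
    frame carries all-zero parameters.
    """

    per_frame: np.ndarray
    per_slice_pe_shift: np.ndarray
    reference_frame: Optional[int] = None

    def __post_init__(self) -> None:
        self.per_frame = np.asarray(self.per_frame, dtype=np.float64)
        self.per_slice_pe_shift = np.asarray(self.per_slice_pe_shift, dtype=np.float64)
        if self.per_frame.ndim != 2 or self.per_frame.shape[1] != 6:
            raise ValueError("per_frame must be (T, 6)")
        if self.per_slice_pe_shift.shape[0] != self.per_frame.shape[0]:
            raise ValueError("per_slice_pe_shift frame count mismatch")

    @property
    def n_frames(self) -> int:
        return self.per_frame.shape[0]

    @classmethod
    def zero(cls, n_frames: int, n_slices: int) -> "RigidMotion":
        return cls(np.zeros((n_frames, 6)), np.zeros((n_frames, n_slices)))

    def to_dataframe(self):
        import pandas as pd

        cols = ["tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"]
        return pd.DataFrame(self.per_frame, columns=cols)


def _rot_axis(angle_deg: float, axis: int) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s if axis != 1 else s
    m[j, i] = s if axis != 1 else -s
    return m


def rigid_matrix(params, shape, voxel_sizes_mm) -> np.ndarray:
    """Homogeneous 4x4 voxel-space matrix for 6 rigid parameters.

    Rotation about the grid centre, intrinsic x -> y -> z, translations
    converted from mm to voxels through the voxel sizes.
    """
    params = np.asarray(params, dtype=np.float64)
    tx, ty, tz, rx, ry, rz = params
    R = _rot_axis(rx, 0) @ _rot_axis(ry, 1) @ _rot_axis(rz, 2)
    centre = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    t_vox = np.array([tx, ty, tz]) / np.asarray(voxel_sizes_mm, dtype=np.float64)
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = centre - R @ centre + t_vox
    return M


def matrix_to_field(M: np.ndarray, grid) -> DisplacementField:
    """Densify a homogeneous voxel-space matrix into a displacement field."""
    nx, ny, nz = grid
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    ).astype(np.float64)
    mapped = idx @ M[:3, :3].T + M[:3, 3]
    return DisplacementField(mapped - idx)


def rigid_to_field(params, grid, voxel_sizes_mm, inverse: bool = False) -> DisplacementField:
    """Displacement field of a rigid transform (optionally its exact inverse)."""
    M = rigid_matrix(params, grid, voxel_sizes_mm)
    if inverse:
        M = np.linalg.inv(M)
    return matrix_to_field(M, grid)


def pe_shift_field(grid, pe_axis: int, shift) -> DisplacementField:
    """Field shifting along the PE axis; ``shift`` is scalar, per-slice (nz,),
    or a full (nx, ny, nz) voxel map (e.g. a field-map conversion)."""
    shifts = np.zeros(tuple(grid) + (3,))
    shift = np.asarray(shift, dtype=np.float64)
    if shift.ndim == 0:
        shifts[..., pe_axis] = shift
    elif shift.ndim == 1:  # per slice
        shifts[..., pe_axis] = shift[None, None, :]
    elif shift.shape == tuple(grid):
        shifts[..., pe_axis] = shift
    else:
        raise ValueError("shift must be scalar, per-slice, or full-grid")
    return DisplacementField(shifts)
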