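"""Spatial transforms: rigid matrices, dense displacement warps and chains.

All transforms are *pull-back* point maps in world mm: ``apply_points`` takes
coordinates in the reference (destination-grid) space and returns the
corresponding coordinates in the source/moving space.  Composition of a chain
applies its elements sequentially, first element first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "RigidTransform",
    "AffineTransform",
    "Warp",
    "TransformChain",
    "rigid_from_params",
    "params_from_rigid",
    "invert_warp",
    "WarpInversionError",
]


def _rot_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation Rz @ Ry @ Rx from Euler angles in radians."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class AffineTransform:
    """General linear map y = M[:3,:3] x + M[:3,3] in world mm."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("transform is not invertible")

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return type(self)(np.linalg.inv(self.matrix))

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    # -- plain-text (FSL .mat style) I/O -----------------------------------
    def save(self, path) -> None:
        header = (
            "# 4x4 world-space (mm) transform, pull-back convention:\n"
            "# maps reference world coordinates to moving world coordinates\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for row in self.matrix:
                fh.write("  ".join(f"{v: .10f}" for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(v) for v in line.split()])
        return cls(np.asarray(rows))


@dataclass
class RigidTransform(AffineTransform):
    """6-DOF rigid map: orthonormal rotation block (det +1) plus translation."""

    failed: bool = False  # set by registration routines that fell back to init

    def __post_init__(self) -> None:
        super().__post_init__()
        R = self.matrix[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-5):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block has negative determinant")

    def inverse(self) -> "RigidTransform":
        R = self.matrix[:3, :3]
        t = self.matrix[:3, 3]
        out = np.eye(4)
        out[:3, :3] = R.T
        out[:3, 3] = -R.T @ t
        return RigidTransform(out)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))


def rigid_from_params(params, center=None) -> RigidTransform:
    """Build a rigid transform from (rx, ry, rz [rad], tx, ty, tz [mm]).

    Rotation is about ``center`` (world mm) when given, so that rotation and
    translation parameters are approximately decoupled during optimization.
    """
    rx, ry, rz, tx, ty, tz = [float(v) for v in params]
    R = _rot_matrix(rx, ry, rz)
    M = np.eye(4)
    M[:3, :3] = R
    t = np.array([tx, ty, tz])
    if center is not None:
        c = np.asarray(center, dtype=float)
        t = t + c - R @ c
    M[:3, 3] = t
    return RigidTransform(M)


def params_from_rigid(rig: RigidTransform, center=None) -> np.ndarray:
    """Recover (rx, ry, rz, tx, ty, tz) from a rigid matrix (Rz Ry Rx order)."""
    R = rig.matrix[:3, :3]
    ry = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
    if abs(np.cos(ry)) > 1e-8:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:  # gimbal lock; not reached for the small angles used here
        rx = np.arctan2(-R[1, 2], R[1, 1])
        rz = 0.0
    t = rig.matrix[:3, 3].copy()
    if center is not None:
        c = np.asarray(center, dtype=float)
        t = t - c + R @ c
    return np.array([rx, ry, rz, t[0], t[1], t[2]])


@dataclass
class Warp:
    """Dense displacement warp on a named reference grid.

    The total map is ``T(x) = A(x) + u(x)`` where ``A`` is the (rigid or
    12-DOF affine) pre-map and ``u`` the displacement field in mm, stored on
    the warp's own grid and trilinearly interpolated at arbitrary world
    points (zero displacement outside the field of view).  Direction is
    pull-back: reference-space coordinates in, source-space coordinates out.
    Outside the grid the field extrapolates its nearest edge value, keeping
    the map continuous (a hard zero at the border would make it
    non-invertible).
    """

    displacement: np.ndarray  # (nx, ny, nz, 3) mm
    grid_affine: np.ndarray   # voxel->world of the grid carrying the field
    affine: AffineTransform = None  # pre-map; identity when None

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacement field contains non-finite values")
        self.grid_affine = np.asarray(self.grid_affine, dtype=float)
        if self.affine is None:
            self.affine = AffineTransform(np.eye(4))

    def displacement_at(self, pts: np.ndarray) -> np.ndarray:
        """Interpolate the displacement field (mm) at world points."""
        inv = np.linalg.inv(self.grid_affine)
        ijk = np.asarray(pts, float) @ inv[:3, :3].T + inv[:3, 3]
        coords = ijk.T
        return np.stack(
            [
                ndimage.map_coordinates(
                    self.displacement[..., k], coords, order=1, mode="nearest"
                )
                for k in range(3)
            ],
            axis=-1,
        )

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return self.affine.apply_points(pts) + self.displacement_at(pts)

    # -- I/O: 4D NIfTI with 3 components in the 4th dimension, mm units ----
    def save(self, path, affine_path=None) -> None:
        nib.save(
            nib.Nifti1Image(self.displacement.astype(np.float32), self.grid_affine),
            str(path),
        )
        if affine_path is not None:
            self.affine.save(affine_path)

    @classmethod
    def load(cls, path, affine_path=None) -> "Warp":
        img = nib.load(str(path))
        aff = AffineTransform.load(affine_path) if affine_path else None
        return cls(np.asarray(img.dataobj, dtype=np.float64), img.affine, aff)


@dataclass
class TransformChain:
    """Ordered list of transforms applied sequentially (first element first)."""

    elements: list = field(default_factory=list)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        out = np.asarray(pts, dtype=float)
        for el in self.elements:
            out = el.apply_points(out)
        return out

    def inverse(self) -> "TransformChain":
        """Closed-form inverse: invert each element, reverse order.

        Warp elements are inverted numerically (see :func:`invert_warp`).
        """
        inv_elements = []
        for el in reversed(self.elements):
            if isinstance(el, Warp):
                inv_elements.append(invert_warp(el))
            else:
                inv_elements.append(el.inverse())
        return TransformChain(inv_elements)

    def save_manifest(self, path, element_paths) -> None:
        """Write a YAML manifest listing element files in application order."""
        entries = []
        for el, ep in zip(self.elements, element_paths):
            entries.append(
                {
                    "kind": "warp" if isinstance(el, Warp) else "rigid",
                    "file": str(ep),
                }
            )
        with open(path, "w") as fh:
            yaml.safe_dump({"transform_chain": entries}, fh)


class WarpInversionError(RuntimeError):
    """Fixed-point warp inversion failed to converge; carries the residual map."""

    def __init__(self, message, residual):
        super().__init__(message)
        self.residual = residual


def invert_warp(
    w: Warp,
    grid_affine: np.ndarray | None = None,
    grid_shape: tuple | None = None,
    tol_voxel: float = 0.01,
    max_iter: int = 50,
) -> Warp:
    """Numerically invert a warp by fixed-point iteration.

    Writes the total map as ``T(x) = x + u_tot(x)`` and solves
    ``v_{k+1}(y) = -u_tot(y + v_k(y))`` until the maximum update is below
    ``tol_voxel`` voxels or ``max_iter`` iterations.  The inverse is returned
    as a pure displacement warp (identity pre-map) on ``grid_affine`` /
    ``grid_shape`` (defaults: the input warp's own grid).
    """
    if grid_affine is None:
        grid_affine = w.grid_affine
        grid_shape = w.displacement.shape[:3]
    if grid_shape is None:
        raise ValueError("grid_shape required when grid_affine is given")
    grid_affine = np.asarray(grid_affine, dtype=float)
    vox = np.sqrt((grid_affine[:3, :3] ** 2).sum(axis=0)).min()

    idx = np.indices(grid_shape, dtype=float)
    pts = np.stack([idx[0], idx[1], idx[2]], axis=-1).reshape(-1, 3)
    y = pts @ grid_affine[:3, :3].T + grid_affine[:3, 3]

    def u_tot(x):
        return w.apply_points(x) - x

    v = np.zeros_like(y)
    last_update = np.inf
    omega = 0.5  # damping keeps the iteration contractive for rougher fields
    for _ in range(max_iter):
        v_new = v + omega * (-u_tot(y + v) - v)
        last_update = float(np.abs(v_new - v).max())
        v = v_new
        if last_update < tol_voxel * vox:
            break
    else:
        residual = np.linalg.norm(u_tot(y + v) + v, axis=1).reshape(grid_shape)
        raise WarpInversionError(
            f"warp inversion did not converge (last update {last_update:.4f} mm)",
            residual,
        )
    return Warp(v.reshape(*grid_shape, 3), grid_affine)
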