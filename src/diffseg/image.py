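"""Volumetric image containers, NIfTI I/O, resampling and binary-mask operators.

Conventions
-----------
Voxel indices are 0-based; world space is RAS+ millimetres; affines map voxel
index -> world mm (NIfTI convention).  Transforms passed to :func:`resample`
are *pull-back* point maps: they take reference-space world coordinates to
moving-space world coordinates, which is exactly what sampling the moving
image on the reference grid requires.  Out-of-field voxels are filled with 0
(background), never clamped, because inputs are brain-extracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "BinaryMask",
    "GeometryError",
    "load_volume",
    "load_mask",
    "save_volume",
    "resample",
    "erode",
    "dilate",
    "threshold_binarize",
    "cross_mask",
    "subtract_mask",
    "dice",
]

#: full 3x3x3 box structuring element (26-connectivity)
BOX_3x3x3 = np.ones((3, 3, 3), dtype=bool)


class GeometryError(ValueError):
    """Raised when image grids or affines are geometrically invalid/mismatched."""


@dataclass
class Volume:
    """A 3D (or 4D) intensity array with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray
        3D scalar array, or 4D with frames along the last axis (DWI).
    affine : (4, 4) ndarray
        Voxel-index -> world-mm map; must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is not invertible")
        if self.data.ndim not in (3, 4):
            raise GeometryError("Volume data must be 3D or 4D")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def shape3(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    def frame(self, i: int) -> "Volume":
        """Extract one 3D frame of a 4D volume."""
        if self.data.ndim != 4:
            raise GeometryError("frame() requires a 4D volume")
        return Volume(self.data[..., i], self.affine)

    def world_coords(self) -> np.ndarray:
        """World mm coordinates of every voxel centre, shape (*shape3, 3)."""
        idx = np.indices(self.shape3, dtype=float)
        pts = np.stack([idx[0], idx[1], idx[2]], axis=-1)
        return pts @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_grid(self, other: "Volume | BinaryMask") -> bool:
        return self.shape3 == other.shape3 and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


@dataclass
class BinaryMask:
    """A 3D boolean mask sharing the grid of its parent :class:`Volume`."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, [0, 1]).all():
                raise ValueError("mask values must be strictly in {0, 1}")
            arr = arr.astype(bool)
        if arr.ndim != 3:
            raise GeometryError("BinaryMask data must be 3D")
        self.data = arr
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def shape3(self) -> tuple:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other) -> bool:
        return self.shape3 == other.shape3[:3] and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def to_volume(self) -> Volume:
        return Volume(self.data.astype(np.float64), self.affine)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_volume(path) -> Volume:
    img = nib.load(str(path))
    return Volume(np.asarray(img.dataobj, dtype=np.float64), img.affine)


def load_mask(path) -> BinaryMask:
    img = nib.load(str(path))
    return BinaryMask(np.asarray(img.dataobj) > 0.5, img.affine)


def save_volume(vol: "Volume | BinaryMask", path) -> None:
    """Write a Volume (float32) or BinaryMask (uint8) as NIfTI."""
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(moving: Volume, transform, reference: Volume, interp: str = "trilinear") -> Volume:
    """Sample `moving` on the grid of `reference` through a pull-back transform.

    Parameters
    ----------
    moving : Volume
        Image to be resampled.
    transform
        Pull-back point map (reference world mm -> moving world mm): a
        RigidTransform, Warp, TransformChain, or None for identity.
    reference : Volume
        Defines the output grid.
    interp : {"trilinear", "nearest"}
        Use "nearest" for label/mask volumes; a warning is logged if an
        integer-valued volume is interpolated trilinearly.
    """
    if interp not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    order = 1 if interp == "trilinear" else 0
    if interp == "trilinear" and moving.data.dtype.kind in "iub":
        warnings.warn(
            "trilinear interpolation of an integer-valued volume; "
            "use interp='nearest' for label images",
            stacklevel=2,
        )

    pts = reference.world_coords().reshape(-1, 3)
    if transform is not None:
        pts = transform.apply_points(pts)
    inv = np.linalg.inv(moving.affine)
    ijk = pts @ inv[:3, :3].T + inv[:3, 3]
    coords = ijk.T  # (3, n)

    if moving.data.ndim == 3:
        out = ndimage.map_coordinates(
            moving.data, coords, order=order, mode="constant", cval=0.0
        ).reshape(reference.shape3)
    else:
        frames = [
            ndimage.map_coordinates(
                moving.data[..., f], coords, order=order, mode="constant", cval=0.0
            ).reshape(reference.shape3)
            for f in range(moving.data.shape[3])
        ]
        out = np.stack(frames, axis=-1)
    return Volume(out, reference.affine.copy())


# ---------------------------------------------------------------------------
# Binary morphology — full 3x3x3 box element throughout
# ---------------------------------------------------------------------------

def erode(mask: BinaryMask, n_pass: int = 1) -> BinaryMask:
    """Erode with the full 3x3x3 box: a voxel survives iff its whole
    3x3x3 neighbourhood lies inside the mask.  ``n_pass=0`` is identity."""
    if n_pass < 0:
        raise ValueError("n_pass must be >= 0")
    data = mask.data
    for _ in range(n_pass):
        data = ndimage.binary_erosion(data, structure=BOX_3x3x3, border_value=0)
    return BinaryMask(data.copy(), mask.affine.copy())


def dilate(mask: BinaryMask, n_pass: int = 1) -> BinaryMask:
    """Dilate with the full 3x3x3 box: a voxel is set iff any neighbour in
    the box is set."""
    if n_pass < 0:
        raise ValueError("n_pass must be >= 0")
    data = mask.data
    for _ in range(n_pass):
        data = ndimage.binary_dilation(data, structure=BOX_3x3x3, border_value=0)
    return BinaryMask(data.copy(), mask.affine.copy())


def threshold_binarize(prob: Volume, thr: float) -> BinaryMask:
    """Binarize a probability map at ``thr`` (inclusive: prob >= thr is kept).

    The inclusive rule keeps voxels at exactly the threshold, consistent with
    excluding only voxels strictly *below* the cut.
    """
    if not (0.0 < thr < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    lo, hi = float(np.min(prob.data)), float(np.max(prob.data))
    if lo < -1e-9 or hi > 1.0 + 1e-9:
        raise ValueError(f"probability map values outside [0, 1]: [{lo}, {hi}]")
    return BinaryMask(prob.data >= thr, prob.affine.copy())


def _check_same_grid(a, b) -> None:
    if not a.same_grid(b):
        raise GeometryError("masks are not on the same grid")


def cross_mask(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise AND of two masks on the same grid."""
    _check_same_grid(a, b)
    return BinaryMask(a.data & b.data, a.affine.copy())


def subtract_mask(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """a AND NOT b."""
    _check_same_grid(a, b)
    return BinaryMask(a.data & ~b.data, a.affine.copy())


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|a∩b| / (|a| + |b|).

    Returns NaN (with a warning) if both masks are empty: the overlap of two
    empty segmentations is undefined, not 0 or 1.
    """
    _check_same_grid(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        warnings.warn("dice undefined: both masks empty", stacklevel=2)
        return float("nan")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)
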