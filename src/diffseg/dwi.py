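"""Diffusion data handling: gradient tables, b0 averaging, per-frame motion
realignment with b-vector rotation, weighted-least-squares tensor fitting and
FA computation.

The tensor is fitted to the log-linearized signal model

    ln S_i = ln S0 - b_i g_i^T D g_i

by ordinary least squares followed by one reweighted pass with weights equal
to the squared predicted signals, matching the classical weighted
least-squares estimator for log-transformed Rician-corrupted magnitudes.
FA uses the standard eigenvalue definition
FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import BinaryMask, Volume
from .register import register_rigid
from .transforms import RigidTransform

__all__ = [
    "GradientTable",
    "TensorField",
    "average_b0",
    "brain_mask_from_b0",
    "realign_volumes",
    "rotate_bvecs",
    "fit_tensor_wls",
    "fa_from_tensor",
]

#: scanners emit small nonzero nominal b0 values; treat b < 50 s/mm^2 as b0
B0_TOL = 50.0


@dataclass
class GradientTable:
    """Per-frame b-values (s/mm^2) and unit gradient directions.

    b0 frames carry the zero vector; all other directions must be unit norm.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, len(self.bvals)) and self.bvecs.shape[0] != self.bvecs.shape[1]:
            self.bvecs = self.bvecs.T
        if self.bvecs.shape != (len(self.bvals), 3):
            raise ValueError("bvecs must have one 3-vector per frame")
        dw = ~self.is_b0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("non-b0 gradient directions must be unit norm")

    @property
    def n_frames(self) -> int:
        return len(self.bvals)

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals < B0_TOL

    @property
    def n_unique_directions(self) -> int:
        dirs = self.bvecs[~self.is_b0]
        # antipodal directions encode the same diffusion measurement
        canon = np.round(dirs * np.sign(dirs[:, :1] + 1e-12), 5)
        return len(np.unique(canon, axis=0))

    # -- FSL-style text I/O ------------------------------------------------
    def save(self, bvals_path, bvecs_path) -> None:
        Path(bvals_path).write_text(
            " ".join(f"{v:.6g}" for v in self.bvals) + "\n"
        )
        with open(bvecs_path, "w") as fh:
            for k in range(3):
                fh.write(" ".join(f"{v:.10g}" for v in self.bvecs[:, k]) + "\n")

    @classmethod
    def load(cls, bvals_path, bvecs_path) -> "GradientTable":
        bvals = np.loadtxt(bvals_path).ravel()
        bvecs = np.loadtxt(bvecs_path)
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        return cls(bvals, bvecs)


def average_b0(dwi: Volume, gtab: GradientTable) -> Volume:
    """Voxelwise arithmetic mean of all b0 frames."""
    if dwi.data.ndim != 4 or dwi.data.shape[3] != gtab.n_frames:
        raise ValueError("DWI frame count does not match gradient table")
    b0 = gtab.is_b0
    if not b0.any():
        raise ValueError("no b0 frame (b < 50 s/mm^2) in gradient table")
    return Volume(dwi.data[..., b0].mean(axis=3), dwi.affine.copy())


def brain_mask_from_b0(b0: Volume, frac: float = 0.2) -> BinaryMask:
    """Simple brain extraction: intensity threshold at ``frac`` of the robust
    maximum, hole filling, and largest connected component."""
    data = b0.data
    hi = np.percentile(data, 99.0)
    m = data > frac * hi
    m = ndimage.binary_fill_holes(m)
    lab, n = ndimage.label(m)
    if n > 1:
        sizes = ndimage.sum(m, lab, index=np.arange(1, n + 1))
        m = lab == (1 + int(np.argmax(sizes)))
    return BinaryMask(m, b0.affine.copy())


def realign_volumes(
    dwi: Volume, gtab: GradientTable
) -> tuple[Volume, list[RigidTransform]]:
    """Rigidly realign every DWI frame to the averaged b0.

    Each frame is registered with a 6-DOF normalized-correlation cost (same
    modality) to the mean of the b0 frames and resampled onto the DWI grid.
    Returns the realigned 4D volume and one pull-back transform per frame
    (reference world -> frame world).  Frames whose optimization does not
    improve the cost are kept untransformed and flagged (``failed=True``).
    """
    from .image import resample  # local import: image <-> transforms layering

    b0_idx = np.flatnonzero(gtab.is_b0)
    if len(b0_idx) == 0:
        raise ValueError("no b0 frame (b < 50 s/mm^2) in gradient table")
    out = np.empty_like(dwi.data, dtype=float)
    motions: list[RigidTransform] = [None] * gtab.n_frames

    def align(frame, ref, levels):
        # b0 frames share the reference contrast and support a fine level;
        # diffusion-weighted frames are registered at half resolution only,
        # where the smoothing keeps their direction-dependent contrast from
        # dragging the fit
        T = register_rigid(frame, ref, cost="ncc", levels=levels, maxiter=6)
        if T.failed:
            return T, frame.data
        return T, resample(frame, T, ref, interp="trilinear").data

    # pass 1: b0 frames to the first b0 (the reference frame, identity
    # motion by definition); averaging unaligned b0s would bias the
    # reference toward any frame that moved
    first_b0 = dwi.frame(int(b0_idx[0]))
    motions[b0_idx[0]] = RigidTransform.identity()
    out[..., b0_idx[0]] = first_b0.data
    for f in b0_idx[1:]:
        motions[f], out[..., f] = align(dwi.frame(int(f)), first_b0, (2, 1))

    # pass 2: diffusion-weighted frames to the mean of the realigned b0s
    ref = Volume(out[..., b0_idx].mean(axis=3), dwi.affine)
    for f in range(gtab.n_frames):
        if motions[f] is not None:
            continue
        motions[f], out[..., f] = align(dwi.frame(f), ref, (2,))
    return Volume(out, dwi.affine.copy()), motions


def rotate_bvecs(gtab: GradientTable, motions: list[RigidTransform]) -> GradientTable:
    """Rotate gradient directions to compensate for per-frame realignment.

    A frame's pull-back motion maps reference coordinates to that frame's
    coordinates with rotation R; a scanner-frame encoding direction g is
    therefore R^T g when expressed in the realigned (reference) frame.  b0
    zero vectors are untouched; outputs are renormalized to unit length.
    """
    if len(motions) != gtab.n_frames:
        raise ValueError("need one motion transform per frame")
    bvecs = gtab.bvecs.copy()
    for f, T in enumerate(motions):
        if gtab.is_b0[f]:
            continue
        v = T.rotation.T @ bvecs[f]
        n = np.linalg.norm(v)
        if n > 0:
            bvecs[f] = v / n
    return GradientTable(gtab.bvals.copy(), bvecs)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor (6 unique components, mm^2/s).

    ``tensors`` stores (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) per voxel; voxels
    outside the fitted mask are NaN.  Eigenvalues are computed on demand,
    descending, with negative values clamped to 0 and flagged.
    """

    tensors: np.ndarray  # (nx, ny, nz, 6)
    s0: np.ndarray
    affine: np.ndarray
    mask: np.ndarray            # voxels with a valid fit
    clamped: np.ndarray = None  # voxels where eigenvalues were clamped
    _evals: np.ndarray = field(default=None, repr=False)

    def as_matrices(self) -> np.ndarray:
        t = self.tensors
        D = np.zeros(t.shape[:3] + (3, 3))
        D[..., 0, 0] = t[..., 0]
        D[..., 1, 1] = t[..., 1]
        D[..., 2, 2] = t[..., 2]
        D[..., 0, 1] = D[..., 1, 0] = t[..., 3]
        D[..., 0, 2] = D[..., 2, 0] = t[..., 4]
        D[..., 1, 2] = D[..., 2, 1] = t[..., 5]
        return D

    def eigenvalues(self) -> np.ndarray:
        """Descending eigenvalues per voxel; negatives clamped to 0 (flagged)."""
        if self._evals is not None:
            return self._evals
        D = self.as_matrices()
        flat = D.reshape(-1, 3, 3)
        valid = self.mask.reshape(-1)
        ev = np.zeros((flat.shape[0], 3))
        if valid.any():
            w = np.linalg.eigvalsh(flat[valid])  # ascending
            ev[valid] = w[:, ::-1]
        clamped = (ev < 0).any(axis=1) & valid
        ev = np.maximum(ev, 0.0)
        self._evals = ev.reshape(self.mask.shape + (3,))
        self.clamped = clamped.reshape(self.mask.shape)
        return self._evals


def fit_tensor_wls(
    dwi: Volume, gtab: GradientTable, mask: BinaryMask
) -> TensorField:
    """Weighted-least-squares tensor fit inside a brain mask.

    Per voxel: OLS on the log signals first, then one weighted pass with
    weights equal to the squared predicted signals.  Non-positive signals are
    excluded from that voxel's fit (their log is undefined); voxels with
    fewer than 7 usable measurements are marked unfittable.
    """
    if gtab.n_unique_directions < 6:
        raise ValueError(">=6 unique non-b0 directions required for tensor fit")
    if not mask.data.any():
        raise ValueError("brain mask is empty")
    if dwi.data.shape[3] != gtab.n_frames:
        raise ValueError("DWI frame count does not match gradient table")

    g = gtab.bvecs
    b = gtab.bvals
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )  # (n_frames, 7)

    vox = mask.data
    S = dwi.data[vox]  # (n_vox, n_frames)
    valid = S > 0
    usable = valid.sum(axis=1) >= 7
    logS = np.where(valid, np.log(np.maximum(S, 1e-30)), 0.0)

    def solve(weights):
        # batched weighted normal equations: (X^T W X) beta = X^T W y
        W = weights * valid
        XtWX = np.einsum("vf,fi,fj->vij", W, X, X)
        XtWy = np.einsum("vf,fi,vf->vi", W, X, logS)
        XtWX += 1e-12 * np.eye(7)
        return np.linalg.solve(XtWX, XtWy[..., None])[..., 0]

    beta = solve(np.ones_like(S))
    pred = np.exp(beta @ X.T)
    beta = solve(pred**2)

    shape = mask.shape3
    tensors = np.full(shape + (6,), np.nan)
    s0 = np.zeros(shape)
    fitmask = np.zeros(shape, dtype=bool)
    flat_idx = np.argwhere(vox)[usable]
    tensors[flat_idx[:, 0], flat_idx[:, 1], flat_idx[:, 2]] = beta[usable, 1:]
    s0[flat_idx[:, 0], flat_idx[:, 1], flat_idx[:, 2]] = np.exp(beta[usable, 0])
    fitmask[flat_idx[:, 0], flat_idx[:, 1], flat_idx[:, 2]] = True
    return TensorField(tensors, s0, mask.affine.copy(), fitmask)


def fa_from_tensor(t: TensorField) -> Volume:
    """Fractional anisotropy map in [0, 1]; unfittable or all-zero voxels -> 0."""
    ev = t.eigenvalues()
    mean = ev.mean(axis=-1, keepdims=True)
    num = ((ev - mean) ** 2).sum(axis=-1)
    den = (ev**2).sum(axis=-1)
    fa = np.zeros(ev.shape[:3])
    nz = den > 0
    fa[nz] = np.sqrt(1.5 * num[nz] / den[nz])
    fa = np.clip(fa, 0.0, 1.0)
    fa[~t.mask] = 0.0
    return Volume(fa, t.affine.copy())
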