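"""Tissue segmentation and anatomy-restricted tract / boundary segmentation.

The T1 image, back-projected into native diffusion space, is segmented into
CSF/GM/WM by a 3-class Gaussian-mixture EM on intensities (classes assigned
by ascending mean intensity, valid for T1 contrast).  The WM posterior is
thresholded at 0.8 to build the WM map that restricts atlas tracts to the
underlying anatomy; the same threshold re-binarizes warped tract masks to
exclude partial-volume boundary voxels.  Boundary masks are one-voxel WM
shells split into WM/CSF and WM/GM classes by dilated-CSF cross-masking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .image import (
    BinaryMask,
    Volume,
    cross_mask,
    dilate,
    erode,
    resample,
    subtract_mask,
    threshold_binarize,
)

__all__ = [
    "TissueProbMaps",
    "ROIAtlas",
    "BoundarySet",
    "segment_tissues",
    "make_wm_mask",
    "segment_tract",
    "segment_wm_boundary",
    "split_boundary",
    "tract_boundary",
    "SegmentationError",
]

WM_THRESHOLD = 0.8      # WM posterior cut excluding partial-volume voxels
TRACT_THRESHOLD = 0.8   # re-binarization cut for warped tract masks
CSF_THRESHOLD = 0.8     # CSF posterior cut for boundary splitting


class SegmentationError(RuntimeError):
    pass


@dataclass
class TissueProbMaps:
    """CSF/GM/WM posterior probability maps on a common grid."""

    csf: Volume
    gm: Volume
    wm: Volume


@dataclass
class ROIAtlas:
    """Integer-coded tract label volume in template space plus a label table."""

    labels: Volume
    names: dict  # code -> tract name

    def __post_init__(self) -> None:
        codes = np.unique(self.labels.data)
        codes = codes[codes != 0]
        if not np.allclose(codes, np.round(codes)):
            raise ValueError("atlas label volume must be integer-coded")
        missing = [int(c) for c in codes if int(c) not in self.names]
        if missing:
            raise ValueError(f"atlas codes without names: {missing}")

    @property
    def codes(self) -> list:
        codes = np.unique(self.labels.data)
        return [int(c) for c in codes if c != 0]

    def binary(self, code: int) -> BinaryMask:
        if code not in self.codes:
            raise KeyError(f"code {code} not present in atlas")
        return BinaryMask(self.labels.data == code, self.labels.affine.copy())

    # -- label-table I/O (TSV: code <tab> name) ----------------------------
    def save_table(self, path) -> None:
        pd.DataFrame(
            {"code": list(self.names), "name": list(self.names.values())}
        ).to_csv(path, sep="\t", index=False)

    @staticmethod
    def load_table(path) -> dict:
        df = pd.read_csv(path, sep="\t")
        return {int(c): str(n) for c, n in zip(df["code"], df["name"])}


@dataclass
class BoundarySet:
    """Whole-brain WM boundary and its partition into WM/CSF and WM/GM."""

    whole_wm_boundary: BinaryMask
    wm_csf_boundary: BinaryMask
    wm_gm_boundary: BinaryMask


def _poly_design(idx: np.ndarray, shape, order: int = 2) -> np.ndarray:
    c = (np.asarray(shape) - 1) / 2.0
    x = (idx - c) / np.maximum(c, 1.0)
    cols = [np.ones(len(x))]
    for k in range(3):
        cols.append(x[:, k])
    if order >= 2:
        for k in range(3):
            cols.append(x[:, k] ** 2)
        cols.append(x[:, 0] * x[:, 1])
        cols.append(x[:, 0] * x[:, 2])
        cols.append(x[:, 1] * x[:, 2])
    return np.column_stack(cols)


def _bias_from_residuals(
    vals: np.ndarray, class_means: np.ndarray, resp: np.ndarray,
    idx: np.ndarray, shape, order: int = 2,
) -> np.ndarray:
    """Coarse polynomial log-domain bias field estimated on class residuals.

    Fitting the polynomial to ``log I - log mu_class`` (expected class mean
    under the current posteriors) removes smooth scanner inhomogeneity
    without absorbing genuine anatomical contrast, which itself varies
    smoothly across the head.
    """
    pred = np.log(np.maximum(resp @ class_means, 1e-6))
    resid = np.log(np.maximum(vals, 1e-6)) - pred
    A = _poly_design(idx, shape, order)
    coef, *_ = np.linalg.lstsq(A, resid, rcond=None)
    bias = A @ coef
    return bias - bias.mean()


def segment_tissues(
    t1_in_dwi: Volume,
    brain_mask: BinaryMask,
    smooth_posteriors_vox: float = 0.5,
    bias_correct: bool = True,
    contrast: str = "t1",
) -> TissueProbMaps:
    """3-class Gaussian-mixture EM tissue segmentation of a T1 image.

    Classes are ordered by mean intensity and assigned CSF < GM < WM, which
    holds for T1 contrast only; other contrasts are rejected.  Posteriors
    are optionally smoothed (sigma 1 voxel) and renormalized as a light
    spatial regularization.  EM is initialized from intensity quantiles and
    is fully deterministic; a degenerate fit (a class collapsing below 0.5%
    of voxels) is re-initialized once from different quantiles, and a second
    failure raises :class:`SegmentationError`.
    """
    if contrast != "t1":
        raise ValueError("only T1 contrast supported (class order CSF<GM<WM)")
    if not brain_mask.data.any():
        raise SegmentationError("brain mask is empty")
    data = t1_in_dwi.data.astype(float)
    vals = data[brain_mask.data].reshape(-1, 1)
    if np.ptp(vals) < 1e-9:
        raise SegmentationError("degenerate intensity distribution (single value)")

    def fit(quantiles):
        means = np.quantile(vals, quantiles).reshape(-1, 1)
        gmm = GaussianMixture(
            n_components=3,
            covariance_type="full",
            means_init=means,
            max_iter=200,
            tol=1e-5,
            reg_covar=1e-6,
            random_state=0,
            n_init=1,
        )
        gmm.fit(vals)
        post = gmm.predict_proba(vals)
        frac = post.sum(axis=0) / len(vals)
        return gmm, post, frac

    gmm, post, frac = fit([0.1, 0.5, 0.9])
    if frac.min() < 0.005:
        gmm, post, frac = fit([0.25, 0.5, 0.75])
        if frac.min() < 0.005:
            raise SegmentationError("EM degenerate: a tissue class collapsed")

    if bias_correct:
        # one bias-refinement round: estimate a smooth polynomial field from
        # class residuals, divide it out, refit
        idx = np.argwhere(brain_mask.data).astype(float)
        bias = _bias_from_residuals(
            vals.ravel(), gmm.means_.ravel(), post, idx, t1_in_dwi.shape3
        )
        vals = (vals.ravel() * np.exp(-bias)).reshape(-1, 1)
        gmm, post, frac = fit([0.1, 0.5, 0.9])
        if frac.min() < 0.005:
            raise SegmentationError("EM degenerate after bias refinement")

    order = np.argsort(gmm.means_.ravel())  # ascending: CSF, GM, WM
    maps = []
    for cls in order:
        p = np.zeros(t1_in_dwi.shape3)
        p[brain_mask.data] = post[:, cls]
        maps.append(p)
    if smooth_posteriors_vox and smooth_posteriors_vox > 0:
        sm = [ndimage.gaussian_filter(p, smooth_posteriors_vox) for p in maps]
        total = np.maximum(sum(sm), 1e-12)
        maps = [np.where(brain_mask.data, p / total, 0.0) for p in sm]
    aff = t1_in_dwi.affine.copy()
    return TissueProbMaps(
        csf=Volume(maps[0], aff), gm=Volume(maps[1], aff), wm=Volume(maps[2], aff)
    )


def make_wm_mask(wm_prob: Volume, thr: float = WM_THRESHOLD) -> BinaryMask:
    """Threshold the WM posterior (default 0.8, inclusive) and binarize."""
    return threshold_binarize(wm_prob, thr)


def segment_tract(
    atlas: ROIAtlas,
    code: int,
    chain,
    wm_mask: BinaryMask,
    reference: Volume | None = None,
    pre_erode: int = 1,
    wm_erode: int = 1,
    tract_threshold: float = TRACT_THRESHOLD,
    interp: str = "trilinear",
) -> tuple[BinaryMask, bool]:
    """Anatomy-restricted segmentation of one atlas tract in native space.

    Pipeline: (a) extract the binary tract from the atlas; (b) erode
    ``pre_erode`` single-voxel passes in template space; (c) warp to the
    native grid as a probability (trilinear on the 0/1 mask); (d) threshold
    at 0.8 and binarize; (e) cross-mask with the WM map, eroded
    ``wm_erode - 1`` extra passes (``wm_erode=2`` is the conservative
    variant).

    Returns ``(mask, empty_flag)``; an empty output is a success with the
    flag raised (small structures may legitimately vanish), never an error.
    """
    if reference is None:
        reference = wm_mask.to_volume()
    tract = atlas.binary(code)
    tract = erode(tract, pre_erode)
    prob = resample(
        tract.to_volume(), chain, reference,
        interp="trilinear" if interp == "trilinear" else "nearest",
    )
    if interp == "trilinear":
        prob.data[:] = np.clip(prob.data, 0.0, 1.0)
        native = threshold_binarize(prob, tract_threshold)
    else:
        native = BinaryMask(prob.data > 0.5, prob.affine)
    wm = erode(wm_mask, max(wm_erode - 1, 0))
    out = cross_mask(native, wm)
    return out, out.n_voxels == 0


def segment_wm_boundary(wm_mask: BinaryMask) -> BinaryMask:
    """One-voxel-thick WM shell: the mask minus its single-pass erosion."""
    if not wm_mask.data.any():
        return BinaryMask(np.zeros(wm_mask.shape3, bool), wm_mask.affine.copy())
    return subtract_mask(wm_mask, erode(wm_mask, 1))


def split_boundary(wm_boundary: BinaryMask, csf_mask: BinaryMask) -> BoundarySet:
    """Partition the WM boundary into WM/CSF and WM/GM classes.

    WM/CSF = dilated CSF mask AND the boundary; WM/GM = the remainder.  The
    two classes are disjoint and their union is the whole boundary by
    construction.
    """
    wm_csf = cross_mask(dilate(csf_mask, 1), wm_boundary)
    wm_gm = subtract_mask(wm_boundary, wm_csf)
    return BoundarySet(
        whole_wm_boundary=wm_boundary, wm_csf_boundary=wm_csf, wm_gm_boundary=wm_gm
    )


def tract_boundary(
    tract: BinaryMask, boundaries: BoundarySet
) -> tuple[BinaryMask, BinaryMask, bool]:
    """Per-tract WM/GM and WM/CSF boundary masks.

    Returns ``(wm_gm, wm_csf, empty_flag)``; empty intersections are allowed
    (small tracts have no boundary voxels) and flagged.  Boundary sampling is
    only meaningful for large tracts.
    """
    wm_gm = cross_mask(tract, boundaries.wm_gm_boundary)
    wm_csf = cross_mask(tract, boundaries.wm_csf_boundary)
    flag = wm_gm.n_voxels == 0 and wm_csf.n_voxels == 0
    if flag:
        warnings.warn("tract has no boundary voxels", stacklevel=2)
    return wm_gm, wm_csf, flag
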