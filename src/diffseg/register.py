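"""Spatial alignment: rigid pre-alignment, boundary-based refinement (BBR),
small-deformation nonlinear warping, and transform-chain assembly.

All estimators are deterministic given their inputs: fixed multi-resolution
schedules, derivative-free Powell optimization, no random restarts.  Cost
functions follow modality: correlation ratio for cross-modal rigid alignment,
normalized correlation for same-modality frame realignment, a tanh boundary
contrast for BBR, and sum-of-squared differences for the nonlinear stage.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, optimize

from .image import Volume, BinaryMask
from .transforms import (
    AffineTransform,
    RigidTransform,
    TransformChain,
    Warp,
    invert_warp,
    params_from_rigid,
    rigid_from_params,
)

__all__ = [
    "rigid_prealign",
    "register_rigid",
    "bbr_refine",
    "bbr_cost",
    "affine_align",
    "nonlinear_to_template",
    "build_native_chain",
    "invert_warp",
]

# BBR constants: sampling offsets along the boundary normal, tanh slope on
# percent contrast, and the cap on boundary sample sites.  The slope keeps
# typical WM/GM contrasts (tens of percent) out of deep tanh saturation (a
# saturated cost is flat near the optimum and lets the transform drift), and
# averaging a 1 mm offset (inside the partial-volume ramp of a 2 mm b0,
# hence sensitive to sub-voxel shifts) with a 2 mm offset (purer tissue
# samples) keeps the cost both sharp and well-posed.
BBR_OFFSETS_MM = (1.0, 2.0)
BBR_SLOPE = 0.05
BBR_MAX_SITES = 5000
BBR_MIN_SITES = 100


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _smooth(data: np.ndarray, sigma_vox: float) -> np.ndarray:
    if sigma_vox <= 0:
        return data
    return ndimage.gaussian_filter(data.astype(float), sigma_vox)


def _level_samples(fixed: Volume, factor: int):
    """Smoothed + strided fixed-image samples for one pyramid level.

    Returns (world points (n,3), intensities (n,)) restricted to the
    foreground (above 5% of max) of the smoothed fixed image.
    """
    sm = _smooth(fixed.data, 0.5 * factor)
    sl = (slice(None, None, factor),) * 3
    idx = np.indices(fixed.shape3, dtype=float)
    pts = np.stack([idx[0][sl], idx[1][sl], idx[2][sl]], axis=-1).reshape(-1, 3)
    vals = sm[sl].reshape(-1)
    keep = vals > 0.05 * vals.max() if vals.max() > 0 else np.ones_like(vals, bool)
    pts = pts[keep] @ fixed.affine[:3, :3].T + fixed.affine[:3, 3]
    return pts, vals[keep]


def _sample(vol_data: np.ndarray, affine: np.ndarray, pts_world: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    ijk = pts_world @ inv[:3, :3].T + inv[:3, 3]
    return ndimage.map_coordinates(vol_data, ijk.T, order=1, mode="constant", cval=0.0)


def _cost_ncc(f: np.ndarray, m: np.ndarray) -> float:
    """1 - Pearson correlation (same-modality)."""
    fd = f - f.mean()
    md = m - m.mean()
    denom = np.sqrt((fd**2).sum() * (md**2).sum())
    if denom < 1e-12:
        return 1.0
    return float(1.0 - (fd * md).sum() / denom)


def _cost_cr(f: np.ndarray, m: np.ndarray, n_bins: int = 32) -> float:
    """1 - correlation ratio of moving intensities conditioned on fixed bins."""
    var_m = m.var()
    if var_m < 1e-12:
        return 1.0
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return 1.0
    bins = np.clip(((f - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    n_k = np.bincount(bins, minlength=n_bins)
    s_k = np.bincount(bins, weights=m, minlength=n_bins)
    s2_k = np.bincount(bins, weights=m * m, minlength=n_bins)
    nz = n_k > 0
    within = (s2_k[nz] - s_k[nz] ** 2 / n_k[nz]).sum() / len(m)
    return float(within / var_m)


_COSTS = {"ncc": _cost_ncc, "cr": _cost_cr}

# Powell search directions: ~0.05 rad for rotations, 2 mm for translations.
_RIGID_DIREC = np.diag([0.05, 0.05, 0.05, 2.0, 2.0, 2.0])


def _fov_center(vol: Volume) -> np.ndarray:
    c_idx = (np.asarray(vol.shape3, float) - 1) / 2.0
    return vol.affine[:3, :3] @ c_idx + vol.affine[:3, 3]


def register_rigid(
    moving: Volume,
    fixed: Volume,
    init: RigidTransform | None = None,
    cost: str = "cr",
    levels=(4, 2, 1),
    maxiter: int = 10,
    xtol: float = 1e-3,
    ftol: float = 1e-4,
) -> RigidTransform:
    """6-DOF intensity registration by multi-resolution Powell descent.

    Returns the pull-back map (fixed world -> moving world) that resamples
    ``moving`` onto the grid of ``fixed``.  ``failed`` is set on the result
    if no level improved on the initial cost.  The search is bounded to
    +/- 20 degrees and +/- 25 mm around the init — inputs are expected to be
    roughly oriented, and an unbounded search can lock onto flipped poses
    of approximately symmetric heads.
    """
    cost_fn = _COSTS[cost]
    center = _fov_center(fixed)
    init = init if init is not None else RigidTransform.identity()
    params = params_from_rigid(init, center)
    lo = params - np.array([0.35] * 3 + [25.0] * 3)
    hi = params + np.array([0.35] * 3 + [25.0] * 3)

    def in_bounds(p):
        return bool(np.all(p >= lo) and np.all(p <= hi))

    opts = {"xtol": xtol, "ftol": ftol, "maxiter": maxiter}

    improved = False
    for factor in levels:
        pts, fvals = _level_samples(fixed, factor)
        mv_sm = _smooth(moving.data, 0.5 * factor)

        def fun(p):
            T = rigid_from_params(p, center)
            m = _sample(mv_sm, moving.affine, T.apply_points(pts))
            return cost_fn(fvals, m)

        c0 = fun(params)
        res = optimize.minimize(
            fun, params, method="Powell",
            options={**opts, "direc": _RIGID_DIREC.copy()},
        )
        if not in_bounds(res.x):
            # the unbounded line searches locked onto a distant (typically
            # flipped) pose; redo the level inside the trust region, then
            # polish unbounded from within the right basin
            res = optimize.minimize(
                fun, params, method="Powell",
                bounds=list(zip(lo, hi)),
                options={**opts, "direc": _RIGID_DIREC.copy()},
            )
            res = optimize.minimize(
                fun, res.x, method="Powell",
                options={**opts, "direc": _RIGID_DIREC.copy()},
            )
            if not in_bounds(res.x):
                continue
        if res.fun < c0 - 1e-12:
            params = res.x
            improved = True

    if not improved:
        out = RigidTransform(init.matrix.copy())
        out.failed = True
        return out
    return rigid_from_params(params, center)


def rigid_prealign(
    moving: Volume, fixed: Volume, init: RigidTransform | None = None
) -> RigidTransform:
    """Cross-modal 6-DOF pre-alignment (correlation-ratio cost).

    Used for the initial alignment of the diffusion b0 (EPI) to the
    skull-stripped T1; both inputs must be brain-extracted with overlapping
    fields of view.  Deterministic given inputs and init.
    """
    return register_rigid(moving, fixed, init=init, cost="cr")


# ---------------------------------------------------------------------------
# Boundary-based registration
# ---------------------------------------------------------------------------

def _boundary_sites(wm_mask: BinaryMask, max_sites: int = BBR_MAX_SITES):
    """Boundary sample sites (world mm) and outward unit normals.

    Sites are the one-voxel shell of the WM mask; normals come from the
    gradient of the signed distance transform (positive outside), evaluated
    at the shell voxels, expressed in world space.
    """
    m = wm_mask.data
    shell = m & ~ndimage.binary_erosion(m, np.ones((3, 3, 3)), border_value=0)
    # signed distance: positive outside WM, negative inside
    d_out = ndimage.distance_transform_edt(~m, sampling=wm_mask.voxel_size)
    d_in = ndimage.distance_transform_edt(m, sampling=wm_mask.voxel_size)
    sdist = d_out - d_in
    grads = np.gradient(sdist, *wm_mask.voxel_size)
    ijk = np.argwhere(shell)
    g = np.stack([grads[k][shell] for k in range(3)], axis=-1)
    sd = sdist[shell]
    norms = np.linalg.norm(g, axis=1)
    ok = norms > 1e-6
    ijk, g, norms, sd = ijk[ok], g[ok], norms[ok], sd[ok]
    # voxel-space gradient direction -> world direction
    n_world = (g / norms[:, None]) @ np.linalg.inv(wm_mask.affine[:3, :3]).T
    n_world /= np.maximum(np.linalg.norm(n_world, axis=1), 1e-12)[:, None]
    pts = ijk @ wm_mask.affine[:3, :3].T + wm_mask.affine[:3, 3]
    # project shell-voxel centres (which lie ~half a voxel inside the mask)
    # onto the zero level of the signed distance: an inward-biased site set
    # would bias the whole registration outward by the same amount
    pts = pts - sd[:, None] * n_world
    if len(pts) > max_sites:  # deterministic decimation
        step = int(np.ceil(len(pts) / max_sites))
        pts, n_world = pts[::step], n_world[::step]
    return pts, n_world


def bbr_cost(
    b0: Volume,
    transform: RigidTransform,
    sites: np.ndarray,
    normals: np.ndarray,
    offset_mm: float = 2.0,
    slope: float = BBR_SLOPE,
):
    """Mean boundary cost 1 - tanh(M*Q) over usable sites at one offset.

    Q is the percent contrast 100*(I_out - I_in)/(0.5*(I_out + I_in)) sampled
    at +/- ``offset_mm`` along the boundary normal after mapping the T1-space
    sites into b0 space.  On a b0 (T2-weighted EPI) image tissue outside the
    WM boundary is brighter than WM, so positive Q is rewarded.  Sites that
    leave the b0 field of view contribute the worst cost (2.0) rather than
    being dropped — shrinking the usable set must never look like an
    improvement.  Returns (cost, n_usable).
    """
    p_in = transform.apply_points(sites - offset_mm * normals)
    p_out = transform.apply_points(sites + offset_mm * normals)
    i_in = _sample(b0.data, b0.affine, p_in)
    i_out = _sample(b0.data, b0.affine, p_out)
    mean = 0.5 * (i_in + i_out)
    usable = mean > 1e-6
    if usable.sum() == 0:
        return 2.0, 0
    q = 100.0 * (i_out[usable] - i_in[usable]) / mean[usable]
    per_site = np.full(len(sites), 2.0)
    per_site[usable] = 1.0 - np.tanh(slope * q)
    return float(per_site.mean()), int(usable.sum())


def bbr_refine(
    b0: Volume,
    t1: Volume,
    wm_mask: BinaryMask,
    init: RigidTransform,
    offsets_mm: tuple = BBR_OFFSETS_MM,
    slope: float = BBR_SLOPE,
) -> RigidTransform:
    """Boundary-based refinement of the T1->b0 rigid alignment.

    Drives the 6-DOF transform so that the intensity contrast of the b0
    image across the T1-derived WM boundary is maximal (cost averaged over
    the sampling offsets in ``offsets_mm``); refuses (returns ``init`` with
    ``failed=True``) when fewer than 100 usable boundary sites exist, which
    signals an upstream segmentation failure.  The returned transform never
    has a worse boundary cost than ``init``.

    Sites whose outward sample falls in CSF (dark on the T1) are excluded up
    front: boundary contrast drives alignment where grey and white matter
    are differentiated, and the very bright CSF of a b0 image otherwise
    biases the optimum toward the ventricles.
    """
    sites, normals = _boundary_sites(wm_mask)
    if len(sites):
        t1_out = _sample(t1.data, t1.affine, sites + max(offsets_mm) * normals)
        inside = t1.data[wm_mask.data]
        wm_level = np.median(inside) if inside.size else 0.0
        gm_like = t1_out > 0.45 * wm_level  # CSF is far darker than GM on T1
        if gm_like.sum() >= BBR_MIN_SITES:
            sites, normals = sites[gm_like], normals[gm_like]

    def cost_of(T):
        costs, ns = [], []
        for d in offsets_mm:
            c, n = bbr_cost(b0, T, sites, normals, d, slope)
            costs.append(c)
            ns.append(n)
        return float(np.mean(costs)), min(ns)

    c_init, n_init = cost_of(init)
    if n_init < BBR_MIN_SITES:
        out = RigidTransform(init.matrix.copy())
        out.failed = True
        return out

    center = _fov_center(t1)
    p0 = params_from_rigid(init, center)

    def fun(p):
        c, n = cost_of(rigid_from_params(p, center))
        return 2.0 if n < BBR_MIN_SITES else c

    # deterministic coarse pre-search over translations around the init:
    # a few millimetres of displacement can put Powell in a spurious valley
    # of the boundary cost, while the true basin is easily found on a grid
    best_p, best_c = p0.copy(), fun(p0)
    steps = (-3.0, -1.5, 0.0, 1.5, 3.0)
    for dx in steps:
        for dy in steps:
            for dz in steps:
                q = p0 + np.array([0, 0, 0, dx, dy, dz])
                c = fun(q)
                if c < best_c:
                    best_p, best_c = q, c

    res = optimize.minimize(
        fun,
        best_p,
        method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-6, "maxiter": 10, "direc": _RIGID_DIREC.copy()},
    )
    if res.fun < c_init:
        return rigid_from_params(res.x, center)
    out = RigidTransform(init.matrix.copy())
    out.failed = True
    return out


# ---------------------------------------------------------------------------
# Affine (9/12-DOF) initialization for template alignment
# ---------------------------------------------------------------------------

def _affine_from_params(p: np.ndarray, center: np.ndarray) -> AffineTransform:
    """rotations (3), translations (3), log-scales (3), shears (3)."""
    rig = rigid_from_params(p[:6], None)
    S = np.diag(np.exp(p[6:9]))
    Sh = np.eye(3)
    Sh[0, 1], Sh[0, 2], Sh[1, 2] = p[9], p[10], p[11]
    A = rig.matrix[:3, :3] @ Sh @ S
    M = np.eye(4)
    M[:3, :3] = A
    t = rig.matrix[:3, 3]
    M[:3, 3] = t + center - A @ center
    return AffineTransform(M)


def affine_align(
    moving: Volume,
    fixed: Volume,
    init: RigidTransform | None = None,
    cost: str = "ncc",
    levels=(4, 2),
) -> AffineTransform:
    """12-DOF affine registration (rigid + scale + shear), Powell descent.

    Used to initialize template alignment where head sizes differ; the
    nonlinear stage absorbs the remainder.  Rotations are bounded to ~25
    degrees, scales to +/-35% and shears to +/-0.2 around the init: template
    alignment starts roughly oriented, and an unbounded affine search can
    lock onto flipped poses of approximately symmetric heads.
    """
    cost_fn = _COSTS[cost]
    center = _fov_center(fixed)
    p = np.zeros(12)
    if init is not None:
        p[:6] = params_from_rigid(init, center)
    direc = np.diag([0.05] * 3 + [2.0] * 3 + [0.05] * 3 + [0.02] * 3)
    bounds = (
        [(pi - 0.45, pi + 0.45) for pi in p[:3]]
        + [(pi - 25.0, pi + 25.0) for pi in p[3:6]]
        + [(-0.3, 0.3)] * 3
        + [(-0.2, 0.2)] * 3
    )
    for factor in levels:
        pts, fvals = _level_samples(fixed, factor)
        mv_sm = _smooth(moving.data, 0.5 * factor)

        def fun(q):
            T = _affine_from_params(q, center)
            return cost_fn(fvals, _sample(mv_sm, moving.affine, T.apply_points(pts)))

        res = optimize.minimize(
            fun, p, method="Powell", bounds=bounds,
            options={"xtol": 1e-3, "ftol": 1e-5, "maxiter": 8, "direc": direc.copy()},
        )
        if res.fun < fun(p):
            p = res.x
    return _affine_from_params(p, center)


# ---------------------------------------------------------------------------
# Small-deformation nonlinear registration (demons-style SSD)
# ---------------------------------------------------------------------------

def _normalize(data: np.ndarray) -> np.ndarray:
    hi = np.percentile(data[data > 0], 99.5) if (data > 0).any() else 1.0
    return np.clip(data / max(hi, 1e-12), 0.0, 1.2)


def nonlinear_to_template(
    t1: Volume,
    template: Volume,
    levels=(4, 2, 1),
    iters_per_level: int = 50,
    sigma_reg_vox: float = 2.0,
    sigma_fluid_vox: float = 1.0,
    affine_init: AffineTransform | None = None,
    init_warp: Warp | None = None,
) -> Warp:
    """Register a skull-stripped T1 to a template; return the pull-back warp.

    A 12-DOF affine initialization is followed by multi-resolution
    demons-style descent on the sum-of-squared differences, with Gaussian
    smoothing (sigma ``sigma_reg_vox`` voxels) regularizing the displacement
    field each iteration.  Intensities are normalized to [0, 1] internally.
    If the cost increases for 3 consecutive iterations at a level, descent
    stops there and the best field so far is kept (with a warning).

    The returned :class:`Warp` lives on the template grid and maps template
    world coordinates to T1 world coordinates, i.e. it resamples the T1 onto
    the template directly.
    """
    f_full = _normalize(template.data)
    m_full = _normalize(t1.data)
    if init_warp is not None and affine_init is None:
        affine_init = init_warp.affine
    if affine_init is None:
        affine_init = affine_align(
            Volume(m_full, t1.affine), Volume(f_full, template.affine)
        )

    # displacement in mm on the current level grid; optionally seeded from a
    # previous estimate (e.g. a more strongly regularized pass)
    u = init_warp.displacement if init_warp is not None else None
    u_affine = init_warp.grid_affine if init_warp is not None else None
    for factor in levels:
        f_sm = _smooth(f_full, 0.5 * factor)
        m_sm = _smooth(m_full, 0.5 * factor)
        sl = (slice(None, None, factor),) * 3
        f_lvl = f_sm[sl]
        lvl_affine = template.affine.copy()
        lvl_affine[:3, :3] *= factor
        vox = np.sqrt((lvl_affine[:3, :3] ** 2).sum(axis=0))

        idx = np.indices(f_lvl.shape, dtype=float)
        pts = np.stack([idx[0], idx[1], idx[2]], axis=-1).reshape(-1, 3)
        pts_w = pts @ lvl_affine[:3, :3].T + lvl_affine[:3, 3]
        base = affine_init.apply_points(pts_w)

        grads = np.gradient(f_lvl, *vox)  # fixed-image gradient, 1/mm
        g = np.stack([gr.reshape(-1) for gr in grads], axis=-1)
        g2 = (g**2).sum(axis=1)
        f_flat = f_lvl.reshape(-1)

        if u is None:
            u_flat = np.zeros_like(pts_w)
        else:  # carry displacement up from the previous (coarser) level
            prev = Warp(u, u_affine)
            u_flat = prev.displacement_at(pts_w)

        best_u = u_flat.copy()
        best_ssd = np.inf
        prev_ssd = np.inf
        worse_streak = 0
        for _ in range(iters_per_level):
            warped = _sample(m_sm, t1.affine, base + u_flat)
            diff = f_flat - warped
            ssd = float((diff**2).sum())
            if ssd < best_ssd:
                best_ssd = ssd
                best_u = u_flat.copy()
            worse_streak = worse_streak + 1 if ssd > prev_ssd else 0
            prev_ssd = ssd
            if worse_streak >= 3:
                warnings.warn(
                    "nonlinear registration diverging; keeping best field",
                    stacklevel=2,
                )
                break
            denom = g2 + diff**2
            step = np.where(denom > 1e-9, diff / np.maximum(denom, 1e-9), 0.0)
            force = g * step[:, None]
            # cap the per-iteration update at one voxel to keep the field
            # smooth enough to remain invertible
            fnorm = np.linalg.norm(force, axis=1)
            cap = float(vox.min())
            big = fnorm > cap
            force[big] *= (cap / fnorm[big])[:, None]
            # fluid-like smoothing of the update, then diffusion-like
            # smoothing of the accumulated field
            fshape = f_lvl.shape + (3,)
            force = force.reshape(fshape)
            for k in range(3):
                force[..., k] = _smooth(force[..., k], sigma_fluid_vox)
            u_field = (u_flat + force.reshape(-1, 3)).reshape(fshape)
            for k in range(3):
                u_field[..., k] = _smooth(u_field[..., k], sigma_reg_vox)
            u_flat = u_field.reshape(-1, 3)
        u = best_u.reshape(f_lvl.shape + (3,))
        u_affine = lvl_affine

    # materialize on the full-resolution template grid
    if u_affine.shape != template.affine.shape or not np.allclose(u_affine, template.affine):
        prev = Warp(u, u_affine)
        idx = np.indices(template.shape3, dtype=float)
        pts = np.stack([idx[0], idx[1], idx[2]], axis=-1).reshape(-1, 3)
        pts_w = pts @ template.affine[:3, :3].T + template.affine[:3, 3]
        u = prev.displacement_at(pts_w).reshape(template.shape3 + (3,))
    return Warp(u, template.affine.copy(), affine=affine_init)


# ---------------------------------------------------------------------------
# Chain assembly
# ---------------------------------------------------------------------------

def build_native_chain(
    warp_t1_to_template: Warp, bbr_b0_to_t1: RigidTransform
) -> tuple[TransformChain, RigidTransform]:
    """Compose the one-step template->native-DWI transform.

    Parameters
    ----------
    warp_t1_to_template : Warp
        The T1-to-template registration, stored as the pull-back map
        template world -> T1 world.
    bbr_b0_to_t1 : RigidTransform
        The BBR b0-to-T1 registration, stored as the pull-back map
        T1 world -> b0 world.

    Returns
    -------
    chain : TransformChain
        Pull-back map b0 world -> template world: resamples template-space
        images (atlas labels) directly onto the native DWI grid.  This is
        the inverse of the concatenated (warp then BBR) forward transform.
    inv_bbr : RigidTransform
        Pull-back map b0 world -> T1 world, used to back-project the T1
        image onto the native b0 grid.
    """
    inv_bbr = bbr_b0_to_t1.inverse()
    inv_warp = invert_warp(warp_t1_to_template)
    return TransformChain([inv_bbr, inv_warp]), inv_bbr
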