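"""Synthetic multimodal ground-truth phantoms.

Builds a digital subject with nested ellipsoidal tissue compartments
(CSF shell, GM shell, WM core, CSF ventricles) and six embedded WM tracts of
graded size — a large callosal-like slab, two medium corticospinal-like
cylinders, two thin cingulum-like bars and a small fragile fornix-like
bridge next to the ventricles.  Each voxel carries a ground-truth diffusion
tensor (prolate in WM, oriented along the tract axis; nearly isotropic GM;
high-diffusivity isotropic CSF).  From this truth the generator renders

* a noise-free "standard template" T1 (1 mm grid, template space),
* a subject T1 (1 mm grid) displaced from template space by a smooth
  analytic sinusoidal warp, with Gaussian noise,
* a DWI series (2 mm grid, 64 directions at b=1000 s/mm^2 plus 4 b0
  frames) in a space related to the T1 by a known rigid transform, with
  Rician magnitude noise (default SNR 20 at b0 in WM),

plus the tract atlas in template space and every ground-truth transform.
Identical seeds yield bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage

from .dwi import GradientTable
from .image import BinaryMask, Volume, resample, threshold_binarize
from .segment import ROIAtlas, segment_tract
from .transforms import RigidTransform, TransformChain, rigid_from_params

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "PhantomSession",
    "AnalyticWarp",
    "make_phantom",
    "add_rician_noise",
    "simulate_visits",
    "fibonacci_directions",
    "truth_native_chain",
    "truth_wm_mask",
    "truth_native_tract",
]

# tissue codes in the truth label field
BG, CSF, GM, WM = 0, 1, 2, 3

T1_MEANS = {CSF: 50.0, GM: 120.0, WM: 200.0}     # T1-weighted contrast
S0_MEANS = {CSF: 850.0, GM: 550.0, WM: 350.0}    # b0 (T2-weighted EPI) contrast

# diffusivities (mm^2/s) and anisotropies per compartment
MD_WM, MD_GM, MD_CSF = 0.75e-3, 0.80e-3, 3.0e-3
FA_GM = 0.15
FA_WM_DEFAULT = 0.50

TRACTS = {
    # code: (name, FA, principal axis)
    1: ("cc_slab", 0.85, (1.0, 0.0, 0.0)),
    2: ("cst_left", 0.75, (0.0, 0.0, 1.0)),
    3: ("cst_right", 0.75, (0.0, 0.0, 1.0)),
    4: ("cingulum_left", 0.70, (0.0, 1.0, 0.0)),
    5: ("cingulum_right", 0.70, (0.0, 1.0, 0.0)),
    6: ("fornix_like", 0.65, (0.0, 1.0, 0.0)),
}


@dataclass
class PhantomParams:
    """Study conditions of the synthetic cohort."""

    size: int = 72                 # template grid (1 mm isotropic)
    dwi_size: int = 36             # DWI grid (2 mm isotropic)
    n_directions: int = 64
    n_b0: int = 4
    bvalue: float = 1000.0         # s/mm^2
    t1_sigma: float = 5.0          # Gaussian noise SD on the T1
    snr_b0: float = 20.0           # WM b0 SNR; 0 disables DWI noise
    warp_amplitude_mm: float = 2.5
    rigid_rot_deg: float = 3.0     # T1<->DWI ground-truth rigid magnitude
    rigid_trans_mm: float = 2.0
    visit_rot_deg: float = 2.0     # per-visit repositioning bounds
    visit_trans_mm: float = 2.0
    seed: int = 0


def fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (spherical Fibonacci)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(1 - z**2, 0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


class AnalyticWarp:
    """Smooth sinusoidal displacement map x -> x + u(x), closed form.

    Serves as the ground-truth subject->template nonlinear transform; its
    gradient magnitude (amplitude * 2*pi / wavelength) stays well below 1,
    so the map is a bijection and numerically invertible.
    """

    def __init__(self, amplitude_mm: float, extent_mm: float, seed: int):
        rng = np.random.default_rng(seed)
        self.amplitude = amplitude_mm * (0.6 + 0.4 * rng.random(3))
        self.wavelength = extent_mm * (1.0 + 0.5 * rng.random(3))
        self.phase = 2 * np.pi * rng.random(3)
        dirs = rng.normal(size=(3, 3))
        self.k = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        u = np.empty_like(pts)
        for i in range(3):
            proj = pts @ self.k[i]
            u[:, i] = self.amplitude[i] * np.sin(
                2 * np.pi * proj / self.wavelength[i] + self.phase[i]
            )
        return u

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts + self.displacement(pts)


@dataclass
class PhantomTruth:
    """Ground truth: label fields, tensors, transforms and parameters."""

    params: PhantomParams
    tissue_labels: Volume          # template grid, codes BG/CSF/GM/WM
    atlas: ROIAtlas                # tract labels, template grid
    tensors: np.ndarray            # (n,n,n,6) Dxx Dyy Dzz Dxy Dxz Dyz
    s0: np.ndarray                 # b0 signal field, template grid
    t1_signal: np.ndarray          # noise-free T1 intensity field
    template: Volume               # the rendered noise-free template T1
    warp_subject_to_template: AnalyticWarp
    rigid_b0_to_t1: RigidTransform  # pull-back: b0 world -> T1 world
    t1_affine: np.ndarray
    dwi_affine: np.ndarray

    def manifest(self) -> dict:
        w = self.warp_subject_to_template
        return {
            "params": asdict(self.params),
            "warp": {
                "amplitude_mm": w.amplitude.tolist(),
                "wavelength_mm": w.wavelength.tolist(),
                "phase": w.phase.tolist(),
                "directions": w.k.tolist(),
            },
            "rigid_b0_to_t1": self.rigid_b0_to_t1.matrix.tolist(),
            "tracts": {c: TRACTS[c][0] for c in TRACTS},
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.manifest(), fh)


@dataclass
class PhantomSession:
    """One rendered scanning session (a visit) of the phantom subject."""

    t1: Volume
    dwi: Volume
    gtab: GradientTable
    visit_rigid: RigidTransform        # scanner world -> anatomical world
    rigid_b0_to_t1: RigidTransform     # this visit's b0->T1 pull-back map
    frame_motions: list                # per-frame world rigid (head motion)
    seed: int


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------

def _prolate_tensor(fa: float, md: float, axis) -> np.ndarray:
    """(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) of a prolate tensor with given FA/MD."""
    if fa <= 0:
        lam1 = lam23 = md
    else:
        f = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))
        lam1 = md * (1 + 2 * f)
        lam23 = md * (1 - f)
    e = np.asarray(axis, dtype=float)
    e = e / np.linalg.norm(e)
    D = lam23 * np.eye(3) + (lam1 - lam23) * np.outer(e, e)
    return np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])


def _build_truth_fields(size: int):
    """Tissue labels, tract labels, tensors and signal fields on the grid."""
    c = (size - 1) / 2.0
    idx = np.indices((size, size, size), dtype=float)
    dx, dy, dz = idx[0] - c, idx[1] - c, idx[2] - c
    scale = size / 64.0  # geometry defined at the 64 mm reference extent
    ax, ay, az = 28 * scale, 28 * scale, 26 * scale
    r2 = (dx / ax) ** 2 + (dy / ay) ** 2 + (dz / az) ** 2

    labels = np.full((size, size, size), BG, dtype=np.int16)
    labels[r2 <= 1.0] = CSF           # outer subarachnoid shell
    labels[r2 <= 0.93**2] = GM
    labels[r2 <= 0.66] = WM           # WM core (squared-radius cut)

    def vent(x0):
        return (
            ((dx - x0 * scale) / (3.0 * scale)) ** 2
            + (dy / (8.0 * scale)) ** 2
            + (dz / (3.0 * scale)) ** 2
        ) <= 1.0

    ventricles = vent(4.0) | vent(-4.0)
    labels[ventricles & (labels == WM)] = CSF

    s = scale
    tract_shapes = {
        1: (np.abs(dx) <= 15 * s) & (np.abs(dy) <= 8 * s)
           & (dz >= 8 * s) & (dz <= 14 * s),
        2: (((dx + 10 * s) ** 2 + (dy + 7 * s) ** 2) <= (4 * s) ** 2)
           & (dz >= -11 * s) & (dz <= 0 * s),
        3: (((dx - 10 * s) ** 2 + (dy + 7 * s) ** 2) <= (4 * s) ** 2)
           & (dz >= -11 * s) & (dz <= 0 * s),
        4: (dx >= -13 * s) & (dx <= -7 * s) & (dy >= -5 * s) & (dy <= 10 * s)
           & (dz >= 1 * s) & (dz <= 6 * s),
        5: (dx >= 7 * s) & (dx <= 13 * s) & (dy >= -5 * s) & (dy <= 10 * s)
           & (dz >= 1 * s) & (dz <= 6 * s),
        6: (np.abs(dx) <= 3 * s) & (np.abs(dy) <= 6 * s)
           & (dz >= 3 * s) & (dz <= 7 * s),
    }
    tract_labels = np.zeros((size, size, size), dtype=np.int16)
    for code, shape in tract_shapes.items():
        if (shape & (labels != WM)).any():
            raise ValueError(
                f"tract {TRACTS[code][0]} escapes the WM compartment"
            )
        shape = shape & (tract_labels == 0)
        tract_labels[shape] = code

    tensors = np.zeros((size, size, size, 6))
    s0 = np.zeros((size, size, size))
    t1 = np.zeros((size, size, size))
    tensors[labels == CSF] = _prolate_tensor(0.0, MD_CSF, (1, 0, 0))
    tensors[labels == GM] = _prolate_tensor(FA_GM, MD_GM, (1, 0, 0))
    tensors[labels == WM] = _prolate_tensor(FA_WM_DEFAULT, MD_WM, (1, 0, 0))
    for code, (_, fa, axis) in TRACTS.items():
        tensors[tract_labels == code] = _prolate_tensor(fa, MD_WM, axis)
    for code, mean in T1_MEANS.items():
        t1[labels == code] = mean
    for code, mean in S0_MEANS.items():
        s0[labels == code] = mean
    # smooth multiplicative intensity texture, fixed in anatomical space:
    # real tissue is not piecewise constant, and without texture nonlinear
    # registration is blind to tangential motion along tissue boundaries
    # distinct wavelengths per axis and a phase-shifted term break the
    # rotational / mirror quasi-symmetries of the ellipsoidal geometry that
    # could otherwise trap global alignment in a flipped pose
    tex = (
        1.0
        + 0.10 * np.sin(2 * np.pi * dx / (17 * scale))
        * np.sin(2 * np.pi * dy / (31 * scale))
        + 0.08 * np.sin(2 * np.pi * (dy + dz) / (26 * scale) + 0.9)
        + 0.04 * np.sin(2 * np.pi * dy / (55 * scale) + 0.5)
    )
    t1 *= tex
    s0 *= tex
    return labels, tract_labels, tensors, s0, t1


def _random_rigid(rng, rot_deg: float, trans_mm: float, center) -> RigidTransform:
    angles = np.deg2rad(rng.uniform(-rot_deg, rot_deg, 3))
    trans = rng.uniform(-trans_mm, trans_mm, 3)
    return rigid_from_params(np.concatenate([angles, trans]), center)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _sample_fields(truth: "PhantomTruth", pts_template: np.ndarray, arrays):
    inv = np.linalg.inv(truth.template.affine)
    ijk = pts_template @ inv[:3, :3].T + inv[:3, 3]
    coords = ijk.T
    out = []
    for arr in arrays:
        if arr.ndim == 3:
            out.append(
                ndimage.map_coordinates(arr, coords, order=1, mode="constant")
            )
        else:
            out.append(
                np.stack(
                    [
                        ndimage.map_coordinates(
                            arr[..., k], coords, order=1, mode="constant"
                        )
                        for k in range(arr.shape[-1])
                    ],
                    axis=-1,
                )
            )
    return out


def add_rician_noise(signal: Volume, sigma: float, seed: int) -> Volume:
    """Magnitude MR noise: out = sqrt((S + n1)^2 + n2^2), n ~ N(0, sigma^2)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Volume(signal.data.copy(), signal.affine.copy())
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.data.shape)
    n2 = rng.normal(0.0, sigma, signal.data.shape)
    return Volume(
        np.sqrt((signal.data + n1) ** 2 + n2**2), signal.affine.copy()
    )


def _render_session(
    truth: PhantomTruth,
    visit_rigid: RigidTransform,
    rigid_b0_to_t1: RigidTransform,
    frame_motions: list | None,
    seed: int,
    noisy: bool = True,
) -> PhantomSession:
    p = truth.params
    warp = truth.warp_subject_to_template
    rng_seed = np.random.default_rng(seed)
    t1_seed, dwi_seed = rng_seed.integers(0, 2**31 - 1, 2)

    # --- T1: voxel -> world -> (visit rigid) -> warp -> template fields
    t1_shape = (p.size,) * 3
    idx = np.indices(t1_shape, dtype=float)
    pts = np.stack([idx[0], idx[1], idx[2]], axis=-1).reshape(-1, 3)
    pts_w = pts @ truth.t1_affine[:3, :3].T + truth.t1_affine[:3, 3]
    pts_t = warp.apply_points(visit_rigid.apply_points(pts_w))
    (t1_vals,) = _sample_fields(truth, pts_t, [truth.t1_signal])
    t1_data = t1_vals.reshape(t1_shape)
    if noisy and p.t1_sigma > 0:
        rng = np.random.default_rng(t1_seed)
        t1_data = np.maximum(
            t1_data + rng.normal(0.0, p.t1_sigma, t1_shape), 0.0
        )
    t1_vol = Volume(t1_data, truth.t1_affine.copy())

    # --- gradient table
    dirs = fibonacci_directions(p.n_directions)
    bvals = np.concatenate([np.zeros(p.n_b0), np.full(p.n_directions, p.bvalue)])
    bvecs = np.vstack([np.zeros((p.n_b0, 3)), dirs])
    gtab = GradientTable(bvals, bvecs)

    # --- DWI
    dwi_shape = (p.dwi_size,) * 3
    idx = np.indices(dwi_shape, dtype=float)
    pts = np.stack([idx[0], idx[1], idx[2]], axis=-1).reshape(-1, 3)
    pts_w = pts @ truth.dwi_affine[:3, :3].T + truth.dwi_affine[:3, 3]

    motions = frame_motions or [None] * gtab.n_frames
    if len(motions) != gtab.n_frames:
        raise ValueError("need one frame motion (or None) per frame")
    base_rot = visit_rigid.rotation @ rigid_b0_to_t1.rotation

    def anat_points(world_pts):
        return warp.apply_points(
            visit_rigid.apply_points(rigid_b0_to_t1.apply_points(world_pts))
        )

    # cache for the common no-motion case
    pts_t_still = anat_points(pts_w)
    D_still, s0_still = _sample_fields(truth, pts_t_still, [truth.tensors, truth.s0])

    frames = np.empty(dwi_shape + (gtab.n_frames,))
    for f in range(gtab.n_frames):
        H = motions[f]
        if H is None:
            D, s0v, rot = D_still, s0_still, base_rot
        else:
            pts_f = anat_points(H.inverse().apply_points(pts_w))
            D, s0v = _sample_fields(truth, pts_f, [truth.tensors, truth.s0])
            rot = base_rot @ H.rotation.T
        b = gtab.bvals[f]
        if b < 1e-9:
            sig = s0v
        else:
            g = rot @ gtab.bvecs[f]
            quad = (
                D[:, 0] * g[0] ** 2 + D[:, 1] * g[1] ** 2 + D[:, 2] * g[2] ** 2
                + 2 * (D[:, 3] * g[0] * g[1] + D[:, 4] * g[0] * g[2]
                       + D[:, 5] * g[1] * g[2])
            )
            sig = s0v * np.exp(-b * quad)
        frames[..., f] = sig.reshape(dwi_shape)

    dwi_vol = Volume(frames, truth.dwi_affine.copy())
    if noisy and p.snr_b0 > 0:
        sigma = S0_MEANS[WM] / p.snr_b0
        dwi_vol = add_rician_noise(dwi_vol, sigma, int(dwi_seed))

    return PhantomSession(
        t1=t1_vol,
        dwi=dwi_vol,
        gtab=gtab,
        visit_rigid=visit_rigid,
        rigid_b0_to_t1=rigid_b0_to_t1,
        frame_motions=list(motions),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# public construction API
# ---------------------------------------------------------------------------

def make_phantom(
    params: PhantomParams | None = None,
    seed: int | None = None,
    frame_motions: list | None = None,
    noisy: bool = True,
) -> tuple[PhantomTruth, PhantomSession]:
    """Build the ground truth and render the first session.

    ``seed`` overrides ``params.seed``.  Identical parameters and seed yield
    bit-identical phantoms.
    """
    params = params or PhantomParams()
    if seed is not None:
        params = PhantomParams(**{**asdict(params), "seed": int(seed)})
    if params.size < 48:
        raise ValueError("template grid must be at least 48^3")

    labels, tract_labels, tensors, s0, t1_signal = _build_truth_fields(params.size)
    template_affine = np.eye(4)
    t1_affine = np.eye(4)
    extent = params.size  # mm
    dwi_affine = np.diag([2.0, 2.0, 2.0, 1.0])
    # centre the DWI field of view on the template extent
    off = (extent - 2.0 * params.dwi_size) / 2.0 + 0.5
    dwi_affine[:3, 3] = off

    rng = np.random.default_rng(params.seed)
    warp = AnalyticWarp(
        params.warp_amplitude_mm, float(extent), int(rng.integers(2**31 - 1))
    )
    center = np.full(3, (extent - 1) / 2.0)
    rigid = _random_rigid(rng, params.rigid_rot_deg, params.rigid_trans_mm, center)

    template = Volume(t1_signal.copy(), template_affine)
    atlas = ROIAtlas(
        Volume(tract_labels.astype(np.int16), template_affine),
        {c: TRACTS[c][0] for c in TRACTS},
    )
    truth = PhantomTruth(
        params=params,
        tissue_labels=Volume(labels.astype(np.int16), template_affine),
        atlas=atlas,
        tensors=tensors,
        s0=s0,
        t1_signal=t1_signal,
        template=template,
        warp_subject_to_template=warp,
        rigid_b0_to_t1=rigid,
        t1_affine=t1_affine,
        dwi_affine=dwi_affine,
    )
    session = _render_session(
        truth,
        RigidTransform.identity(),
        rigid,
        frame_motions,
        seed=int(rng.integers(2**31 - 1)),
        noisy=noisy,
    )
    return truth, session


def simulate_visits(
    truth: PhantomTruth, n_visits: int = 3, seeds=None, noisy: bool = True
) -> list[PhantomSession]:
    """Re-render the subject for repeated visits.

    Each visit gets fresh noise, a small random whole-session repositioning
    and a small perturbation of the T1<->DWI rigid (both bounded by the
    phantom's visit_trans_mm / visit_rot_deg); the anatomical ground truth
    is shared across visits.  One seed per visit (defaults derive from the
    master seed).
    """
    p = truth.params
    if seeds is None:
        master = np.random.default_rng(p.seed + 1)
        seeds = [int(s) for s in master.integers(0, 2**31 - 1, n_visits)]
    if len(seeds) != n_visits:
        raise ValueError("need one seed per visit")
    center = np.full(3, (p.size - 1) / 2.0)
    sessions = []
    for v, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        if v == 0:
            reposition = RigidTransform.identity()
            rigid_v = truth.rigid_b0_to_t1
        else:
            reposition = _random_rigid(
                rng, p.visit_rot_deg, p.visit_trans_mm, center
            )
            jitter = _random_rigid(
                rng, p.visit_rot_deg / 2.0, p.visit_trans_mm / 2.0, center
            )
            rigid_v = RigidTransform(
                truth.rigid_b0_to_t1.matrix @ jitter.matrix
            )
        sessions.append(
            _render_session(
                truth, reposition, rigid_v, None,
                seed=int(rng.integers(2**31 - 1)), noisy=noisy,
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# ground-truth references for validation
# ---------------------------------------------------------------------------

def truth_native_chain(truth: PhantomTruth, session: PhantomSession) -> TransformChain:
    """Exact pull-back chain b0 world -> template world for a session."""
    composite = RigidTransform(
        session.visit_rigid.matrix @ session.rigid_b0_to_t1.matrix
    )
    return TransformChain([composite, truth.warp_subject_to_template])


def _dwi_reference(truth: PhantomTruth) -> Volume:
    shape = (truth.params.dwi_size,) * 3
    return Volume(np.zeros(shape), truth.dwi_affine.copy())


def truth_wm_mask(
    truth: PhantomTruth, session: PhantomSession, thr: float = 0.8
) -> BinaryMask:
    """Partial-volume WM fraction in native DWI space, thresholded at 0.8."""
    wm_ind = (truth.tissue_labels.data == WM).astype(float)
    prob = resample(
        Volume(wm_ind, truth.template.affine),
        truth_native_chain(truth, session),
        _dwi_reference(truth),
    )
    prob.data[:] = np.clip(prob.data, 0.0, 1.0)
    return threshold_binarize(prob, thr)


def truth_native_tract(
    truth: PhantomTruth,
    session: PhantomSession,
    code: int,
    pre_erode: int = 1,
    wm_erode: int = 1,
    protocol: bool = True,
) -> BinaryMask:
    """Ground-truth native-space tract mask for a session.

    With ``protocol=True`` the reference follows the segmentation protocol
    (template-space erosion, trilinear warp, 0.8 re-threshold, WM
    cross-mask) but uses the *exact* transforms and the partial-volume WM
    truth, so a comparison against the pipeline output isolates estimation
    error.  With ``protocol=False`` it is the plain voxelized tract
    (partial-volume fraction >= 0.5).
    """
    chain = truth_native_chain(truth, session)
    if not protocol:
        ind = (truth.atlas.labels.data == code).astype(float)
        prob = resample(
            Volume(ind, truth.template.affine), chain, _dwi_reference(truth)
        )
        return BinaryMask(prob.data >= 0.5, prob.affine)
    wm = truth_wm_mask(truth, session)
    mask, _ = segment_tract(
        truth.atlas, code, chain, wm,
        reference=_dwi_reference(truth),
        pre_erode=pre_erode, wm_erode=wm_erode,
    )
    return mask
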