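"""Rigid pre-alignment, boundary-based refinement, nonlinear warping and
transform-chain recovery on seeded phantoms."""

import warnings

import numpy as np
import pytest

from diffseg.dwi import average_b0, brain_mask_from_b0
from diffseg.image import BinaryMask, Volume, dice, resample
from diffseg.phantom import AnalyticWarp, make_phantom
from diffseg.register import (
    _boundary_sites,
    affine_align,
    bbr_cost,
    bbr_refine,
    build_native_chain,
    nonlinear_to_template,
    rigid_prealign,
    register_rigid,
)
from diffseg.segment import make_wm_mask, segment_tissues
from diffseg.transforms import (
    AffineTransform,
    RigidTransform,
    TransformChain,
    rigid_from_params,
)


@pytest.fixture(scope="module")
def phantom_bundle():
    """Phantom + derived images shared by the registration tests."""
    truth, sess = make_phantom(seed=1)
    b0 = average_b0(sess.dwi, sess.gtab)
    t1 = sess.t1
    t1_mask = brain_mask_from_b0(t1, frac=0.15)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tissues = segment_tissues(t1, t1_mask)
    wm = make_wm_mask(tissues.wm, 0.5)
    return truth, sess, b0, t1, wm


def transform_error_mm(est, true, pts):
    return float(
        np.linalg.norm(est.apply_points(pts) - true.apply_points(pts), axis=1).mean()
    )


class TestRigidPrealign:
    def test_self_registration_is_identity(self, phantom_bundle):
        _, _, b0, _, _ = phantom_bundle
        T = register_rigid(b0, b0, cost="cr", levels=(2,))
        assert np.linalg.norm(T.translation) < 0.1
        assert np.allclose(T.rotation, np.eye(3), atol=2e-3)  # ~0.1 deg

    def test_recovers_offset_and_rotation(self, phantom_bundle):
        truth, _, b0, t1, _ = phantom_bundle
        pts = np.argwhere(t1.data > 50)[::101].astype(float)
        true_map = truth.rigid_b0_to_t1.inverse()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = rigid_prealign(b0, t1)
        # ground-truth offset includes ~2 mm translation and ~3 deg rotation
        assert transform_error_mm(est, true_map, pts) <= 0.5

    def test_seeded_perturbation_recovery(self, phantom_bundle):
        # median recovery error over seeded ground-truth rigids (<=8 mm/8 deg)
        truth, sess, b0, t1, _ = phantom_bundle
        rng = np.random.default_rng(42)
        center = np.full(3, (t1.shape3[0] - 1) / 2.0)
        pts = np.argwhere(t1.data > 50)[::151].astype(float)
        errors = []
        for _ in range(8):
            p = np.concatenate(
                [np.deg2rad(rng.uniform(-8, 8, 3)), rng.uniform(-8, 8, 3)]
            )
            gt = rigid_from_params(p, center)
            moved = resample(t1, gt, t1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = register_rigid(moved, t1, cost="ncc")
            # the pull-back that re-aligns `moved` onto t1 is gt^{-1}
            errors.append(transform_error_mm(est, gt.inverse(), pts))
        assert np.median(errors) <= 0.5


class TestBBR:
    def test_cost_at_truth_beats_random_perturbations(self, phantom_bundle):
        truth, _, b0, t1, wm = phantom_bundle
        sites, normals = _boundary_sites(wm)
        true_map = truth.rigid_b0_to_t1.inverse()
        c_true, _ = bbr_cost(b0, true_map, sites, normals)
        rng = np.random.default_rng(3)
        center = np.full(3, (t1.shape3[0] - 1) / 2.0)
        worse = 0
        for _ in range(50):
            p = np.concatenate(
                [np.deg2rad(rng.uniform(-2, 2, 3)), rng.uniform(-2, 2, 3)]
            )
            pert = RigidTransform(
                rigid_from_params(p, center).matrix @ true_map.matrix
            )
            c_pert, _ = bbr_cost(b0, pert, sites, normals)
            worse += c_pert >= c_true
        assert worse >= 45  # near-optimal at truth

    def test_refines_displaced_init(self, phantom_bundle):
        truth, _, b0, t1, wm = phantom_bundle
        true_map = truth.rigid_b0_to_t1.inverse()
        center = np.full(3, (t1.shape3[0] - 1) / 2.0)
        off = rigid_from_params([0.015, -0.012, 0.02, 1.8, -1.5, 1.4], center)
        init = RigidTransform(off.matrix @ true_map.matrix)
        refined = bbr_refine(b0, t1, wm, init)
        delta = refined.matrix @ np.linalg.inv(true_map.matrix)
        angle = np.rad2deg(np.arccos(np.clip((np.trace(delta[:3, :3]) - 1) / 2, -1, 1)))
        pts = np.argwhere(wm.data)[::101].astype(float)
        # mean point error inside WM is the quantity that propagates into
        # the segmentation; the boundary cost additionally has a soft
        # rotational mode of about a degree on smooth closed surfaces
        # (documented in the methods note), hence the looser angle bound
        assert transform_error_mm(refined, true_map, pts) <= 1.0
        assert angle <= 1.5

    def test_never_worsens_boundary_cost(self, phantom_bundle):
        truth, _, b0, t1, wm = phantom_bundle
        sites, normals = _boundary_sites(wm)
        init = rigid_prealign(b0, t1)
        refined = bbr_refine(b0, t1, wm, init)
        c_init = np.mean([bbr_cost(b0, init, sites, normals, d)[0] for d in (1.0, 2.0)])
        c_ref = np.mean([bbr_cost(b0, refined, sites, normals, d)[0] for d in (1.0, 2.0)])
        assert c_ref <= c_init + 1e-12

    def test_structureless_b0_raises_failure_flag(self, phantom_bundle):
        _, _, b0, t1, wm = phantom_bundle
        rng = np.random.default_rng(0)
        noise = Volume(np.abs(rng.normal(0, 1e-9, b0.shape3)), b0.affine)
        out = bbr_refine(noise, t1, wm, RigidTransform.identity())
        assert out.failed


class TestNonlinear:
    def test_template_to_itself_near_zero_field(self, phantom_noise_free):
        truth, _ = phantom_noise_free
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = nonlinear_to_template(
                truth.template, truth.template,
                affine_init=AffineTransform(np.eye(4)),
            )
        interior = truth.tissue_labels.data > 0
        disp = np.linalg.norm(W.displacement[interior], axis=-1)
        assert np.sqrt((disp**2).mean()) < 0.1  # voxels (1 mm grid)

    def test_recovers_synthetic_sinusoidal_warp(self, phantom_noise_free):
        truth, _ = phantom_noise_free
        template = truth.template
        gtw = AnalyticWarp(3.0, float(truth.params.size), seed=7)
        deformed = resample(template, gtw, template)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = nonlinear_to_template(
                deformed, template, affine_init=AffineTransform(np.eye(4))
            )
        interior = truth.tissue_labels.data > 0
        pts = np.argwhere(interior)[::17].astype(float)
        y = pts.copy()
        for _ in range(80):  # numeric inverse of the analytic warp
            y = pts - gtw.displacement(y)
        err = np.linalg.norm(W.apply_points(pts) - y, axis=1)
        assert np.sqrt((err**2).mean()) <= 1.0

    def test_warp_reduces_ssd_over_rigid(self, phantom_noise_free):
        truth, _ = phantom_noise_free
        template = truth.template
        gtw = AnalyticWarp(3.0, float(truth.params.size), seed=7)
        deformed = resample(template, gtw, template)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = nonlinear_to_template(
                deformed, template, affine_init=AffineTransform(np.eye(4))
            )
        f = template.data / template.data.max()
        m = deformed.data / template.data.max()
        ref = Volume(m, template.affine)
        idx = np.indices(template.shape3, dtype=float)
        pts = np.stack([idx[0], idx[1], idx[2]], -1).reshape(-1, 3)
        from diffseg.register import _sample

        ssd_rigid = ((f.reshape(-1) - m.reshape(-1)) ** 2).sum()
        warped = _sample(m, template.affine, W.apply_points(pts))
        ssd_warp = ((f.reshape(-1) - warped) ** 2).sum()
        assert ssd_warp <= 0.7 * ssd_rigid


class TestChainAssembly:
    def test_identity_components_give_identity_chain(self, rng):
        from diffseg.transforms import Warp

        w = Warp(np.zeros((6, 6, 6, 3)), np.eye(4))
        chain, inv_bbr = build_native_chain(w, RigidTransform.identity())
        pts = rng.uniform(0, 5, (30, 3))
        assert np.allclose(chain.apply_points(pts), pts, atol=1e-9)
        assert np.allclose(inv_bbr.matrix, np.eye(4))

    def test_round_trip_residual(self, phantom_bundle):
        truth, sess, b0, t1, wm = phantom_bundle
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pre = rigid_prealign(b0, t1)
            bbr = bbr_refine(b0, t1, wm, pre)
            W = nonlinear_to_template(t1, truth.template)
        chain, _ = build_native_chain(W, bbr)
        forward = TransformChain([W, bbr])  # template -> t1 -> b0
        rng = np.random.default_rng(5)
        interior = np.argwhere(b0.data > 100)
        pts = interior[rng.choice(len(interior), 1000, replace=False)].astype(float)
        pts = pts @ b0.affine[:3, :3].T + b0.affine[:3, 3]
        res = forward.apply_points(chain.apply_points(pts)) - pts
        rms_vox = np.sqrt((np.linalg.norm(res, axis=1) ** 2).mean()) / 2.0
        assert rms_vox <= 0.1

    def test_atlas_round_trip_overlap(self, phantom_bundle):
        truth, sess, b0, t1, wm = phantom_bundle
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pre = rigid_prealign(b0, t1)
            bbr = bbr_refine(b0, t1, wm, pre)
            W = nonlinear_to_template(t1, truth.template)
        chain, _ = build_native_chain(W, bbr)
        forward = TransformChain([W, bbr])
        label = truth.atlas.binary(1).to_volume()  # large slab
        native = resample(label, chain, b0)
        native_mask = BinaryMask(native.data >= 0.5, b0.affine)
        back = resample(native_mask.to_volume(), forward, truth.template)
        back_mask = BinaryMask(back.data >= 0.5, truth.template.affine)
        assert dice(back_mask, truth.atlas.binary(1)) >= 0.9
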