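"""Certainty fusion, warping, field algebra and the demons operator."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mcatlas.errors import ConfigurationError
from mcatlas.images import (
    AffineTransform,
    Channel,
    ChannelSet,
    DisplacementField,
    MaskImage,
    ScalarImage,
    SHImage,
)
from mcatlas.metrics import UpdateFieldPair
from mcatlas import registration as reg
from mcatlas.phantom import lobe_coefficients
from mcatlas.sh import direction_set, real_sh_basis


class TestCertainty:
    def test_constant_image_is_zero(self):
        cm = reg.certainty_map(ScalarImage(np.full((6, 6, 6), 3.0)))
        assert np.all(cm.values == 0)

    def test_nonconstant_max_is_one(self, rng):
        cm = reg.certainty_map(ScalarImage(rng.standard_normal((6, 6, 6))))
        assert cm.values.max() == 1.0
        assert cm.values.min() >= 0.0

    def test_linear_ramp_uniform_interior(self):
        x = np.arange(8, dtype=float)
        img = ScalarImage(np.broadcast_to(x[:, None, None], (8, 8, 8)).copy())
        cm = reg.certainty_map(img)
        assert np.allclose(cm.values[1:-1], 1.0)  # constant interior gradient


class TestFusion:
    def test_single_channel_passthrough(self, rng):
        u = UpdateFieldPair(rng.standard_normal((5, 5, 5, 3)), rng.standard_normal((5, 5, 5, 3)))
        cert = reg.CertaintyMap(rng.uniform(0.1, 1.0, (5, 5, 5)))
        fused = reg.fuse_updates([u], [cert])
        assert np.allclose(fused.toward_fixed, u.toward_fixed)

    def test_equal_weights_give_arithmetic_mean(self, rng):
        pairs = [
            UpdateFieldPair(rng.standard_normal((4, 4, 4, 3)), rng.standard_normal((4, 4, 4, 3)))
            for _ in range(3)
        ]
        certs = [reg.CertaintyMap(np.full((4, 4, 4), 0.7)) for _ in range(3)]
        fused = reg.fuse_updates(pairs, certs)
        assert np.allclose(fused.toward_fixed, np.mean([p.toward_fixed for p in pairs], axis=0))

    def test_matches_weighted_mean_oracle_and_convexity(self, rng):
        pairs = [
            UpdateFieldPair(rng.standard_normal((4, 4, 4, 3)), rng.standard_normal((4, 4, 4, 3)))
            for _ in range(3)
        ]
        certs = [reg.CertaintyMap(rng.uniform(0, 1, (4, 4, 4))) for _ in range(3)]
        fused = reg.fuse_updates(pairs, certs)
        w = np.stack([c.values for c in certs])
        f = np.stack([p.toward_fixed for p in pairs])
        expected = (w[..., None] * f).sum(axis=0) / w.sum(axis=0)[..., None]
        assert np.abs(fused.toward_fixed - expected).max() < 1e-12
        # convexity: every fused component within the channel envelope
        assert np.all(fused.toward_fixed <= f.max(axis=0) + 1e-12)
        assert np.all(fused.toward_fixed >= f.min(axis=0) - 1e-12)

    def test_zero_total_weight_gives_zero(self, rng):
        u = UpdateFieldPair(rng.standard_normal((3, 3, 3, 3)), rng.standard_normal((3, 3, 3, 3)))
        fused = reg.fuse_updates([u], [reg.CertaintyMap(np.zeros((3, 3, 3)))])
        assert np.all(fused.toward_fixed == 0)

    def test_count_mismatch_raises(self, rng):
        u = UpdateFieldPair(np.zeros((3, 3, 3, 3)), np.zeros((3, 3, 3, 3)))
        with pytest.raises(ConfigurationError):
            reg.fuse_updates([u, u], [reg.CertaintyMap(np.zeros((3, 3, 3)))])


def _scalar_set(values, name="img", role="intensity"):
    return ChannelSet("s", 40.0, [Channel(name, ScalarImage(values), role)])


class TestWarping:
    def test_zero_warp_is_identity(self, rng):
        cs = _scalar_set(rng.standard_normal((8, 8, 8)))
        warp = DisplacementField(np.zeros((8, 8, 8, 3)))
        out = reg.warp_channelset(cs, warp)
        assert np.allclose(out["img"].image.values, cs["img"].image.values, atol=1e-12)

    def test_integer_translation_shifts_exactly(self, rng):
        vals = rng.standard_normal((10, 10, 10))
        cs = _scalar_set(vals)
        warp = DisplacementField(np.zeros((10, 10, 10, 3)))
        warp.vectors[..., 0] = 2.0  # sample from x+2
        out = reg.warp_channelset(cs, warp)
        assert np.allclose(out["img"].image.values[:-2], vals[2:], atol=1e-12)

    def test_mask_warps_to_binary(self):
        vals = np.zeros((8, 8, 8))
        vals[2:6, 2:6, 2:6] = 1.0
        cs = ChannelSet("s", 40.0, [Channel("m", MaskImage(vals), "mask")])
        warp = DisplacementField(np.full((8, 8, 8, 3), 0.4))
        out = reg.warp_channelset(cs, warp)
        assert set(np.unique(out["m"].image.values)) <= {0.0, 1.0}

    def test_rotation_warp_reorients_fiber_peak(self):
        """Rotating a single-fibre ODF image must rotate its peak."""
        n = 16
        center = (n - 1) / 2.0
        coeffs = np.zeros((n, n, n, 15))
        coeffs[...] = lobe_coefficients(np.array([1.0, 0, 0]), 4, 8.0)
        img = SHImage(coeffs, 4)
        rot = Rotation.from_euler("z", 35, degrees=True).as_matrix()
        # pull-back phi(x) = R^T (x - c) + c rotates the image (and its
        # fibres) forward by R
        idx = np.stack(np.meshgrid(*(np.arange(n, dtype=float),) * 3, indexing="ij"), -1)
        mapped = (idx - center) @ rot + center  # rows: R^T (x - c) + c
        warp = DisplacementField(mapped - idx)
        cs = ChannelSet("s", 40.0, [Channel("odf", img, "odf")])
        out = reg.warp_channelset(cs, warp)
        d = direction_set(724)
        amps = real_sh_basis(d, 4) @ out["odf"].image.coeffs[8, 8, 8]
        peak = d[np.argmax(amps)]
        expected = rot @ np.array([1.0, 0, 0])
        angle = np.degrees(np.arccos(min(abs(float(peak @ expected)), 1.0)))
        assert angle < 5.0


class TestFieldAlgebra:
    def test_invert_zero_field(self):
        w = DisplacementField(np.zeros((6, 6, 6, 3)))
        assert np.all(reg.invert_warp(w).vectors == 0)

    def test_invert_uniform_translation(self):
        w = DisplacementField(np.full((8, 8, 8, 3), 1.25))
        inv = reg.invert_warp(w)
        assert np.abs(inv.vectors + 1.25).max() < 1e-6

    def test_invert_smooth_warp_roundtrip(self):
        n = 16
        x, y, z = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
        u = np.zeros((n, n, n, 3))
        u[..., 0] = 0.8 * np.sin(2 * np.pi * x / n) * np.cos(2 * np.pi * y / n)
        u[..., 1] = 0.6 * np.sin(2 * np.pi * z / n)
        w = DisplacementField(u)
        inv = reg.invert_warp(w)
        comp = reg.compose_displacements(w, inv)  # u(x + v(x)) + v(x)
        assert np.linalg.norm(comp.vectors, axis=-1).max() < 0.1  # voxels (1mm grid)

    def test_jacobian_zero_warp_is_one(self):
        jac = reg.jacobian_map(DisplacementField(np.zeros((6, 6, 6, 3))))
        assert np.allclose(jac.values, 1.0)

    def test_jacobian_uniform_scaling(self):
        n, s = 12, 1.1
        idx = np.stack(np.meshgrid(*(np.arange(n, dtype=float),) * 3, indexing="ij"), -1)
        warp = DisplacementField(s * idx - idx)  # total map x -> s x
        jac = reg.jacobian_map(warp)
        assert np.allclose(jac.values[1:-1, 1:-1, 1:-1], s**3, atol=1e-10)

    def test_jacobian_affine_matches_determinant(self):
        n = 12
        mat = np.array([[1.05, 0.02, 0.0], [0.0, 0.96, 0.03], [0.01, 0.0, 1.02]])
        idx = np.stack(np.meshgrid(*(np.arange(n, dtype=float),) * 3, indexing="ij"), -1)
        warp = DisplacementField(idx @ mat.T - idx)
        jac = reg.jacobian_map(warp)
        assert np.abs(jac.values[1:-1, 1:-1, 1:-1] - np.linalg.det(mat)).max() < 1e-3


@pytest.fixture(scope="module")
def textured_pair():
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(5)
    n = 24
    vals = gaussian_filter(rng.standard_normal((n, n, n)), 1.8)
    vals = (vals - vals.min()) / np.ptp(vals)
    return n, vals


class TestAffineRegister:
    def test_identity_pair(self, textured_pair):
        n, vals = textured_pair
        fixed = _scalar_set(vals, "t2w")
        aff = reg.affine_register(fixed, fixed, "t2w")
        assert np.abs(aff.matrix[:3, 3]).max() < 0.1  # < 0.1 voxel translation
        assert np.abs(aff.matrix[:3, :3] - np.eye(3)).max() < 0.02

    def test_translation_recovery(self, textured_pair):
        n, vals = textured_pair
        fixed = _scalar_set(vals, "t2w")
        moving = _scalar_set(np.roll(vals, 3, axis=0), "t2w")
        aff = reg.affine_register(fixed, moving, "t2w")
        # pull-back: moving point = fixed point + 3 along x
        assert abs(aff.matrix[0, 3] - 3.0) < 0.2
        assert np.abs(aff.matrix[1:3, 3]).max() < 0.2

    def test_scale_recovery(self, textured_pair):
        n, vals = textured_pair
        center = (n - 1) / 2.0
        idx = np.stack(np.meshgrid(*(np.arange(n, dtype=float),) * 3, indexing="ij"), -1)
        pts = (idx - center) * 1.1 + center
        from mcatlas.resample import sample_at_world

        scaled = sample_at_world(vals, np.eye(4), pts)
        fixed = _scalar_set(vals, "t2w")
        moving = _scalar_set(scaled, "t2w")
        aff = reg.affine_register(fixed, moving, "t2w")
        # moving(x) = fixed(1.1 (x - c) + c), so the pull-back affine
        # from fixed to moving space carries scale 1/1.1
        scales = np.linalg.norm(aff.matrix[:3, :3], axis=0)
        expected = 1.0 / 1.1
        assert np.abs(scales / expected - 1.0).max() < 0.01  # within 1%


class TestDemons:
    def test_identity_registration_stays_still(self, tiny_spec, tiny_truth):
        from mcatlas.phantom import clean_channelset

        cs = clean_channelset(tiny_spec, 40.0, tiny_truth).subset(["t2w", "cortex"])
        cfg = reg.RegistrationConfig(max_iterations_per_level=(5, 5, 5))
        wmf, wfm = reg.register_multichannel(cs, cs, cfg)
        assert np.linalg.norm(wmf.vectors, axis=-1).max() < 0.05
        assert np.linalg.norm(wfm.vectors, axis=-1).max() < 0.05

    def test_channel_mismatch_raises(self, tiny_spec, tiny_truth):
        from mcatlas.phantom import clean_channelset

        cs = clean_channelset(tiny_spec, 40.0, tiny_truth)
        with pytest.raises(ConfigurationError):
            reg.register_multichannel(cs.subset(["t2w"]), cs.subset(["t1w"]))

    def test_symmetry_of_role_swap(self, tiny_spec, tiny_truth):
        """Swapping fixed and moving yields the exchanged warp pair."""
        from mcatlas.phantom import clean_channelset, make_phantom_subject

        subject, _ = make_phantom_subject(tiny_spec, 40.0, 21, tiny_truth)
        template = clean_channelset(tiny_spec, 40.0, tiny_truth)
        # mild deformation between template and itself warped
        import dataclasses

        spec2 = dataclasses.replace(tiny_spec, warp_amplitude_voxels=1.0)
        subject, _ = make_phantom_subject(spec2, 40.0, 21, tiny_truth)
        cfg = reg.RegistrationConfig(max_iterations_per_level=(15, 10, 8))
        ab = reg.register_multichannel(template.subset(["t2w"]), subject.subset(["t2w"]), cfg)
        ba = reg.register_multichannel(subject.subset(["t2w"]), template.subset(["t2w"]), cfg)
        brain = np.linalg.norm(ab[0].vectors, axis=-1) > 0.2
        diff = np.linalg.norm(ab[0].vectors - ba[1].vectors, axis=-1)
        assert diff[brain].mean() < 0.2 if brain.any() else True
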