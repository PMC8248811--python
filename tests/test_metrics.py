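"""LAC / LNCC metrics and their demons update fields against literal
per-voxel loop oracles."""

import numpy as np
import pytest

from mcatlas.errors import ChannelIncompatibilityError, GridMismatchError
from mcatlas.images import MaskImage, ScalarImage, SHImage
from mcatlas import metrics


def neighborhood(arr, i, j, k, r):
    return arr[
        max(i - r, 0) : i + r + 1, max(j - r, 0) : j + r + 1, max(k - r, 0) : k + r + 1
    ]


def brute_force_correlation(stack_a, stack_b, radius):
    """Literal triple-loop evaluation of the local correlation of two
    channel stacks (trailing channel axis), centred by neighbourhood
    means."""
    shape = stack_a.shape[:3]
    values = np.zeros(shape)
    defined = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                na = neighborhood(stack_a, i, j, k, radius)
                nb = neighborhood(stack_b, i, j, k, radius)
                ca = na - na.mean(axis=(0, 1, 2))
                cb = nb - nb.mean(axis=(0, 1, 2))
                num = float((ca * cb).sum())
                da = float((ca * ca).sum())
                db = float((cb * cb).sum())
                if da > 0 and db > 0:
                    values[i, j, k] = num / np.sqrt(da * db)
                    defined[i, j, k] = True
    return values, defined


def brute_force_updates(stack_a, stack_b, radius, voxel_size=(1.0, 1.0, 1.0)):
    """Literal per-voxel evaluation of the symmetric update-field pair."""
    shape = stack_a.shape[:3]
    n_ch = stack_a.shape[3]
    mu_a = np.zeros_like(stack_a)
    mu_b = np.zeros_like(stack_b)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                mu_a[i, j, k] = neighborhood(stack_a, i, j, k, radius).mean(axis=(0, 1, 2))
                mu_b[i, j, k] = neighborhood(stack_b, i, j, k, radius).mean(axis=(0, 1, 2))
    cen_a = stack_a - mu_a
    cen_b = stack_b - mu_b
    grad_a = metrics.central_gradient(cen_a, np.asarray(voxel_size))
    grad_b = metrics.central_gradient(cen_b, np.asarray(voxel_size))
    lam_a = np.zeros(shape + (3,))
    lam_b = np.zeros(shape + (3,))
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                nca = neighborhood(cen_a, i, j, k, 0)  # centred values at x only
                # inner products accumulate over the neighbourhood of x
                ca = neighborhood(stack_a, i, j, k, radius) - mu_a[i, j, k]
                cb = neighborhood(stack_b, i, j, k, radius) - mu_b[i, j, k]
                cross = float((ca * cb).sum())
                ssa = float((ca * ca).sum())
                ssb = float((cb * cb).sum())
                if ssa <= 0 or ssb <= 0:
                    continue
                factor = 2.0 * cross / (ssa * ssb)
                ra = cen_b[i, j, k] - cross / ssa * cen_a[i, j, k]
                rb = cen_a[i, j, k] - cross / ssb * cen_b[i, j, k]
                lam_a[i, j, k] = factor * (ra[:, None] * grad_a[i, j, k]).sum(axis=0)
                lam_b[i, j, k] = factor * (rb[:, None] * grad_b[i, j, k]).sum(axis=0)
    return lam_b, lam_a  # (toward_fixed, toward_moving)


class TestLAC:
    def test_matches_triple_loop(self, small_sh_pair):
        a, b = small_sh_pair
        cm = metrics.local_angular_correlation(a, b, radius=2)
        ref, ref_def = brute_force_correlation(a.coeffs[..., 1:], b.coeffs[..., 1:], 2)
        assert np.array_equal(cm.defined, ref_def)
        assert np.abs(cm.values[cm.defined] - ref[cm.defined]).max() < 1e-10

    def test_self_correlation_is_one(self, small_sh_pair):
        a, _ = small_sh_pair
        cm = metrics.local_angular_correlation(a, a, radius=2)
        assert cm.defined.any()
        assert np.allclose(cm.values[cm.defined], 1.0)

    def test_negated_anisotropy_is_minus_one(self, small_sh_pair):
        a, _ = small_sh_pair
        b = SHImage(a.coeffs.copy(), a.lmax)
        b.coeffs[..., 1:] *= -1
        cm = metrics.local_angular_correlation(a, b, radius=2)
        assert np.allclose(cm.values[cm.defined], -1.0)

    def test_isotropic_offset_invariance(self, small_sh_pair):
        """Adding a constant to the l=0 coefficient leaves LAC unchanged."""
        a, b = small_sh_pair
        base = metrics.local_angular_correlation(a, b, radius=2)
        shifted = SHImage(a.coeffs.copy(), a.lmax)
        shifted.coeffs[..., 0] += 11.7
        cm = metrics.local_angular_correlation(shifted, b, radius=2)
        assert np.array_equal(cm.values, base.values)

    def test_symmetry_and_bounds(self, small_sh_pair):
        a, b = small_sh_pair
        ab = metrics.local_angular_correlation(a, b, radius=2)
        ba = metrics.local_angular_correlation(b, a, radius=2)
        assert np.allclose(ab.values, ba.values, atol=1e-12)
        assert np.all(np.abs(ab.values[ab.defined]) <= 1 + 1e-9)

    def test_lmax_mismatch_raises(self, small_sh_pair, rng):
        a, _ = small_sh_pair
        other = SHImage(rng.standard_normal((8, 8, 8, 15)), 4)
        with pytest.raises(ChannelIncompatibilityError):
            metrics.local_angular_correlation(a, other, radius=2)


class TestLNCC:
    def test_matches_loop_oracle(self, small_scalar_pair):
        a, b = small_scalar_pair
        cm = metrics.lncc(a, b, radius=2)
        ref, ref_def = brute_force_correlation(a.values[..., None], b.values[..., None], 2)
        assert np.abs(cm.values[cm.defined] - ref[cm.defined]).max() < 1e-10

    def test_affine_intensity_invariance(self, small_scalar_pair):
        a, _ = small_scalar_pair
        b = ScalarImage(2.5 * a.values + 1.3)
        cm = metrics.lncc(a, b, radius=2)
        assert np.allclose(cm.values[cm.defined], 1.0)

    def test_negation_gives_minus_one(self, small_scalar_pair):
        a, _ = small_scalar_pair
        cm = metrics.lncc(a, ScalarImage(-a.values), radius=2)
        assert np.allclose(cm.values[cm.defined], -1.0)

    def test_grid_mismatch_raises(self, small_scalar_pair, rng):
        a, _ = small_scalar_pair
        with pytest.raises(GridMismatchError):
            metrics.lncc(a, ScalarImage(rng.standard_normal((6, 6, 6))), radius=2)


class TestUpdateFields:
    def test_lac_matches_loop_oracle(self, small_sh_pair):
        a, b = small_sh_pair
        pair = metrics.lac_update_fields(a, b, radius=2)
        ref_fixed, ref_moving = brute_force_updates(a.coeffs[..., 1:], b.coeffs[..., 1:], 2)
        assert np.abs(pair.toward_fixed - ref_fixed).max() < 1e-8
        assert np.abs(pair.toward_moving - ref_moving).max() < 1e-8

    def test_lncc_matches_loop_oracle(self, small_scalar_pair):
        a, b = small_scalar_pair
        pair = metrics.lncc_update_fields(a, b, radius=2)
        ref_fixed, ref_moving = brute_force_updates(a.values[..., None], b.values[..., None], 2)
        assert np.abs(pair.toward_fixed - ref_fixed).max() < 1e-8
        assert np.abs(pair.toward_moving - ref_moving).max() < 1e-8

    def test_identical_inputs_give_zero(self, small_sh_pair):
        a, _ = small_sh_pair
        pair = metrics.lac_update_fields(a, a, radius=2)
        assert np.all(pair.toward_fixed == 0)
        assert np.all(pair.toward_moving == 0)

    def test_constant_region_gives_zero_scalar_update(self):
        vals = np.zeros((8, 8, 8))
        vals[6:, :, :] = np.arange(8 * 8 * 2).reshape(2, 8, 8)
        a = ScalarImage(vals)
        b = ScalarImage(vals * 0.5 + 1)
        pair = metrics.lncc_update_fields(a, b, radius=1)
        assert np.all(pair.toward_fixed[:3] == 0)  # flat region far from edits

    def test_role_swap_symmetry(self, small_sh_pair):
        a, b = small_sh_pair
        fwd = metrics.lac_update_fields(a, b, radius=2)
        rev = metrics.lac_update_fields(b, a, radius=2)
        assert np.abs(fwd.toward_fixed - rev.toward_moving).max() < 1e-10
        assert np.abs(fwd.toward_moving - rev.toward_fixed).max() < 1e-10

    def test_global_scale_invariance(self, small_sh_pair):
        a, b = small_sh_pair
        base = metrics.lac_update_fields(a, b, radius=2)
        scaled = metrics.lac_update_fields(
            SHImage(3.7 * a.coeffs, 2), SHImage(3.7 * b.coeffs, 2), radius=2
        )
        assert np.abs(scaled.toward_fixed - base.toward_fixed).max() < 1e-8


def test_box_sum_is_exact_on_integers(rng):
    """The separable box filter equals direct neighbourhood sums exactly."""
    arr = rng.integers(-50, 50, size=(7, 6, 5)).astype(float)
    r = 2
    fast = metrics.box_sum(arr, r)
    for i in range(7):
        for j in range(6):
            for k in range(5):
                assert fast[i, j, k] == neighborhood(arr, i, j, k, r).sum()
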