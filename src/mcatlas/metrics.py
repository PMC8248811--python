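"""Local similarity metrics and their symmetric demons update fields.

Two metrics drive the multi-channel registration:

* **LAC** (local angular correlation) for ODF channels: a Pearson-type
  correlation of the degree ``l >= 2`` SH coefficients accumulated over a
  cubic spatial neighbourhood, with each coefficient image centred by its
  local neighbourhood mean.  The ``l = 0`` term is excluded, which makes
  the metric insensitive to isotropic offsets.
* **LNCC** (local normalised cross-correlation) for scalar and mask
  channels: the single-channel specialisation of the same construction.

For either metric the symmetric pair of demons update fields is

``lambda_A = 2 <A,B> / (<A><B>) * (B - <A,B>/<A> * A) . grad(A)``

(and the mirrored expression for ``lambda_B``), where ``A``, ``B`` are the
locally mean-centred channel vectors at a voxel, ``< >`` the neighbourhood
inner products and the product with ``grad`` contracts over the channel
(SH-coefficient) dimension.  Any global constant factor of the update is
absorbed by the registration step-size rule.

All neighbourhood sums use a cubic ``(2r+1)^3`` window with uniform
weights, implemented by exact separable box filtering (neighbourhoods are
truncated at the volume borders; the voxel count ``n(x)`` shrinks there
accordingly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

from .images import (
    MaskImage,
    ScalarImage,
    SHImage,
    n_coeffs,
    require_compatible_sh,
    require_same_grid,
)

EPS_FRACTION = 1e-6  # of the global mean local sum-of-squares inside the mask


@dataclass
class CorrelationMap:
    """Per-voxel correlation in [-1, 1] with an explicit defined-mask."""

    values: np.ndarray
    defined: np.ndarray
    voxel_to_world: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def mean(self) -> float:
        """Mean correlation over defined voxels (nan if none defined)."""
        if not self.defined.any():
            return float("nan")
        return float(self.values[self.defined].mean())


@dataclass
class UpdateFieldPair:
    """Symmetric demons updates, world-mm 3-vectors per voxel.

    ``toward_fixed`` moves the moving-side image toward the fixed side
    (``lambda_B``); ``toward_moving`` the converse (``lambda_A``).
    """

    toward_fixed: np.ndarray
    toward_moving: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.toward_fixed.shape[:3]  # type: ignore[return-value]


def box_sum(arr: np.ndarray, radius: int) -> np.ndarray:
    """Sliding cubic-window sum over the first three axes, truncated at
    borders (zero contribution from outside the volume).  Separable and
    integer-exact."""
    kernel = np.ones(2 * radius + 1)
    out = np.asarray(arr, dtype=float)
    for axis in range(3):
        out = correlate1d(out, kernel, axis=axis, mode="constant", cval=0.0)
    return out


def neighborhood_count(grid_shape: tuple[int, int, int], radius: int) -> np.ndarray:
    """Number of in-volume voxels in each cubic neighbourhood."""
    return box_sum(np.ones(grid_shape), radius)


def central_gradient(arr: np.ndarray, voxel_size: np.ndarray) -> np.ndarray:
    """Central-difference spatial gradient (replicate borders), per-mm.

    ``arr`` may be 3D or 4D (trailing channel axis); output appends a
    length-3 axis for the spatial derivative.
    """
    padded = np.pad(arr, [(1, 1)] * 3 + [(0, 0)] * (arr.ndim - 3), mode="edge")
    grads = []
    for axis in range(3):
        hi = np.roll(padded, -1, axis=axis)
        lo = np.roll(padded, 1, axis=axis)
        core = tuple(slice(1, -1) for _ in range(3))
        grads.append((hi - lo)[core] / (2.0 * voxel_size[axis]))
    return np.stack(grads, axis=-1)


def _as_stack(img: ScalarImage | SHImage, skip_l0: bool) -> np.ndarray:
    """Channel stack (x, y, z, C): SH coefficients (optionally l >= 2 only)
    or a single scalar channel."""
    if isinstance(img, SHImage):
        start = n_coeffs(0) if skip_l0 else 0
        return img.coeffs[..., start:]
    return img.values[..., None]


def _local_stats(stack_a: np.ndarray, stack_b: np.ndarray, radius: int):
    """Neighbourhood-centred inner products summed over channels.

    Returns ``(n, mu_a, mu_b, cross, ss_a, ss_b)`` where ``cross``,
    ``ss_a``, ``ss_b`` are the centred sums <A,B>, <A>, <B> of the metric
    and ``mu_*`` the per-channel neighbourhood means.
    """
    n = neighborhood_count(stack_a.shape[:3], radius)
    s_a = np.stack([box_sum(stack_a[..., c], radius) for c in range(stack_a.shape[-1])], -1)
    s_b = np.stack([box_sum(stack_b[..., c], radius) for c in range(stack_b.shape[-1])], -1)
    mu_a = s_a / n[..., None]
    mu_b = s_b / n[..., None]
    cross = np.zeros(stack_a.shape[:3])
    ss_a = np.zeros(stack_a.shape[:3])
    ss_b = np.zeros(stack_a.shape[:3])
    for c in range(stack_a.shape[-1]):
        a, b = stack_a[..., c], stack_b[..., c]
        cross += box_sum(a * b, radius) - s_a[..., c] * s_b[..., c] / n
        ss_a += box_sum(a * a, radius) - s_a[..., c] ** 2 / n
        ss_b += box_sum(b * b, radius) - s_b[..., c] ** 2 / n
    # centred sums of squares are non-negative up to roundoff
    ss_a = np.maximum(ss_a, 0.0)
    ss_b = np.maximum(ss_b, 0.0)
    return n, mu_a, mu_b, cross, ss_a, ss_b


def _mask_array(mask: MaskImage | None, grid_shape) -> np.ndarray:
    if mask is None:
        return np.ones(grid_shape, dtype=bool)
    return mask.values.astype(bool)


def _epsilon(ss_a: np.ndarray, ss_b: np.ndarray, mask: np.ndarray) -> float:
    if not mask.any():
        return 0.0
    return EPS_FRACTION * 0.5 * float(ss_a[mask].mean() + ss_b[mask].mean())


def _correlation(fixed, moving, radius, mask, skip_l0) -> CorrelationMap:
    stack_a = _as_stack(fixed, skip_l0)
    stack_b = _as_stack(moving, skip_l0)
    inside = _mask_array(mask, stack_a.shape[:3])
    if stack_a.shape[-1] == 0:  # lmax 0 ODF: no l >= 2 content at all
        return CorrelationMap(
            np.zeros(stack_a.shape[:3]), np.zeros(stack_a.shape[:3], bool), fixed.voxel_to_world.copy()
        )
    _, _, _, cross, ss_a, ss_b = _local_stats(stack_a, stack_b, radius)
    eps = _epsilon(ss_a, ss_b, inside)
    defined = inside & (ss_a > eps) & (ss_b > eps)
    values = np.zeros(stack_a.shape[:3])
    np.divide(cross, np.sqrt(ss_a * ss_b), out=values, where=defined)
    values[defined] = np.clip(values[defined], -1.0, 1.0)
    return CorrelationMap(values, defined, fixed.voxel_to_world.copy())


def local_angular_correlation(
    fixed: SHImage, moving: SHImage, radius: int = 3, mask: MaskImage | None = None
) -> CorrelationMap:
    """Local angular correlation of two SH images (l >= 2 terms only)."""
    require_compatible_sh(fixed, moving)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return _correlation(fixed, moving, radius, mask, skip_l0=True)


def lncc(
    fixed: ScalarImage, moving: ScalarImage, radius: int = 3, mask: MaskImage | None = None
) -> CorrelationMap:
    """Local normalised cross-correlation of two scalar images."""
    require_same_grid(fixed, moving)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return _correlation(fixed, moving, radius, mask, skip_l0=False)


def _update_fields(fixed, moving, radius, mask, skip_l0) -> UpdateFieldPair:
    stack_a = _as_stack(fixed, skip_l0)
    stack_b = _as_stack(moving, skip_l0)
    shape = stack_a.shape[:3]
    inside = _mask_array(mask, shape)
    if stack_a.shape[-1] == 0:
        zero = np.zeros(shape + (3,))
        return UpdateFieldPair(zero.copy(), zero.copy())
    n, mu_a, mu_b, cross, ss_a, ss_b = _local_stats(stack_a, stack_b, radius)
    eps = _epsilon(ss_a, ss_b, inside)
    defined = inside & (ss_a > eps) & (ss_b > eps)

    centered_a = stack_a - mu_a
    centered_b = stack_b - mu_b
    voxel_size = fixed.voxel_size
    grad_a = central_gradient(centered_a, voxel_size)  # (x,y,z,C,3)
    grad_b = central_gradient(centered_b, voxel_size)

    with np.errstate(divide="ignore", invalid="ignore"):
        factor = 2.0 * cross / (ss_a * ss_b)
        ratio_a = cross / ss_a  # <A,B>/<A>
        ratio_b = cross / ss_b  # <A,B>/<B>
    factor = np.where(defined, factor, 0.0)
    ratio_a = np.where(defined, ratio_a, 0.0)
    ratio_b = np.where(defined, ratio_b, 0.0)

    resid_a = centered_b - ratio_a[..., None] * centered_a
    resid_b = centered_a - ratio_b[..., None] * centered_b
    lam_a = factor[..., None] * np.einsum("...c,...ci->...i", resid_a, grad_a)
    lam_b = factor[..., None] * np.einsum("...c,...ci->...i", resid_b, grad_b)
    lam_a[~defined] = 0.0
    lam_b[~defined] = 0.0
    return UpdateFieldPair(toward_fixed=lam_b, toward_moving=lam_a)


def lac_update_fields(
    fixed: SHImage, moving: SHImage, radius: int = 3, mask: MaskImage | None = None
) -> UpdateFieldPair:
    """Symmetric LAC demons update fields for an ODF channel pair."""
    require_compatible_sh(fixed, moving)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return _update_fields(fixed, moving, radius, mask, skip_l0=True)


def lncc_update_fields(
    fixed: ScalarImage, moving: ScalarImage, radius: int = 3, mask: MaskImage | None = None
) -> UpdateFieldPair:
    """Symmetric LNCC demons update fields for a scalar channel pair."""
    require_same_grid(fixed, moving)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return _update_fields(fixed, moving, radius, mask, skip_l0=False)
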