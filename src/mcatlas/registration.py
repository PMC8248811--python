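"""Symmetric multi-channel diffeomorphic-demons registration.

The registration operator takes two channel sets (scalar, mask and ODF
channels on a shared grid) and returns the pair of dense displacement
fields aligning them.  Per iteration, each channel contributes a
symmetric pair of demons update fields (LNCC for scalar/mask roles, LAC
for ODF roles); the per-channel updates are fused by certainty-gradient
weighting, Gaussian-smoothed, step-normalised and composed into the two
half-warps that deform fixed and moving toward a common midpoint.  A
multi-resolution pyramid with a per-level SH band-limit schedule follows
common ODF-registration practice.

Displacement convention (pull-back): a field ``u`` on the reference grid
resamples an image as ``warped(x) = image(x + u(x))`` in world mm, so the
returned ``warp_moving_to_fixed`` maps reference-space points into the
moving image's space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize

from .errors import ConfigurationError, InvalidFieldError, RegistrationError
from .images import (
    AffineTransform,
    AnyImage,
    Channel,
    ChannelSet,
    DisplacementField,
    MaskImage,
    ScalarImage,
    SHImage,
    world_coordinates,
)
from .metrics import (
    CorrelationMap,
    UpdateFieldPair,
    central_gradient,
    lac_update_fields,
    lncc,
    lncc_update_fields,
    local_angular_correlation,
)
from .resample import resample_image, sample_at_world, scaled_grid
from .sh import rotate_sh_batch

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RegistrationConfig:
    """Settings of the multi-resolution demons loop.

    Defaults follow common ODF-registration practice: three levels at
    relative scales {0.5, 0.75, 1.0} with SH band limits {0, 2, 2}, a
    3-voxel metric neighbourhood, 1-voxel smoothing of the fused update
    and 0.75-voxel smoothing of the composed displacement field.  The
    iteration caps, step size and convergence tolerance are this
    implementation's own declared defaults (configurable and logged).
    """

    level_scales: tuple[float, ...] = (0.5, 0.75, 1.0)
    lmax_schedule: tuple[int, ...] = (0, 2, 2)
    neighborhood_radius: int = 3
    sigma_update_voxels: float = 1.0
    sigma_displacement_voxels: float = 0.75
    max_iterations_per_level: tuple[int, ...] = (80, 60, 40)
    step_size_voxels: float = 0.5
    convergence_tolerance: float = 0.002
    metric_stop: float = 1e-6  # stop when mean correlation > 1 - metric_stop
    metric_improvement: float = 1e-6  # minimum mean-correlation gain per iteration
    plateau_patience: int = 15  # stop after this many non-improving iterations
    certainty_sh_l0_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.level_scales) != len(self.lmax_schedule):
            raise ConfigurationError("level_scales and lmax_schedule must have equal length")
        if len(self.max_iterations_per_level) != len(self.level_scales):
            raise ConfigurationError("max_iterations_per_level must match level count")
        if self.sigma_update_voxels <= 0 or self.sigma_displacement_voxels <= 0:
            raise ConfigurationError("smoothing sigmas must be positive")
        if any(l % 2 != 0 for l in self.lmax_schedule):
            raise ConfigurationError("lmax schedule entries must be even")


@dataclass
class CertaintyMap:
    """Gradient-magnitude channel weight, max-normalised to [0, 1]."""

    values: np.ndarray
    channel: str = ""


# ---------------------------------------------------------------------------
# certainty and fusion

def certainty_map(channel: AnyImage, name: str = "", sh_l0_only: bool = False) -> CertaintyMap:
    """Certainty weight of a channel: spatial-gradient magnitude,
    normalised so its maximum is exactly 1 (all-zero for constant input).

    For SH images the magnitude is the root sum of squares over all
    coefficients of the per-coefficient gradient norms (``sh_l0_only``
    restricts it to the isotropic l=0 coefficient).
    """
    if isinstance(channel, SHImage):
        stack = channel.coeffs[..., :1] if sh_l0_only else channel.coeffs
    else:
        stack = channel.values[..., None]
    grad = central_gradient(stack, channel.voxel_size)
    mag = np.sqrt(np.einsum("...ci,...ci->...", grad, grad))
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    return CertaintyMap(mag, name)


def fuse_updates(
    updates: list[UpdateFieldPair],
    certainties: list[CertaintyMap],
    certainties_toward_moving: list[CertaintyMap] | None = None,
) -> UpdateFieldPair:
    """Certainty-weighted per-voxel mean of channel update fields.

    ``certainties`` weights the toward-fixed direction; the toward-moving
    direction uses ``certainties_toward_moving`` when given (per-side
    certainty maps from the two warped channel stacks), else the same
    weights.  Voxels with zero total weight get a zero fused update.
    """
    if len(updates) != len(certainties):
        raise ConfigurationError(
            f"{len(updates)} update pairs but {len(certainties)} certainty maps"
        )
    if certainties_toward_moving is None:
        certainties_toward_moving = certainties
    elif len(certainties_toward_moving) != len(updates):
        raise ConfigurationError("per-side certainty list length mismatch")

    def _weighted(fields: list[np.ndarray], weights: list[CertaintyMap]) -> np.ndarray:
        total = np.zeros(fields[0].shape[:3])
        acc = np.zeros_like(fields[0])
        for f, w in zip(fields, weights):
            acc += w.values[..., None] * f
            total += w.values
        out = np.zeros_like(acc)
        np.divide(acc, total[..., None], out=out, where=total[..., None] > 0)
        return out

    return UpdateFieldPair(
        toward_fixed=_weighted([u.toward_fixed for u in updates], certainties),
        toward_moving=_weighted([u.toward_moving for u in updates], certainties_toward_moving),
    )


# ---------------------------------------------------------------------------
# warping

def _warp_jacobian(warp: DisplacementField) -> np.ndarray:
    """Per-voxel Jacobian of the total world mapping p -> p + u(p), (..., 3, 3)."""
    inv_lin = np.linalg.inv(warp.voxel_to_world[:3, :3])
    # du/dvoxel via central differences, then chain rule to world derivatives
    du = central_gradient(warp.vectors, np.ones(3))  # (..., comp, dvox)
    return np.eye(3) + du @ inv_lin


def _polar_rotations(jac: np.ndarray) -> np.ndarray:
    """Rotation factors of the polar decomposition J = R S, batched.

    Uses the scaled Newton iteration ``R <- (R + R^{-T}) / 2`` (quadratic
    convergence for matrices with positive determinant); voxels where the
    field folds (det <= 0) fall back to an SVD with reflection repair.
    """
    jac = np.asarray(jac, dtype=float)
    det = np.linalg.det(jac)
    bad = det <= 1e-8
    rot = jac.copy()
    if np.any(bad):
        u, _, vt = np.linalg.svd(jac[bad])
        fix = u @ vt
        neg = np.linalg.det(fix) < 0
        if np.any(neg):
            u = u.copy()
            u[neg, :, 2] *= -1
            fix = u @ vt
        rot[bad] = fix
    good = ~bad
    r = rot[good]
    for _ in range(30):
        r_new = 0.5 * (r + _inv3x3(np.swapaxes(r, -1, -2)))
        if np.abs(r_new - r).max() < 1e-10:
            r = r_new
            break
        r = r_new
    rot[good] = r
    return rot


def _inv3x3(m: np.ndarray) -> np.ndarray:
    """Batched 3x3 inverse via the cofactor formula (faster than LAPACK
    dispatch for large stacks of tiny matrices)."""
    a = m[..., 0, 0]; b = m[..., 0, 1]; c = m[..., 0, 2]
    d = m[..., 1, 0]; e = m[..., 1, 1]; f = m[..., 1, 2]
    g = m[..., 2, 0]; h = m[..., 2, 1]; i = m[..., 2, 2]
    co = np.empty_like(m)
    co[..., 0, 0] = e * i - f * h
    co[..., 0, 1] = c * h - b * i
    co[..., 0, 2] = b * f - c * e
    co[..., 1, 0] = f * g - d * i
    co[..., 1, 1] = a * i - c * g
    co[..., 1, 2] = c * d - a * f
    co[..., 2, 0] = d * h - e * g
    co[..., 2, 1] = b * g - a * h
    co[..., 2, 2] = a * e - b * d
    det = a * co[..., 0, 0] + b * co[..., 1, 0] + c * co[..., 2, 0]
    return co / det[..., None, None]


def warp_channelset(subject: ChannelSet, warp: DisplacementField) -> ChannelSet:
    """Resample every channel of a subject through a displacement field.

    Scalar channels: trilinear; masks: trilinear then >= 0.5 threshold;
    SH channels: per-coefficient trilinear followed by per-voxel
    reorientation with the rotational (polar) part of the local warp
    Jacobian, so fibre orientations follow the deformation.
    """
    if not np.all(np.isfinite(warp.vectors)):
        raise InvalidFieldError("displacement field contains non-finite values")
    pts = world_coordinates(warp.grid_shape, warp.voxel_to_world) + warp.vectors
    out_channels: list[Channel] = []
    rotations: np.ndarray | None = None
    for ch in subject:
        img = ch.image
        if isinstance(img, SHImage):
            coeffs = np.stack(
                [
                    sample_at_world(img.coeffs[..., c], img.voxel_to_world, pts)
                    for c in range(img.n_coeffs)
                ],
                axis=-1,
            )
            if img.lmax > 0:
                if rotations is None:
                    jac = _warp_jacobian(warp).reshape(-1, 3, 3)
                    # image content rotates with the *inverse* of the local
                    # pull-back Jacobian rotation
                    rotations = np.swapaxes(_polar_rotations(jac), -1, -2)
                flat = rotate_sh_batch(coeffs.reshape(-1, img.n_coeffs), rotations)
                coeffs = flat.reshape(coeffs.shape)
            out = SHImage(coeffs, img.lmax, warp.voxel_to_world.copy())
        else:
            vals = sample_at_world(img.values, img.voxel_to_world, pts)
            if isinstance(img, MaskImage) or ch.role == "mask":
                out = MaskImage((vals >= 0.5).astype(float), warp.voxel_to_world.copy())
            else:
                out = ScalarImage(vals, warp.voxel_to_world.copy())
        out_channels.append(Channel(ch.name, out, ch.role))
    return ChannelSet(subject.subject_id, subject.age, out_channels)


def apply_affine_to_channelset(
    subject: ChannelSet,
    affine: AffineTransform,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
) -> ChannelSet:
    """Resample channels through a world affine onto a target grid.

    The affine maps reference-space world points into the subject's
    world space (pull-back, same convention as displacement fields).
    SH channels are reoriented with the rotational part of the inverse
    linear map.
    """
    pts = world_coordinates(target_shape, np.asarray(target_affine, float))
    mapped = pts @ affine.matrix[:3, :3].T + affine.matrix[:3, 3]
    rot = _polar_rotations(affine.matrix[None, :3, :3])[0].T
    out_channels: list[Channel] = []
    for ch in subject:
        img = ch.image
        if isinstance(img, SHImage):
            coeffs = np.stack(
                [
                    sample_at_world(img.coeffs[..., c], img.voxel_to_world, mapped)
                    for c in range(img.n_coeffs)
                ],
                axis=-1,
            )
            if img.lmax > 0:
                flat = rotate_sh_batch(
                    coeffs.reshape(-1, img.n_coeffs),
                    np.broadcast_to(rot, (coeffs[..., 0].size, 3, 3)),
                )
                coeffs = flat.reshape(coeffs.shape)
            out: AnyImage = SHImage(coeffs, img.lmax, np.asarray(target_affine, float).copy())
        else:
            vals = sample_at_world(img.values, img.voxel_to_world, mapped)
            if isinstance(img, MaskImage) or ch.role == "mask":
                out = MaskImage((vals >= 0.5).astype(float), np.asarray(target_affine, float).copy())
            else:
                out = ScalarImage(vals, np.asarray(target_affine, float).copy())
        out_channels.append(Channel(ch.name, out, ch.role))
    return ChannelSet(subject.subject_id, subject.age, out_channels)


# ---------------------------------------------------------------------------
# displacement-field algebra

def compose_displacements(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Displacement of ``(id + outer) o (id + inner)``:
    ``w(x) = inner(x) + outer(x + inner(x))`` (fields share the grid)."""
    pts = world_coordinates(inner.grid_shape, inner.voxel_to_world) + inner.vectors
    sampled = np.stack(
        [sample_at_world(outer.vectors[..., c], outer.voxel_to_world, pts) for c in range(3)],
        axis=-1,
    )
    return DisplacementField(inner.vectors + sampled, inner.voxel_to_world.copy())


def invert_warp(
    warp: DisplacementField,
    max_iterations: int = 50,
    tolerance_voxels: float = 1e-3,
    residual_limit_voxels: float = 0.1,
    mask: MaskImage | None = None,
) -> DisplacementField:
    """Fixed-point inverse of a displacement field.

    Iterates ``v <- -u(x + v(x))`` until the update stalls; raises
    :class:`RegistrationError` with the residual if the composition
    ``max |u(x + v(x)) + v(x)|`` still exceeds ``residual_limit_voxels``
    after ``max_iterations``.
    """
    pts0 = world_coordinates(warp.grid_shape, warp.voxel_to_world)
    min_spacing = float(warp.voxel_size.min())
    v = np.zeros_like(warp.vectors)
    for _ in range(max_iterations):
        pts = pts0 + v
        u_at = np.stack(
            [sample_at_world(warp.vectors[..., c], warp.voxel_to_world, pts) for c in range(3)],
            axis=-1,
        )
        v_new = -u_at
        change = np.linalg.norm(v_new - v, axis=-1).max() / min_spacing
        v = v_new
        if change < tolerance_voxels:
            break
    residual = np.linalg.norm(
        np.stack(
            [
                sample_at_world(warp.vectors[..., c], warp.voxel_to_world, pts0 + v)
                for c in range(3)
            ],
            axis=-1,
        )
        + v,
        axis=-1,
    )
    region = mask.values.astype(bool) if mask is not None else np.ones(warp.grid_shape, bool)
    worst = float(residual[region].max()) / min_spacing
    if worst > residual_limit_voxels:
        raise RegistrationError(
            f"warp inversion did not converge: max residual {worst:.3f} voxels"
        )
    return DisplacementField(v, warp.voxel_to_world.copy())


def jacobian_map(warp: DisplacementField) -> ScalarImage:
    """Determinant of the Jacobian of the total mapping x -> x + u(x)."""
    jac = _warp_jacobian(warp)
    return ScalarImage(np.linalg.det(jac), warp.voxel_to_world.copy())


# ---------------------------------------------------------------------------
# affine pre-alignment

def _affine_from_params(params: np.ndarray, center: np.ndarray) -> np.ndarray:
    """12-parameter affine about a world centre: translation(3),
    rotation vector(3, rad), log-scales(3), shears(3)."""
    t, rvec, logs, sh = params[:3], params[3:6], params[6:9], params[9:12]
    angle = np.linalg.norm(rvec)
    if angle < 1e-12:
        rot = np.eye(3)
    else:
        k = rvec / angle
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * kx @ kx
    shear = np.eye(3)
    shear[0, 1], shear[0, 2], shear[1, 2] = sh
    lin = rot @ np.diag(np.exp(logs)) @ shear
    mat = np.eye(4)
    mat[:3, :3] = lin
    mat[:3, 3] = center - lin @ center + t
    return mat


def _global_ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def affine_register(
    fixed: ChannelSet,
    moving: ChannelSet,
    driver_channel: str,
    scales: tuple[float, ...] = (0.25, 0.5),
    seed: int = 0,
) -> AffineTransform:
    """12-parameter affine pre-alignment maximising global NCC.

    Deterministic multi-resolution Powell optimisation of the NCC between
    the fixed driver channel and the moving driver resampled through the
    candidate affine.  Returns the world affine mapping fixed-space
    points into the moving image's space (pull-back convention).
    """
    del seed  # optimisation is deterministic; kept for interface parity
    f_img = fixed[driver_channel].image
    m_img = moving[driver_channel].image
    if isinstance(f_img, SHImage) or isinstance(m_img, SHImage):
        raise ConfigurationError("affine driver channel must be scalar")
    center = np.asarray(
        world_coordinates(f_img.grid_shape, f_img.voxel_to_world).reshape(-1, 3).mean(axis=0)
    )
    params = np.zeros(12)
    extent = float(np.max(np.asarray(f_img.grid_shape) * f_img.voxel_size))
    for scale in tuple(scales) + (1.0,):
        shape, affine = scaled_grid(f_img.grid_shape, f_img.voxel_to_world, scale)
        f_level = resample_image(f_img, shape, affine)
        pts = world_coordinates(shape, affine)

        def negative_ncc(p: np.ndarray) -> float:
            mat = _affine_from_params(p, center)
            mapped = pts @ mat[:3, :3].T + mat[:3, 3]
            m_vals = sample_at_world(m_img.values, m_img.voxel_to_world, mapped)
            return -_global_ncc(f_level.values, m_vals)

        if negative_ncc(params) > -1e-6 and scale == tuple(scales)[0]:
            # flat start: probe coarse translations for an overlap
            best = (negative_ncc(params), params.copy())
            for shift in np.array(
                [[0, 0, 0]]
                + [v for v in np.eye(3) * extent / 4]
                + [v for v in -np.eye(3) * extent / 4]
            ):
                trial = params.copy()
                trial[:3] = shift
                val = negative_ncc(trial)
                if val < best[0]:
                    best = (val, trial)
            params = best[1]
            if best[0] > -1e-6:
                raise RegistrationError(
                    "affine initialisation found no overlap between images"
                )
        res = minimize(
            negative_ncc, params, method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 2000},
        )
        params = res.x
    return AffineTransform(_affine_from_params(params, center))


# ---------------------------------------------------------------------------
# the multi-channel demons operator

def _level_channelset(cs: ChannelSet, shape, affine, lmax: int) -> ChannelSet:
    chans = []
    for ch in cs:
        img = ch.image
        if isinstance(img, SHImage):
            img = img.truncated(lmax)
        elif isinstance(img, MaskImage):
            # masks are driven as soft 0/1 scalar channels during the
            # iterations (no re-thresholding between resamplings)
            img = ScalarImage(img.values, img.voxel_to_world)
        chans.append(Channel(ch.name, resample_image(img, shape, affine), ch.role))
    return ChannelSet(cs.subject_id, cs.age, chans)


def _resample_field(field_: DisplacementField, shape, affine) -> DisplacementField:
    pts = world_coordinates(shape, np.asarray(affine, float))
    vecs = np.stack(
        [sample_at_world(field_.vectors[..., c], field_.voxel_to_world, pts) for c in range(3)],
        axis=-1,
    )
    return DisplacementField(vecs, np.asarray(affine, float).copy())


def _smooth_field(vectors: np.ndarray, sigma_voxels: float) -> np.ndarray:
    return np.stack(
        [gaussian_filter(vectors[..., c], sigma=sigma_voxels) for c in range(3)], axis=-1
    )


def _channel_updates(
    f_ch: Channel, m_ch: Channel, radius: int, level_lmax: int
) -> tuple[UpdateFieldPair, CorrelationMap]:
    """Metric dispatch: LAC for ODF channels (falling back to LNCC on the
    isotropic l=0 coefficient when the level band limit is 0), LNCC for
    scalar and mask channels."""
    fi, mi = f_ch.image, m_ch.image
    if f_ch.role == "odf" and isinstance(fi, SHImage) and fi.lmax >= 2:
        pair = lac_update_fields(fi, mi, radius=radius)
        corr = local_angular_correlation(fi, mi, radius=radius)
        return pair, corr
    if isinstance(fi, SHImage):
        fi = ScalarImage(fi.coeffs[..., 0], fi.voxel_to_world)
        mi = ScalarImage(mi.coeffs[..., 0], mi.voxel_to_world)
    elif isinstance(fi, MaskImage):
        fi = ScalarImage(fi.values, fi.voxel_to_world)
        mi = ScalarImage(mi.values, mi.voxel_to_world)
    pair = lncc_update_fields(fi, mi, radius=radius)
    corr = lncc(fi, mi, radius=radius)
    del level_lmax
    return pair, corr


def register_multichannel(
    fixed: ChannelSet,
    moving: ChannelSet,
    config: RegistrationConfig | None = None,
) -> tuple[DisplacementField, DisplacementField]:
    """Symmetric multi-channel demons registration.

    Returns ``(warp_moving_to_fixed, warp_fixed_to_moving)``: pull-back
    displacement fields on the fixed/reference grid resampling the moving
    image into fixed space and vice versa.  The per-iteration mean metric
    values are logged.
    """
    config = config or RegistrationConfig()
    if fixed.names() != moving.names() or [c.role for c in fixed] != [c.role for c in moving]:
        raise ConfigurationError("fixed and moving channel names/roles must match")

    full_shape = fixed.grid_shape
    full_affine = fixed.voxel_to_world
    u_a: DisplacementField | None = None  # fixed -> midpoint half-warp
    u_b: DisplacementField | None = None  # moving -> midpoint half-warp

    for level, (scale, lmax, max_iter) in enumerate(
        zip(config.level_scales, config.lmax_schedule, config.max_iterations_per_level)
    ):
        shape, affine = scaled_grid(full_shape, full_affine, scale)
        f_level = _level_channelset(fixed, shape, affine, lmax)
        m_level = _level_channelset(moving, shape, affine, lmax)
        spacing = float(np.linalg.norm(np.asarray(affine)[:3, :3], axis=0).min())
        if u_a is None:
            u_a = DisplacementField(np.zeros(shape + (3,)), np.asarray(affine, float).copy())
            u_b = DisplacementField(np.zeros(shape + (3,)), np.asarray(affine, float).copy())
        else:
            u_a = _resample_field(u_a, shape, affine)
            u_b = _resample_field(u_b, shape, affine)

        prev_mean = np.inf
        rising = 0
        best_corr = -np.inf
        stalled = 0
        for iteration in range(max_iter):
            wf = warp_channelset(f_level, u_a)
            wm = warp_channelset(m_level, u_b)
            updates: list[UpdateFieldPair] = []
            cert_f: list[CertaintyMap] = []
            cert_m: list[CertaintyMap] = []
            corr_values = []
            for f_ch, m_ch in zip(wf, wm):
                pair, corr = _channel_updates(f_ch, m_ch, config.neighborhood_radius, lmax)
                updates.append(pair)
                cert_f.append(
                    certainty_map(f_ch.image, f_ch.name, config.certainty_sh_l0_only)
                )
                cert_m.append(
                    certainty_map(m_ch.image, m_ch.name, config.certainty_sh_l0_only)
                )
                corr_values.append(corr.mean())
            # metric-based stopping happens before the update is applied,
            # so already-aligned pairs are left untouched
            mean_corr = float(np.nanmean(corr_values))
            if mean_corr > 1.0 - config.metric_stop:
                logger.info("level %d: metric saturated (%.8f); stopping", level, mean_corr)
                break
            if mean_corr > best_corr + config.metric_improvement:
                best_corr = mean_corr
                stalled = 0
            else:
                stalled += 1
                if stalled >= config.plateau_patience:
                    logger.info("level %d: metric plateau after %d iterations", level, iteration)
                    break

            # toward_fixed acts on the moving side (weights from warped
            # moving channels); toward_moving on the fixed side
            fused = fuse_updates(updates, cert_m, cert_f)

            lam_b = _smooth_field(fused.toward_fixed, config.sigma_update_voxels)
            lam_a = _smooth_field(fused.toward_moving, config.sigma_update_voxels)
            peak = max(
                np.linalg.norm(lam_a, axis=-1).max(), np.linalg.norm(lam_b, axis=-1).max()
            )
            # demons step rule: the raw forces carry no length scale, so
            # each iteration is normalised to a fixed maximum step (the
            # metric-based stop above protects converged pairs)
            if peak > 0:
                rescale = config.step_size_voxels * spacing / peak
                lam_a = lam_a * rescale
                lam_b = lam_b * rescale
            mean_update = 0.5 * (
                np.linalg.norm(lam_a, axis=-1).mean() + np.linalg.norm(lam_b, axis=-1).mean()
            ) / spacing

            u_a = compose_displacements(u_a, DisplacementField(lam_a, u_a.voxel_to_world))
            u_b = compose_displacements(u_b, DisplacementField(lam_b, u_b.voxel_to_world))
            u_a = DisplacementField(
                _smooth_field(u_a.vectors, config.sigma_displacement_voxels), u_a.voxel_to_world
            )
            u_b = DisplacementField(
                _smooth_field(u_b.vectors, config.sigma_displacement_voxels), u_b.voxel_to_world
            )

            logger.info(
                "level %d iter %d: mean metric %s, mean update %.4f vox",
                level, iteration,
                "/".join(f"{v:.4f}" for v in corr_values), mean_update,
            )
            if mean_update < config.convergence_tolerance:
                break
            if mean_update > prev_mean:
                rising += 1
                if rising >= 10:
                    raise RegistrationError(
                        f"divergence at level {level}: mean update rose for 10 iterations"
                    )
            else:
                rising = 0
            prev_mean = mean_update

    assert u_a is not None and u_b is not None
    if tuple(u_a.grid_shape) != tuple(full_shape):
        u_a = _resample_field(u_a, full_shape, full_affine)
        u_b = _resample_field(u_b, full_shape, full_affine)

    u_a_inv = invert_warp(u_a, residual_limit_voxels=1.0)
    u_b_inv = invert_warp(u_b, residual_limit_voxels=1.0)
    warp_moving_to_fixed = compose_displacements(u_b, u_a_inv)
    warp_fixed_to_moving = compose_displacements(u_a, u_b_inv)
    return warp_moving_to_fixed, warp_fixed_to_moving
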