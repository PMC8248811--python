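"""Cohort-to-reference registration, age-windowed robust averaging, and
template unbiasing transforms.

Stage 1 registers every subject to a single structural reference using
scalar + mask driver channels and builds one global multi-channel
template by robust weighted averaging.  Stage 2 re-registers against
that template with the ODF channel added (normalised first), then
produces age-windowed templates (0.5-week windows over 37-44 weeks PMA)
and, per window, the unbiasing transforms: the average inverse warp and
the scale/shear-only average inverse affine that map the age-specific
average space back to the global reference space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, RegistrationError
from .images import (
    AffineTransform,
    AnyImage,
    Channel,
    ChannelSet,
    DisplacementField,
    MaskImage,
    ScalarImage,
    SHImage,
    require_same_grid,
)
from .registration import (
    RegistrationConfig,
    affine_register,
    apply_affine_to_channelset,
    invert_warp,
    register_multichannel,
    warp_channelset,
)
from .resample import resample_image, scaled_grid

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_CENTERS: tuple[float, ...] = tuple(np.arange(37.0, 44.01, 0.5))


@dataclass
class AgeWindow:
    center: float
    members: list[str]


@dataclass
class SubjectRecord:
    """Per-subject registration outputs on the reference grid."""

    channelset: ChannelSet  # native-space channels
    warp_to_reference: DisplacementField
    affine_to_reference: AffineTransform
    age: float


@dataclass
class TemplateSeries:
    """Per-window templates of one channel with retention weights."""

    channel: str
    centers: list[float]
    templates: list[AnyImage]
    weights: list[np.ndarray]  # per window: (n_members, x, y, z[, coeff]) binary

    def template_at(self, center: float) -> AnyImage:
        return self.templates[self.centers.index(center)]


@dataclass
class UnbiasingTransforms:
    """Average inverse transforms per age window (Fig-3 step B outputs)."""

    centers: list[float]
    warps: list[DisplacementField]
    affines: list[AffineTransform]  # scale/shear only


@dataclass
class AtlasConfig:
    window_centers: tuple[float, ...] = DEFAULT_WINDOW_CENTERS
    resolution_mm: float | None = 0.75  # None: keep the reference grid
    sd_threshold: float = 1.5
    stage1_channels: tuple[str, ...] | None = None  # None: intensity + mask roles
    stage2_channels: tuple[str, ...] | None = None  # None: stage1 + odf roles
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    min_subjects_per_window: int = 2
    seed: int = 0


def assign_age_windows(
    ages, centers=DEFAULT_WINDOW_CENTERS, subject_ids=None
) -> list[AgeWindow]:
    """Assign each subject to the nearest window centre (ties go to the
    younger window).  Empty windows are kept and reported."""
    centers = np.asarray(sorted(centers), dtype=float)
    ages = np.asarray(ages, dtype=float)
    if subject_ids is None:
        subject_ids = [str(i) for i in range(len(ages))]
    lo, hi = centers.min(), centers.max()
    outside = (ages < lo) | (ages > hi)
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} age(s) outside the window range [{lo}, {hi}]",
            stacklevel=2,
        )
    windows = [AgeWindow(float(c), []) for c in centers]
    for sid, age in zip(subject_ids, ages):
        dist = np.abs(centers - age)
        # ties resolved toward the younger (lower) centre: argmin takes
        # the first of equal distances, and centres are ascending
        windows[int(np.argmin(dist))].members.append(sid)
    for w in windows:
        if not w.members:
            logger.info("age window %.1f is empty", w.center)
    return windows


def _values(img: AnyImage) -> np.ndarray:
    return img.coeffs if isinstance(img, SHImage) else img.values


def robust_weighted_average(
    images: list[AnyImage], sd_threshold: float = 1.5
) -> tuple[AnyImage, np.ndarray]:
    """Outlier-rejecting voxelwise average across subjects.

    Per voxel (per coefficient for SH channels): values deviating from
    the across-subject mean by more than ``sd_threshold`` population
    standard deviations get weight 0, the rest weight 1, and the
    template is the weighted mean.  With the default threshold of 1.5 at
    least one subject is always retained (not every deviation can exceed
    1.5 SD), so the average is always defined.
    """
    if len(images) < 2:
        raise InsufficientDataError("robust averaging needs at least 2 images")
    require_same_grid(*images)
    stack = np.stack([_values(im) for im in images], axis=0)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)  # population SD
    omega = (np.abs(stack - mean) <= sd_threshold * sd) | (sd == 0)
    omega = omega.astype(float)
    template = (omega * stack).sum(axis=0) / omega.sum(axis=0)
    first = images[0]
    if isinstance(first, SHImage):
        out: AnyImage = SHImage(template, first.lmax, first.voxel_to_world.copy())
    elif isinstance(first, MaskImage):
        out = MaskImage((template >= 0.5).astype(float), first.voxel_to_world.copy())
    else:
        out = ScalarImage(template, first.voxel_to_world.copy())
    return out, omega


def average_inverse_warp(warps: list[DisplacementField]) -> DisplacementField:
    """Voxelwise mean of the inverted warps (template unbiasing, nonlinear
    part)."""
    if not warps:
        raise InsufficientDataError("no warps to average")
    inverted = [invert_warp(w, residual_limit_voxels=1.0) for w in warps]
    mean = np.mean([w.vectors for w in inverted], axis=0)
    return DisplacementField(mean, warps[0].voxel_to_world.copy())


def _symmetric_factor(linear: np.ndarray) -> np.ndarray:
    """S of the polar decomposition A = R S (symmetric positive-definite)."""
    w, v = np.linalg.eigh(linear.T @ linear)
    return (v * np.sqrt(np.maximum(w, 1e-30))) @ v.T


def _logm_spd(s: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(s)
    return (v * np.log(np.maximum(w, 1e-30))) @ v.T


def _expm_sym(s: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(s)
    return (v * np.exp(w)) @ v.T


def average_inverse_affine(affines: list[AffineTransform]) -> AffineTransform:
    """Scale/shear-only average inverse affine (unbiasing, affine part).

    Each linear part is polar-decomposed A = R S; the symmetric factors
    are averaged in matrix-logarithm space, the average inverted, and
    rotation/translation dropped.
    """
    if not affines:
        raise InsufficientDataError("no affines to average")
    logs = [_logm_spd(_symmetric_factor(a.matrix[:3, :3])) for a in affines]
    avg = _expm_sym(np.mean(logs, axis=0))
    mat = np.eye(4)
    mat[:3, :3] = np.linalg.inv(avg)
    return AffineTransform(mat, flags=frozenset({"scale", "shear"}))


def normalize_odf_channels(cohort: list[ChannelSet]) -> list[ChannelSet]:
    """Global intensity normalisation of ODF channels across a cohort.

    Each subject's SH image is scaled so its mean l=0 coefficient over
    voxels with appreciable signal equals the cohort median of those
    means; scalar and mask channels are untouched.
    """
    means: dict[str, float] = {}
    for cs in cohort:
        for ch in cs:
            if ch.role == "odf" and isinstance(ch.image, SHImage):
                l0 = ch.image.coeffs[..., 0]
                signal = np.abs(l0) > 1e-3 * np.abs(l0).max() if np.abs(l0).max() > 0 else np.zeros_like(l0, bool)
                means[cs.subject_id] = float(l0[signal].mean()) if signal.any() else 0.0
    if not means:
        return cohort
    target = float(np.median(list(means.values())))
    out = []
    for cs in cohort:
        chans = []
        for ch in cs:
            if ch.role == "odf" and isinstance(ch.image, SHImage) and means.get(cs.subject_id, 0.0) != 0.0:
                scale = target / means[cs.subject_id]
                chans.append(
                    Channel(ch.name, SHImage(ch.image.coeffs * scale, ch.image.lmax, ch.image.voxel_to_world.copy()), ch.role)
                )
            else:
                chans.append(ch)
        out.append(cs.with_channels(chans))
    return out


def _driver_names(reference: ChannelSet, config: AtlasConfig, stage: int) -> list[str]:
    if stage == 1 and config.stage1_channels is not None:
        return list(config.stage1_channels)
    if stage == 2 and config.stage2_channels is not None:
        return list(config.stage2_channels)
    names = [ch.name for ch in reference if ch.role in ("intensity", "mask")]
    if stage == 2:
        names += [ch.name for ch in reference if ch.role == "odf"]
    return names


def _reference_grid(reference: ChannelSet, config: AtlasConfig) -> ChannelSet:
    if config.resolution_mm is None:
        return reference
    spacing = reference.channels[0].image.voxel_size
    scale = float(np.mean(spacing)) / config.resolution_mm
    if abs(scale - 1.0) < 1e-6:
        return reference
    shape, affine = scaled_grid(reference.grid_shape, reference.voxel_to_world, scale)
    chans = [
        Channel(ch.name, resample_image(ch.image, shape, affine), ch.role) for ch in reference
    ]
    return reference.with_channels(chans)


def build_atlas_stage(
    cohort: list[ChannelSet],
    reference: ChannelSet,
    stage: int,
    config: AtlasConfig | None = None,
) -> tuple[list[SubjectRecord], dict[str, TemplateSeries], UnbiasingTransforms | None]:
    """One registration-and-averaging pass of the atlas pipeline.

    Stage 1: scalar + mask drivers against a single reference; one
    global template per channel (a TemplateSeries with a single entry).
    Stage 2: scalar + mask + normalised-ODF drivers against the stage-1
    template; age-windowed templates plus unbiasing transforms.
    Subjects whose registration fails are skipped with a logged reason
    as long as enough remain per window.
    """
    if not cohort:
        raise InsufficientDataError("empty cohort")
    if stage not in (1, 2):
        raise ValueError("stage must be 1 or 2")
    config = config or AtlasConfig()
    reference = _reference_grid(reference, config)
    drivers = _driver_names(reference, config, stage)
    if stage == 2:
        cohort = normalize_odf_channels(cohort)

    first_intensity = next(ch.name for ch in reference if ch.role == "intensity")
    records: list[SubjectRecord] = []
    warped_sets: list[ChannelSet] = []
    for cs in cohort:
        try:
            aff = affine_register(reference, cs, first_intensity, seed=config.seed)
            aligned = apply_affine_to_channelset(
                cs, aff, reference.grid_shape, reference.voxel_to_world
            )
            warp, _ = register_multichannel(
                reference.subset(drivers), aligned.subset(drivers), config.registration
            )
            records.append(SubjectRecord(cs, warp, aff, cs.age))
            warped_sets.append(warp_channelset(aligned, warp))
        except RegistrationError as exc:
            logger.warning("subject %s skipped: %s", cs.subject_id, exc)
    if len(records) < 2:
        raise InsufficientDataError("fewer than 2 subjects registered successfully")

    templates: dict[str, TemplateSeries] = {}
    if stage == 1:
        for name in reference.names():
            imgs = [ws[name].image for ws in warped_sets]
            template, omega = robust_weighted_average(imgs, config.sd_threshold)
            templates[name] = TemplateSeries(name, [float("nan")], [template], [omega])
        return records, templates, None

    windows = assign_age_windows(
        [r.age for r in records], config.window_centers, [r.channelset.subject_id for r in records]
    )
    by_id = {r.channelset.subject_id: (r, ws) for r, ws in zip(records, warped_sets)}
    unbias_centers: list[float] = []
    unbias_warps: list[DisplacementField] = []
    unbias_affines: list[AffineTransform] = []
    for name in reference.names():
        templates[name] = TemplateSeries(name, [], [], [])
    for window in windows:
        members = [by_id[sid] for sid in window.members]
        if len(members) < config.min_subjects_per_window:
            logger.info(
                "window %.1f has %d subject(s); skipped", window.center, len(members)
            )
            continue
        for name in reference.names():
            imgs = [ws[name].image for _, ws in members]
            if len(imgs) == 1:  # singleton window: nothing to reject
                template, omega = imgs[0].copy(), np.ones((1,) + _values(imgs[0]).shape)
            else:
                template, omega = robust_weighted_average(imgs, config.sd_threshold)
            ts = templates[name]
            ts.centers.append(window.center)
            ts.templates.append(template)
            ts.weights.append(omega)
        unbias_centers.append(window.center)
        unbias_warps.append(average_inverse_warp([r.warp_to_reference for r, _ in members]))
        unbias_affines.append(average_inverse_affine([r.affine_to_reference for r, _ in members]))
    unbias = UnbiasingTransforms(unbias_centers, unbias_warps, unbias_affines)
    return records, templates, unbias
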