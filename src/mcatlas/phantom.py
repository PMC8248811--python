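"""Seeded synthetic multi-channel cohort generator.

The phantom emulates the structure of a neonatal multi-channel dataset
at desk scale: an ellipsoidal "brain" with a cortical ribbon, a
ventricle, and two crossing white-matter bundles, imaged as T2w-like and
T1w-like scalar channels, cortex/ventricle mask channels and a real-SH
ODF channel.  Every voxel's scalar trajectory in age is *exactly* a
Gompertz curve: the four parameter maps are smoothed mixtures of
per-tissue parameter values (plus a static texture on the asymptotes),
and the signal at age t is the Gompertz function of those maps.  Ground
truth — the parameter maps, tissue labels, per-subject warps and clean
channel maps — is returned alongside, so registration, averaging,
temporal fitting and parcellation can all be checked against known
answers.

Channel realism is schematic (tissues and bundles, not anatomy); the
generator makes no attempt to simulate DWI acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .images import (
    Channel,
    ChannelSet,
    DisplacementField,
    MaskImage,
    ScalarImage,
    SHImage,
    n_coeffs,
)
from .registration import _warp_jacobian, warp_channelset
from .sh import direction_set, fit_sh_coefficients
from .temporal import gompertz

TISSUES = ("background", "wm", "cortex", "ventricle", "bundle")

# per-channel, per-tissue Gompertz truth (alpha, delta, gamma, tau):
# early/late asymptotes in channel units, rate per week, peak in weeks PMA.
# T2w-like signal falls with maturation, T1w-like rises; bundles mature
# faster than surrounding WM; CSF-filled ventricle is almost static.
DEFAULT_CURVES: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "t2w": {
        "background": (0.0, 0.0, 0.3, 40.5),
        "wm": (0.75, 0.58, 0.9, 40.5),
        "cortex": (0.68, 0.62, 0.7, 40.0),
        "ventricle": (0.95, 0.93, 0.3, 40.5),
        "bundle": (0.72, 0.52, 1.1, 40.3),
    },
    "t1w": {
        "background": (0.0, 0.0, 0.3, 40.5),
        "wm": (0.45, 0.70, 1.0, 40.5),
        "cortex": (0.55, 0.63, 0.7, 41.0),
        "ventricle": (0.20, 0.21, 0.3, 40.5),
        "bundle": (0.48, 0.80, 1.3, 40.2),
    },
    # ODF: l=0 amplitude over the brain, lobe amplitude over the bundles
    "odf_iso": {
        "background": (0.0, 0.0, 0.3, 40.5),
        "wm": (0.25, 0.28, 0.5, 40.5),
        "cortex": (0.25, 0.28, 0.5, 40.5),
        "ventricle": (0.25, 0.28, 0.5, 40.5),
        "bundle": (0.25, 0.28, 0.5, 40.5),
    },
    "odf_lobe": {
        "background": (0.0, 0.0, 0.5, 40.5),
        "wm": (0.0, 0.0, 0.5, 40.5),
        "cortex": (0.0, 0.0, 0.5, 40.5),
        "ventricle": (0.0, 0.0, 0.5, 40.5),
        "bundle": (0.40, 0.90, 1.0, 40.5),
    },
}


@dataclass
class PhantomSpec:
    """Generator settings; the defaults are the reference study conditions."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 1.0
    seed: int = 0
    lmax: int = 4
    brain_fraction: tuple[float, float, float] = (0.42, 0.38, 0.34)
    cortex_thickness_voxels: float = 2.5
    ventricle_fraction: tuple[float, float, float] = (0.09, 0.08, 0.08)
    ventricle_offset_fraction: tuple[float, float, float] = (0.0, 0.12, 0.03)
    bundle_radius_voxels: float = 3.5
    lobe_kappa: float = 8.0
    texture_amplitude: float = 0.08
    tissue_smoothing_voxels: float = 0.8
    curves: dict = field(default_factory=lambda: DEFAULT_CURVES)
    noise_sigma: float = 0.05  # fraction of each channel's dynamic range
    warp_amplitude_voxels: float = 2.0
    warp_wavelength_mm: float = 24.0

    def __post_init__(self) -> None:
        extent = min(self.grid_shape) * self.voxel_size_mm
        if self.warp_amplitude_voxels * self.voxel_size_mm > 0.25 * extent:
            raise ValueError("warp amplitude exceeds 25% of the grid extent")

    @property
    def voxel_to_world(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        return aff


@dataclass
class GompertzTruth:
    """Ground-truth Gompertz parameter maps of one scalar channel."""

    alpha: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    tau: np.ndarray

    def evaluate(self, t: float) -> np.ndarray:
        return gompertz(t, self.alpha, self.delta, self.gamma, self.tau)


@dataclass
class TemplateTruth:
    """Spec-level truth shared by all subjects of a cohort."""

    param_maps: dict[str, GompertzTruth]
    labels: dict[str, np.ndarray]
    bundle_directions: tuple[np.ndarray, np.ndarray]
    spec: PhantomSpec


@dataclass
class PhantomTruth:
    """Per-subject ground truth: the warp from template space (pull-back
    convention: subject(x) = clean(x + warp(x))) and the clean maps."""

    age: float
    warp: DisplacementField
    clean: ChannelSet


@dataclass
class CohortTruth:
    template: TemplateTruth
    subjects: list[PhantomTruth]

    @property
    def ages(self) -> list[float]:
        return [s.age for s in self.subjects]


# ---------------------------------------------------------------------------
# geometry and truth maps

def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semiaxes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _tube(shape, axis: int, center2: tuple[float, float], radius: float) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    other = [i for i in range(3) if i != axis]
    d2 = (grids[other[0]] - center2[0]) ** 2 + (grids[other[1]] - center2[1]) ** 2
    return d2 <= radius**2


def tissue_maps(spec: PhantomSpec) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """(soft tissue weights summing to 1, hard boolean label masks)."""
    shape = np.asarray(spec.grid_shape)
    center = (shape - 1) / 2.0
    brain_ax = shape * np.asarray(spec.brain_fraction)
    brain = _ellipsoid(spec.grid_shape, center, brain_ax)
    inner = _ellipsoid(spec.grid_shape, center, brain_ax - spec.cortex_thickness_voxels)
    cortex = brain & ~inner
    vent_center = center + shape * np.asarray(spec.ventricle_offset_fraction)
    ventricle = _ellipsoid(spec.grid_shape, vent_center, shape * np.asarray(spec.ventricle_fraction)) & inner
    b1 = _tube(spec.grid_shape, 0, (center[1] - 0.15 * shape[1], center[2]), spec.bundle_radius_voxels)
    b2 = _tube(spec.grid_shape, 1, (center[0], center[2]), spec.bundle_radius_voxels)
    bundle1 = b1 & inner & ~ventricle
    bundle2 = b2 & inner & ~ventricle
    bundle = bundle1 | bundle2

    hard = {
        "brain": brain,
        "inner": inner,
        "cortex": cortex,
        "ventricle": ventricle,
        "bundle1": bundle1,
        "bundle2": bundle2,
        "crossing": bundle1 & bundle2,
        "wm": inner & ~ventricle,
    }
    labels = np.zeros(spec.grid_shape, dtype=int)  # priority: later wins
    for i, mask in enumerate(
        [inner & ~ventricle & ~bundle, cortex, ventricle, bundle], start=1
    ):
        labels[mask] = i
    soft: dict[str, np.ndarray] = {}
    total = np.zeros(spec.grid_shape)
    for i, name in enumerate(TISSUES):
        onehot = (labels == i).astype(float)
        soft[name] = gaussian_filter(onehot, spec.tissue_smoothing_voxels)
        total += soft[name]
    for name in TISSUES:
        soft[name] /= total
    return soft, hard


def _mix_curves(spec: PhantomSpec, soft: dict[str, np.ndarray], channel: str) -> GompertzTruth:
    maps = []
    for k in range(4):
        acc = np.zeros(spec.grid_shape)
        for tissue in TISSUES:
            acc += soft[tissue] * spec.curves[channel][tissue][k]
        maps.append(acc)
    return GompertzTruth(*maps)


def template_truth(spec: PhantomSpec) -> TemplateTruth:
    """Deterministic template-space truth for a phantom specification."""
    soft, hard = tissue_maps(spec)
    rng = np.random.default_rng(spec.seed)
    inside = 1.0 - soft["background"]
    param_maps: dict[str, GompertzTruth] = {}
    for channel in ("t2w", "t1w"):
        truth = _mix_curves(spec, soft, channel)
        tex = gaussian_filter(rng.standard_normal(spec.grid_shape), 1.5)
        tex *= spec.texture_amplitude / max(np.abs(tex).max(), 1e-12)
        tex *= inside
        truth.alpha = truth.alpha + tex
        truth.delta = truth.delta + tex
        param_maps[channel] = truth
    param_maps["odf_iso"] = _mix_curves(spec, soft, "odf_iso")
    param_maps["odf_lobe"] = _mix_curves(spec, soft, "odf_lobe")
    dir1 = np.array([1.0, 0.0, 0.0])
    dir2 = np.array([0.0, 1.0, 0.0])
    return TemplateTruth(param_maps, hard, (dir1, dir2), spec)


def lobe_coefficients(direction: np.ndarray, lmax: int, kappa: float = 8.0) -> np.ndarray:
    """SH coefficients of a Watson-like single-fibre lobe along a direction,
    normalised to unit peak amplitude."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    grid = direction_set(724)
    amp = np.exp(kappa * ((grid @ d) ** 2 - 1.0))
    coeffs = fit_sh_coefficients(grid, amp, lmax)
    from .sh import real_sh_basis

    peak = float(real_sh_basis(d[None], lmax)[0] @ coeffs)
    return coeffs / peak


def clean_channelset(spec: PhantomSpec, age: float, truth: TemplateTruth | None = None) -> ChannelSet:
    """Template-space channels of a noise-free, unwarped subject at an age."""
    truth = truth or template_truth(spec)
    affine = spec.voxel_to_world
    soft, hard = tissue_maps(spec)
    channels = [
        Channel("t2w", ScalarImage(truth.param_maps["t2w"].evaluate(age), affine), "intensity"),
        Channel("t1w", ScalarImage(truth.param_maps["t1w"].evaluate(age), affine), "intensity"),
        Channel("cortex", MaskImage(hard["cortex"].astype(float), affine), "mask"),
        Channel("ventricle", MaskImage(hard["ventricle"].astype(float), affine), "mask"),
    ]
    iso = truth.param_maps["odf_iso"].evaluate(age)
    lobe_amp = truth.param_maps["odf_lobe"].evaluate(age)
    coeffs = np.zeros(spec.grid_shape + (n_coeffs(spec.lmax),))
    coeffs[..., 0] = iso
    soft_b1 = gaussian_filter(hard["bundle1"].astype(float), spec.tissue_smoothing_voxels)
    soft_b2 = gaussian_filter(hard["bundle2"].astype(float), spec.tissue_smoothing_voxels)
    total_b = np.maximum(soft_b1 + soft_b2, 1e-12)
    lobe1 = lobe_coefficients(truth.bundle_directions[0], spec.lmax, spec.lobe_kappa)
    lobe2 = lobe_coefficients(truth.bundle_directions[1], spec.lmax, spec.lobe_kappa)
    frac1 = np.where(soft_b1 + soft_b2 > 0, soft_b1 / total_b, 0.0)
    frac2 = np.where(soft_b1 + soft_b2 > 0, soft_b2 / total_b, 0.0)
    coeffs[..., 1:] += (lobe_amp * frac1)[..., None] * lobe1[None, None, None, 1:]
    coeffs[..., 1:] += (lobe_amp * frac2)[..., None] * lobe2[None, None, None, 1:]
    coeffs[..., 0] += lobe_amp * (frac1 * lobe1[0] + frac2 * lobe2[0])
    channels.append(Channel("odf", SHImage(coeffs, spec.lmax, affine), "odf"))
    return ChannelSet("template", float(np.clip(age, 20, 50)), channels)


# ---------------------------------------------------------------------------
# subject generation

def random_smooth_warp(
    spec: PhantomSpec, seed: int, amplitude_voxels: float | None = None
) -> DisplacementField:
    """A seeded smooth invertible displacement field: sums of random
    low-frequency separable sinusoids, amplitude-capped, with Jacobian
    positivity verified (and enforced by damping) at generation."""
    amp = spec.warp_amplitude_voxels if amplitude_voxels is None else amplitude_voxels
    field_ = np.zeros(spec.grid_shape + (3,))
    if amp <= 0:
        return DisplacementField(field_, spec.voxel_to_world)
    rng = np.random.default_rng(seed)
    shape = np.asarray(spec.grid_shape, dtype=float)
    extent = shape * spec.voxel_size_mm
    max_mode = np.maximum(1, np.floor(extent / spec.warp_wavelength_mm)).astype(int)
    grids = np.meshgrid(*(np.arange(s) for s in spec.grid_shape), indexing="ij")
    for comp in range(3):
        f = np.zeros(spec.grid_shape)
        for _ in range(3):
            k = [rng.integers(1, m + 1) for m in max_mode]
            ph = rng.uniform(0, 2 * np.pi, size=3)
            wave = np.ones(spec.grid_shape)
            for ax in range(3):
                wave = wave * np.sin(2 * np.pi * k[ax] * grids[ax] / shape[ax] + ph[ax])
            f += rng.standard_normal() * wave
        field_[..., comp] = f
    peak = np.linalg.norm(field_, axis=-1).max()
    field_ *= amp * spec.voxel_size_mm / max(peak, 1e-12)
    warp = DisplacementField(field_, spec.voxel_to_world)
    for _ in range(20):
        det = np.linalg.det(_warp_jacobian(warp))
        if det.min() > 0.05:
            break
        warp = DisplacementField(warp.vectors * 0.9, spec.voxel_to_world)
    return warp


def _add_noise(cs: ChannelSet, sigma_fraction: float, seed: int) -> ChannelSet:
    if sigma_fraction <= 0:
        return cs
    rng = np.random.default_rng(seed)
    channels = []
    for ch in cs:
        img = ch.image
        if ch.role == "mask":
            channels.append(ch)
            continue
        if isinstance(img, SHImage):
            coeffs = img.coeffs.copy()
            for c in range(img.n_coeffs):
                span = np.ptp(coeffs[..., c])
                coeffs[..., c] += sigma_fraction * span * rng.standard_normal(img.grid_shape)
            channels.append(Channel(ch.name, SHImage(coeffs, img.lmax, img.voxel_to_world.copy()), ch.role))
        else:
            span = np.ptp(img.values)
            vals = img.values + sigma_fraction * span * rng.standard_normal(img.grid_shape)
            channels.append(Channel(ch.name, ScalarImage(vals, img.voxel_to_world.copy()), ch.role))
    return cs.with_channels(channels)


def make_phantom_subject(
    spec: PhantomSpec,
    age: float,
    subject_seed: int,
    truth: TemplateTruth | None = None,
) -> tuple[ChannelSet, PhantomTruth]:
    """One synthetic subject: template maps at the given age, deformed by
    a seeded smooth random warp, with seeded additive noise."""
    truth = truth or template_truth(spec)
    clean = clean_channelset(spec, age, truth)
    warp = random_smooth_warp(spec, subject_seed)
    if np.any(warp.vectors != 0):
        subject = warp_channelset(clean, warp)
    else:
        subject = clean.copy()
    subject = _add_noise(subject, spec.noise_sigma, subject_seed + 1)
    subject = ChannelSet(f"sub-{subject_seed}", clean.age, subject.channels)
    return subject, PhantomTruth(age=clean.age, warp=warp, clean=clean)


def make_cohort(
    spec: PhantomSpec,
    n: int,
    age_range: tuple[float, float] = (37.0, 44.0),
    cohort_seed: int = 0,
) -> tuple[list[ChannelSet], CohortTruth]:
    """A seeded cohort with ages drawn uniformly over ``age_range``."""
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    truth = template_truth(spec)
    rng = np.random.default_rng(cohort_seed)
    ages = np.sort(rng.uniform(age_range[0], age_range[1], size=n))
    seeds = rng.integers(1, 2**31 - 1, size=n)
    subjects: list[ChannelSet] = []
    per_subject: list[PhantomTruth] = []
    for i, (age, seed) in enumerate(zip(ages, seeds)):
        cs, st = make_phantom_subject(spec, float(age), int(seed), truth)
        cs = ChannelSet(f"sub-{i:03d}", cs.age, cs.channels)
        subjects.append(cs)
        per_subject.append(st)
    return subjects, CohortTruth(truth, per_subject)
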