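"""Grid resampling utilities (trilinear, replicate borders).

Conventions: 0-based voxel indices, world coordinates in mm; sampling a
volume outside its grid replicates the nearest border value.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .images import AnyImage, MaskImage, ScalarImage, SHImage, world_coordinates


def sample_at_world(
    values: np.ndarray, voxel_to_world: np.ndarray, world_points: np.ndarray, order: int = 1
) -> np.ndarray:
    """Interpolate a 3D volume at world-mm points of shape (..., 3)."""
    inv = np.linalg.inv(voxel_to_world)
    vox = world_points @ inv[:3, :3].T + inv[:3, 3]
    flat = vox.reshape(-1, 3)
    out = map_coordinates(values, flat.T, order=order, mode="nearest")
    return out.reshape(world_points.shape[:-1])


def _resample_array(
    values: np.ndarray,
    voxel_to_world: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    presmooth_sigma: np.ndarray | None = None,
) -> np.ndarray:
    if presmooth_sigma is not None and np.any(presmooth_sigma > 0):
        values = gaussian_filter(values, sigma=presmooth_sigma)
    pts = world_coordinates(target_shape, target_affine)
    return sample_at_world(values, voxel_to_world, pts)


def _antialias_sigma(source_spacing: np.ndarray, target_spacing: np.ndarray) -> np.ndarray:
    """Gaussian presmoothing (in source voxels) before downsampling."""
    ratio = target_spacing / source_spacing
    return np.where(ratio > 1.0, 0.5 * np.sqrt(np.maximum(ratio**2 - 1.0, 0.0)), 0.0)


def resample_image(
    image: AnyImage,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    antialias: bool = True,
) -> AnyImage:
    """Resample an image onto a new grid (no ODF reorientation — intended
    for axis-aligned rescaling such as pyramid levels)."""
    target_affine = np.asarray(target_affine, dtype=float)
    src_spacing = image.voxel_size
    tgt_spacing = np.linalg.norm(target_affine[:3, :3], axis=0)
    sigma = _antialias_sigma(src_spacing, tgt_spacing) if antialias else None
    if isinstance(image, SHImage):
        coeffs = np.stack(
            [
                _resample_array(
                    image.coeffs[..., c], image.voxel_to_world, target_shape, target_affine, sigma
                )
                for c in range(image.n_coeffs)
            ],
            axis=-1,
        )
        return SHImage(coeffs, image.lmax, target_affine.copy())
    vals = _resample_array(image.values, image.voxel_to_world, target_shape, target_affine, sigma)
    if isinstance(image, MaskImage):
        return MaskImage((vals >= 0.5).astype(float), target_affine.copy())
    return ScalarImage(vals, target_affine.copy())


def scaled_grid(
    grid_shape: tuple[int, int, int], voxel_to_world: np.ndarray, scale: float
) -> tuple[tuple[int, int, int], np.ndarray]:
    """Grid of the same physical extent at ``scale`` times the resolution."""
    new_shape = tuple(max(2, int(round(s * scale))) for s in grid_shape)
    factors = np.array([ns / s for ns, s in zip(new_shape, grid_shape)])
    affine = np.asarray(voxel_to_world, dtype=float).copy()
    affine[:3, :3] = affine[:3, :3] / factors[None, :]
    return new_shape, affine
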