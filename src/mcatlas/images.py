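"""In-memory image containers shared by every pipeline stage.

All volumes live on a regular 3D grid with a ``voxel_to_world`` affine
(4x4, millimetres, RAS world axes, 0-based voxel indices).  Displacement
fields store world-mm 3-vectors per voxel of the *reference* grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import ChannelIncompatibilityError, GridMismatchError, InvalidFieldError


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"voxel_to_world must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("voxel_to_world is not invertible")
    return affine


@dataclass
class ScalarImage:
    """A 3D scalar channel (arbitrary channel units)."""

    values: np.ndarray
    voxel_to_world: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"ScalarImage needs a 3D array, got ndim={self.values.ndim}")
        self.voxel_to_world = _check_affine(self.voxel_to_world)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the linear part)."""
        return np.linalg.norm(self.voxel_to_world[:3, :3], axis=0)

    def copy(self) -> "ScalarImage":
        return ScalarImage(self.values.copy(), self.voxel_to_world.copy())


@dataclass
class MaskImage(ScalarImage):
    """A binary 3D mask (values in {0, 1})."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.values)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("MaskImage values must be binary 0/1")

    def copy(self) -> "MaskImage":
        return MaskImage(self.values.copy(), self.voxel_to_world.copy())


@dataclass
class SHImage:
    """A 4D grid of real even-order spherical-harmonic coefficient vectors.

    The 4th axis indexes coefficients in the package-wide (l, m)
    lexicographic order over even l (see :mod:`mcatlas.sh`).
    """

    coeffs: np.ndarray
    lmax: int
    voxel_to_world: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 4:
            raise ValueError("SHImage needs a 4D (x, y, z, coeff) array")
        if self.lmax % 2 != 0 or self.lmax < 0:
            raise ValueError(f"lmax must be even and non-negative, got {self.lmax}")
        n = n_coeffs(self.lmax)
        if self.coeffs.shape[3] != n:
            raise ValueError(
                f"lmax={self.lmax} implies {n} coefficients, got {self.coeffs.shape[3]}"
            )
        self.voxel_to_world = _check_affine(self.voxel_to_world)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.coeffs.shape[:3]  # type: ignore[return-value]

    @property
    def n_coeffs(self) -> int:
        return self.coeffs.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.voxel_to_world[:3, :3], axis=0)

    def copy(self) -> "SHImage":
        return SHImage(self.coeffs.copy(), self.lmax, self.voxel_to_world.copy())

    def truncated(self, lmax: int) -> "SHImage":
        """Keep only coefficients of degree <= lmax (band-limit reduction)."""
        if lmax >= self.lmax:
            return self.copy()
        return SHImage(self.coeffs[..., : n_coeffs(lmax)].copy(), lmax, self.voxel_to_world.copy())


def n_coeffs(lmax: int) -> int:
    """Number of real even-degree SH coefficients up to degree lmax."""
    if lmax % 2 != 0 or lmax < 0:
        raise ValueError(f"lmax must be even and non-negative, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


AnyImage = ScalarImage | MaskImage | SHImage

ROLE_INTENSITY = "intensity"
ROLE_ODF = "odf"
ROLE_MASK = "mask"
_ROLES = (ROLE_INTENSITY, ROLE_ODF, ROLE_MASK)


@dataclass
class Channel:
    name: str
    image: AnyImage
    role: str

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {_ROLES}")


@dataclass
class ChannelSet:
    """A subject's named, grid-shared channels plus age at scan (weeks PMA)."""

    subject_id: str
    age: float
    channels: list[Channel]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ChannelSet needs at least one channel")
        if not (20.0 <= self.age <= 50.0):
            raise ValueError(f"age {self.age} weeks outside sanity range [20, 50]")
        ref = self.channels[0].image
        for ch in self.channels[1:]:
            _require_same_grid(ref, ch.image)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.channels[0].image.grid_shape

    @property
    def voxel_to_world(self) -> np.ndarray:
        return self.channels[0].image.voxel_to_world

    def __iter__(self) -> Iterator[Channel]:
        return iter(self.channels)

    def __getitem__(self, name: str) -> Channel:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(name)

    def names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    def with_channels(self, channels: list[Channel]) -> "ChannelSet":
        return ChannelSet(self.subject_id, self.age, channels)

    def subset(self, names: list[str]) -> "ChannelSet":
        return self.with_channels([self[n] for n in names])

    def copy(self) -> "ChannelSet":
        return self.with_channels([replace(c, image=c.image.copy()) for c in self.channels])


@dataclass
class DisplacementField:
    """Per-voxel world-mm displacement 3-vectors on the reference grid."""

    vectors: np.ndarray
    voxel_to_world: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[3] != 3:
            raise ValueError("DisplacementField needs a (x, y, z, 3) array")
        if not np.all(np.isfinite(self.vectors)):
            raise InvalidFieldError("displacement field contains non-finite values")
        self.voxel_to_world = _check_affine(self.voxel_to_world)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.voxel_to_world[:3, :3], axis=0)

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.vectors.copy(), self.voxel_to_world.copy())

    @classmethod
    def zeros_like(cls, image: AnyImage | "DisplacementField") -> "DisplacementField":
        return cls(np.zeros(image.grid_shape + (3,)), image.voxel_to_world.copy())


@dataclass
class AffineTransform:
    """A 4x4 world-mm affine with flags for the components it carries."""

    matrix: np.ndarray
    flags: frozenset = frozenset({"rotation", "scale", "shear", "translation"})

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], (0, 0, 0, 1)):
            raise ValueError("last affine row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        self.flags = frozenset(self.flags)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.flags)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self @ other)(x) = self(other(x))."""
        return AffineTransform(self.matrix @ other.matrix, self.flags | other.flags)


def _require_same_grid(a, b) -> None:
    if a.grid_shape != b.grid_shape or not np.allclose(a.voxel_to_world, b.voxel_to_world, atol=1e-6):
        raise GridMismatchError(
            f"grids differ: {a.grid_shape} vs {b.grid_shape} or affines mismatch"
        )


def require_same_grid(*images) -> None:
    """Raise :class:`GridMismatchError` unless all images share a grid."""
    for img in images[1:]:
        _require_same_grid(images[0], img)


def require_compatible_sh(a: SHImage, b: SHImage) -> None:
    require_same_grid(a, b)
    if a.lmax != b.lmax:
        raise ChannelIncompatibilityError(f"lmax mismatch: {a.lmax} vs {b.lmax}")


def world_coordinates(grid_shape: tuple[int, int, int], voxel_to_world: np.ndarray) -> np.ndarray:
    """World-mm coordinates of every voxel centre, shape (x, y, z, 3)."""
    idx = np.stack(
        np.meshgrid(*(np.arange(s, dtype=float) for s in grid_shape), indexing="ij"), axis=-1
    )
    return idx @ voxel_to_world[:3, :3].T + voxel_to_world[:3, 3]
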