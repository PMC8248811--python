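"""Real even-order spherical harmonics: basis, evaluation, rotation.

Convention (used package-wide, including the coefficient axis of every
:class:`~mcatlas.images.SHImage` and all NIfTI files written by
:mod:`mcatlas.io`):

* real, orthonormal SH basis on the unit sphere with respect to the
  uniform measure, i.e. ``integral(Y_lm * Y_l'm') dOmega = delta``;
  ``Y_00 = 1/sqrt(4*pi)``;
* antipodally symmetric expansions: even degrees ``l = 0, 2, ..., lmax``
  only, hence ``(lmax+1)(lmax+2)/2`` coefficients;
* coefficient order is (l, m) lexicographic: degree ``l`` ascending over
  even values, order ``m = -l ... +l`` within each degree;
* real orders from the complex harmonics ``Y_l^m`` of scipy:
  ``m = 0`` -> ``Y_l^0`` (real),
  ``m > 0`` -> ``sqrt(2) * (-1)^m * Re(Y_l^m)``,
  ``m < 0`` -> ``sqrt(2) * (-1)^m * Im(Y_l^|m|)``.

Rotations act unitarily within each degree band; they are realised
numerically by an evaluate-rotate-refit construction on fixed direction
sets (least squares on a band-limited function is exact up to
conditioning), avoiding hand-coded Wigner recursions.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

from .errors import InvalidDirectionError, InvalidOrderError, InvalidRotationError
from .images import SHImage, n_coeffs

__all__ = [
    "n_coeffs",
    "sh_index_table",
    "real_sh_basis",
    "evaluate_odf",
    "rotate_sh",
    "rotate_sh_batch",
    "direction_set",
    "quadrature_weights",
    "fit_sh_coefficients",
]


def sh_index_table(lmax: int) -> list[tuple[int, int]]:
    """The (l, m) pair stored at each coefficient index, in package order."""
    if lmax % 2 != 0 or lmax < 0:
        raise InvalidOrderError(f"lmax must be even and non-negative, got {lmax}")
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def _check_directions(directions: np.ndarray) -> np.ndarray:
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.shape[-1] != 3:
        raise InvalidDirectionError("directions must be 3-vectors")
    norms = np.linalg.norm(directions, axis=-1)
    if np.any(norms < 1e-12):
        raise InvalidDirectionError("zero-norm direction")
    if np.any(np.abs(norms - 1.0) > 1e-8):
        raise InvalidDirectionError("directions must be unit-norm within 1e-8")
    return directions


def _real_sh_basis_reference(directions, lmax: int) -> np.ndarray:
    """Reference basis evaluation through scipy's complex harmonics."""
    d = _check_directions(directions)
    flat = d.reshape(-1, 3)
    theta = np.arccos(np.clip(flat[:, 2], -1.0, 1.0))
    phi = np.arctan2(flat[:, 1], flat[:, 0])

    out = np.empty((flat.shape[0], n_coeffs(lmax)))
    col = 0
    for l in range(0, lmax + 1, 2):
        # complex Y_l^m for m >= 0 feeds both +/- m real columns
        ylm = {m: sph_harm_y(l, m, theta, phi) for m in range(0, l + 1)}
        for m in range(-l, l + 1):
            if m == 0:
                out[:, col] = ylm[0].real
            elif m > 0:
                out[:, col] = np.sqrt(2.0) * (-1.0) ** m * ylm[m].real
            else:
                out[:, col] = np.sqrt(2.0) * (-1.0) ** m * ylm[-m].imag
            col += 1
    return out.reshape(d.shape[:-1] + (n_coeffs(lmax),))


def _monomial_exponents(degree: int) -> np.ndarray:
    return np.array(
        [
            (a, b, c)
            for a in range(degree + 1)
            for b in range(degree + 1 - a)
            for c in range(degree + 1 - a - b)
        ]
    )


@lru_cache(maxsize=None)
def _polynomial_coefficients(lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact monomial expansion of the basis on the unit sphere.

    Spherical harmonics of degree <= lmax restricted to the sphere are
    polynomials of degree <= lmax in (x, y, z), so a least-squares fit of
    monomial coefficients on a dense direction set is exact; it is
    validated against the reference evaluation at construction.
    """
    expo = _monomial_exponents(lmax)
    d = direction_set(724)
    mono = np.prod(d[:, None, :] ** expo[None, :, :], axis=-1)
    ref = _real_sh_basis_reference(d, lmax)
    coeff, *_ = np.linalg.lstsq(mono, ref, rcond=None)
    resid = np.abs(mono @ coeff - ref).max()
    if resid > 1e-9:
        raise RuntimeError(f"SH polynomial expansion inexact (residual {resid:.2e})")
    return expo, coeff


def real_sh_basis(directions, lmax: int) -> np.ndarray:
    """Basis matrix of real even-order SH values, (n_directions, n_coeffs).

    Columns follow the package (l, m) lexicographic order; the basis is
    orthonormal under the uniform spherical measure.  Evaluation uses a
    cached exact polynomial expansion (validated against the direct
    harmonic evaluation when built).
    """
    if lmax % 2 != 0 or lmax < 0:
        raise InvalidOrderError(f"lmax must be even and non-negative, got {lmax}")
    d = _check_directions(directions)
    if lmax > 12:
        return _real_sh_basis_reference(d, lmax)
    expo, coeff = _polynomial_coefficients(lmax)
    flat = d.reshape(-1, 3)
    out = np.empty((flat.shape[0], coeff.shape[1]))
    chunk = 1 << 19  # bound the monomial-table memory footprint
    for start in range(0, flat.shape[0], chunk):
        part = flat[start : start + chunk]
        powers = []
        for i in range(3):
            p = np.ones((part.shape[0], lmax + 1))
            for k in range(1, lmax + 1):
                np.multiply(p[:, k - 1], part[:, i], out=p[:, k])
            powers.append(p)
        mono = (
            powers[0][:, expo[:, 0]] * powers[1][:, expo[:, 1]] * powers[2][:, expo[:, 2]]
        )
        out[start : start + chunk] = mono @ coeff
    return out.reshape(d.shape[:-1] + (n_coeffs(lmax),))


def evaluate_odf(image: SHImage, voxel: tuple[int, int, int], directions) -> np.ndarray:
    """ODF amplitudes at one voxel along the given unit directions."""
    voxel = tuple(int(v) for v in voxel)
    for v, s in zip(voxel, image.grid_shape):
        if not 0 <= v < s:
            raise IndexError(f"voxel {voxel} outside grid {image.grid_shape}")
    basis = real_sh_basis(directions, image.lmax)
    return basis @ image.coeffs[voxel]


def _golden_hemisphere(n: int) -> np.ndarray:
    """n deterministic near-uniform points on the upper hemisphere."""
    k = np.arange(n, dtype=float)
    z = (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * k
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@lru_cache(maxsize=None)
def _direction_set_cached(size: int) -> np.ndarray:
    half = _golden_hemisphere(size // 2)
    # tiny fixed rotation breaks alignment of points with the grid axes
    rng = np.random.default_rng(1234)
    q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    half = half @ q.T
    pts = np.vstack([half, -half])
    pts.setflags(write=False)
    return pts


def direction_set(size: int = 300) -> np.ndarray:
    """A fixed near-uniform antipodally symmetric direction set.

    Sizes 60, 300 and 724 are the sets used throughout the package
    (oracles, reorientation, phantom peak checks); any even size works.
    """
    if size % 2 != 0 or size < 2:
        raise ValueError("direction set size must be even and >= 2")
    return _direction_set_cached(size)


def quadrature_weights(directions: np.ndarray, degree: int = 16) -> np.ndarray:
    """Spherical quadrature weights for a near-uniform direction set.

    Starts from uniform weights (4*pi/n each) and applies the least-norm
    correction that makes integration of all even-order SH up to
    ``degree`` exact; products of SH up to degree ``degree // 2`` are then
    integrated exactly, so Gram matrices come out orthonormal to machine
    precision.  Falls back to uniform weights if the set is too small to
    support the requested exactness.
    """
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    n = d.shape[0]
    w0 = np.full(n, 4.0 * np.pi / n)
    degree -= degree % 2
    while degree > 0 and n_coeffs(degree) > n // 2:
        degree -= 2
    if degree <= 0:
        return w0
    basis_t = real_sh_basis(d, degree).T
    target = np.zeros(basis_t.shape[0])
    target[0] = np.sqrt(4.0 * np.pi)  # integral of Y_00 over the sphere
    gram = basis_t @ basis_t.T
    lam = np.linalg.solve(gram, target - basis_t @ w0)
    return w0 + basis_t.T @ lam


def fit_sh_coefficients(directions, amplitudes: np.ndarray, lmax: int) -> np.ndarray:
    """Least-squares SH fit of sampled amplitudes (... , n_directions)."""
    basis = real_sh_basis(directions, lmax)
    coeffs, *_ = np.linalg.lstsq(basis, np.asarray(amplitudes, float).T, rcond=None)
    return coeffs.T


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise InvalidRotationError("rotation must be 3x3")
    if not np.allclose(rotation.T @ rotation, np.eye(3), atol=1e-6):
        raise InvalidRotationError("matrix is not orthogonal within 1e-6")
    if np.linalg.det(rotation) < 0:
        raise InvalidRotationError("matrix is a reflection (det < 0)")
    return rotation


@lru_cache(maxsize=None)
def _refit_operator(lmax: int, size: int) -> tuple[np.ndarray, np.ndarray]:
    """(directions, pseudo-inverse of the basis) for refit-based rotation."""
    d = direction_set(size)
    basis = real_sh_basis(d, lmax)
    return d, np.linalg.pinv(basis)


def rotate_sh(coeffs: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Rotate an SH coefficient vector by a proper rotation.

    The rotated function is ``f_R(d) = f(R^T d)``; band-limited refit on a
    dense fixed direction set makes this exact to numerical precision.
    """
    rotation = _check_rotation(rotation)
    coeffs = np.asarray(coeffs, dtype=float)
    lmax = _lmax_from_count(coeffs.shape[-1])
    d, pinv = _refit_operator(lmax, 300 if lmax <= 4 else 724)
    samples = real_sh_basis(d @ rotation, lmax) @ coeffs  # Y(R^T d) = Y((d^T R)^T)
    return pinv @ samples


def _lmax_from_count(n: int) -> int:
    lmax = 0
    while n_coeffs(lmax) < n:
        lmax += 2
    if n_coeffs(lmax) != n:
        raise InvalidOrderError(f"{n} is not an even-order SH coefficient count")
    return lmax


@lru_cache(maxsize=None)
def _batch_refit_operator(lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Small hemisphere direction set + basis pseudo-inverse for batches.

    Antipodal duplicates carry no information for even-order SH, so a
    hemisphere-only set keeps the per-voxel sample count low.
    """
    k = max(2 * n_coeffs(lmax), 12)
    d = _golden_hemisphere(k)
    rng = np.random.default_rng(4321)
    q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    d = d @ q.T
    basis = real_sh_basis(d, lmax)
    return d, np.linalg.pinv(basis)


def rotate_sh_batch(coeffs: np.ndarray, rotations: np.ndarray) -> np.ndarray:
    """Rotate N coefficient vectors by N rotations at once.

    Parameters
    ----------
    coeffs : (N, n_coeffs)
    rotations : (N, 3, 3) proper rotations (assumed valid; per-voxel
        polar factors from :func:`mcatlas.registration.warp_channelset`).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    rotations = np.asarray(rotations, dtype=float)
    lmax = _lmax_from_count(coeffs.shape[-1])
    if lmax == 0:
        return coeffs.copy()
    d, pinv = _batch_refit_operator(lmax)
    # rotated sample directions per voxel: R^T d_k  -> (N, K, 3)
    rot_dirs = np.einsum("kj,nji->nki", d, rotations)
    basis = real_sh_basis(rot_dirs.reshape(-1, 3), lmax).reshape(
        coeffs.shape[0], d.shape[0], -1
    )
    samples = np.einsum("nkc,nc->nk", basis, coeffs)
    return samples @ pinv.T
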