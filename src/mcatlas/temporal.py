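"""Gompertz-function parametrization of templates, warps and affines in time.

The growth model is the four-parameter Gompertz sigmoid

``G(t) = (alpha - delta) * exp(-exp(-gamma * (tau - t))) + delta``

with early asymptote ``alpha``, late asymptote ``delta``, growth rate
``gamma`` (per week, signed through the alpha/delta ordering) and
growth-peak time ``tau`` (weeks PMA).  It is fitted voxelwise to the
age-windowed template series, to each displacement component of the
per-window average inverse warps, and to each scale/shear entry of the
average inverse affines; together these form a continuous 4D atlas.

Fitting is nonlinear least squares, run as a Levenberg-Marquardt
iteration vectorised across all voxels simultaneously (analytic
Jacobian, box-projected bounds).  An ordinary linear fit is always
computed alongside for the goodness-of-fit comparison; voxels where the
nonlinear fit fails to beat the linear one fall back to a
near-linear parameter set and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .images import DisplacementField, MaskImage, ScalarImage, SHImage

GAMMA_BOUND = 5.0  # per week
GAMMA_MIN = 1e-3  # rate assigned to linear-fallback voxels
TAU_MARGIN = 4.0  # weeks beyond the fitted time range


def gompertz(t, alpha, delta, gamma, tau):
    """Evaluate the Gompertz growth function (broadcasting)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):  # saturates to the asymptote
        inner = np.exp(-np.exp(-gamma * (tau - t)))
    return (alpha - delta) * inner + delta


@dataclass
class GompertzParams:
    """Voxelwise Gompertz and linear fit results for one channel.

    All maps share the spatial shape of the fitted series (an extra
    trailing axis appears when a multi-component quantity such as SH
    coefficients or displacement components was fitted).
    """

    alpha: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    tau: np.ndarray
    r_squared: np.ndarray
    linear_slope: np.ndarray
    linear_intercept: np.ndarray
    linear_r_squared: np.ndarray
    fallback: np.ndarray  # True where the linear fallback replaced the fit
    t_range: tuple[float, float] = (37.0, 44.0)

    def evaluate(self, t: float) -> np.ndarray:
        return gompertz(t, self.alpha, self.delta, self.gamma, self.tau)


def _linear_fit(times: np.ndarray, series: np.ndarray):
    """OLS line per voxel; series shape (n_times, n_voxels)."""
    tm = times.mean()
    tc = times - tm
    denom = (tc**2).sum()
    slope = (tc[:, None] * series).sum(axis=0) / denom
    intercept = series.mean(axis=0) - slope * tm
    resid = series - (slope[None] * times[:, None] + intercept[None])
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((series - series.mean(axis=0)) ** 2).sum(axis=0)
    r2 = np.zeros_like(ss_res)
    np.divide(ss_res, ss_tot, out=r2, where=ss_tot > 0)
    r2 = np.where(ss_tot > 0, 1.0 - r2, 0.0)
    return slope, intercept, r2, ss_tot


def _initial_params(times: np.ndarray, series: np.ndarray, slope: np.ndarray):
    """Start values: asymptotes from the first/last thirds of the series
    (ordered by slope sign), tau at mid-range, gamma from the
    range-normalised central slope."""
    n = len(times)
    third = max(n // 3, 1)
    first = series[:third].mean(axis=0)
    last = series[-third:].mean(axis=0)
    alpha0 = first
    delta0 = last
    tau0 = np.full(series.shape[1], 0.5 * (times[0] + times[-1]))
    span = delta0 - alpha0
    gamma0 = np.where(
        np.abs(span) > 1e-12, np.clip(np.e * slope / np.where(span == 0, 1, span), -GAMMA_BOUND, GAMMA_BOUND), 0.5
    )
    gamma0 = np.where(np.abs(gamma0) < 0.05, np.sign(gamma0 + (gamma0 == 0)) * 0.5, gamma0)
    return np.stack([alpha0, delta0, gamma0, tau0], axis=0)


def _residual_and_jacobian(params: np.ndarray, times: np.ndarray, series: np.ndarray):
    alpha, delta, gamma, tau = params
    u = gamma[None] * (tau[None] - times[:, None])
    eu = np.exp(-np.clip(u, -60, 60))
    inner = np.exp(-eu)
    model = (alpha - delta)[None] * inner + delta[None]
    resid = model - series
    d_alpha = inner
    d_delta = 1.0 - inner
    common = (alpha - delta)[None] * inner * eu
    d_gamma = common * (tau[None] - times[:, None])
    d_tau = common * gamma[None]
    jac = np.stack([d_alpha, d_delta, d_gamma, d_tau], axis=-1)  # (T, V, 4)
    return resid, jac


def _lm_fit(times: np.ndarray, series: np.ndarray, params0: np.ndarray, bounds, n_iter: int = 60):
    """Batched Levenberg-Marquardt with box-projected parameters.

    times: (T,), series: (T, V), params0: (4, V).  Returns (params, ss_res).
    """
    lo, hi = bounds
    params = np.clip(params0, lo[:, None], hi[:, None])
    lam = np.full(series.shape[1], 1e-3)
    resid, jac = _residual_and_jacobian(params, times, series)
    cost = (resid**2).sum(axis=0)
    for _ in range(n_iter):
        jtj = np.einsum("tvi,tvj->vij", jac, jac)
        jtr = np.einsum("tvi,tv->vi", jac, resid)
        # the damping term keeps the normal matrix comfortably invertible
        ridge = np.maximum(lam, 1e-10) + 1e-12 * np.einsum("vii->v", jtj)
        a = jtj + ridge[:, None, None] * np.eye(4)[None]
        try:
            step = np.linalg.solve(a, jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(ai, ri, rcond=None)[0] for ai, ri in zip(a, jtr)])
        trial = np.clip(params - step.T, lo[:, None], hi[:, None])
        resid_t, jac_t = _residual_and_jacobian(trial, times, series)
        cost_t = (resid_t**2).sum(axis=0)
        improved = cost_t < cost
        params = np.where(improved[None], trial, params)
        resid = np.where(improved[None], resid_t, resid)
        jac = np.where(improved[None, :, None], jac_t, jac)
        cost = np.where(improved, cost_t, cost)
        lam = np.where(improved, lam * 0.4, lam * 3.0)
        lam = np.clip(lam, 1e-10, 1e8)
    return params, cost


def fit_gompertz_series(times, series: np.ndarray, n_iter: int = 60) -> GompertzParams:
    """Fit the Gompertz model independently to each series.

    Parameters
    ----------
    times : (T,) window centres in weeks.
    series : (T, ...) values per window; trailing axes are voxel/component
        axes and are fitted independently.
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 5:
        raise InsufficientDataError(
            f"need >= 5 time points to fit 4 parameters, got {len(times)}"
        )
    spatial_shape = series.shape[1:]
    flat = series.reshape(len(times), -1).astype(float)

    slope, intercept, lin_r2, ss_tot = _linear_fit(times, flat)
    params0 = _initial_params(times, flat, slope)
    lo = np.array([-np.inf, -np.inf, -GAMMA_BOUND, times.min() - TAU_MARGIN])
    hi = np.array([np.inf, np.inf, GAMMA_BOUND, times.max() + TAU_MARGIN])
    params, ss_res = _lm_fit(times, flat, params0, (lo, hi), n_iter=n_iter)

    r2 = np.zeros_like(ss_res)
    np.divide(ss_res, ss_tot, out=r2, where=ss_tot > 0)
    r2 = np.where(ss_tot > 0, 1.0 - r2, 0.0)

    # voxels where the nonlinear fit lost to the straight line fall back
    # to a near-linear Gompertz so downstream evaluation stays sane
    fallback = (r2 < lin_r2 - 1e-9) & (ss_tot > 0)
    if np.any(fallback):
        g_fb = np.where(slope >= 0, -GAMMA_MIN, GAMMA_MIN)  # early>late when slope<0
        t0, t1 = times.min(), times.max()
        alpha_fb = intercept + slope * t0
        delta_fb = intercept + slope * t1
        params = params.copy()
        params[0] = np.where(fallback, alpha_fb, params[0])
        params[1] = np.where(fallback, delta_fb, params[1])
        params[2] = np.where(fallback, np.abs(g_fb) * np.sign(g_fb), params[2])
        params[3] = np.where(fallback, 0.5 * (t0 + t1), params[3])
        r2 = np.where(fallback, lin_r2, r2)

    def shaped(a):
        return a.reshape(spatial_shape)

    return GompertzParams(
        alpha=shaped(params[0]),
        delta=shaped(params[1]),
        gamma=shaped(params[2]),
        tau=shaped(params[3]),
        r_squared=shaped(r2),
        linear_slope=shaped(slope),
        linear_intercept=shaped(intercept),
        linear_r_squared=shaped(lin_r2),
        fallback=shaped(fallback),
        t_range=(float(times.min()), float(times.max())),
    )


def fit_gompertz_maps(window_centers, templates: list[ScalarImage | SHImage]) -> GompertzParams:
    """Voxelwise Gompertz fit of an age-windowed template series.

    ``templates`` holds one image per window centre (scalar: one fit per
    voxel; SH: one fit per voxel per coefficient).
    """
    if len(templates) != len(window_centers):
        raise InsufficientDataError("one template per window centre required")
    arrays = [
        t.coeffs if isinstance(t, SHImage) else t.values for t in templates
    ]
    series = np.stack(arrays, axis=0)
    return fit_gompertz_series(window_centers, series)


def fit_gompertz_warps(window_centers, warps: list[DisplacementField]) -> GompertzParams:
    """Gompertz fit per displacement component of a warp series."""
    series = np.stack([w.vectors for w in warps], axis=0)
    return fit_gompertz_series(window_centers, series)


def fit_gompertz_affines(window_centers, affines: list[np.ndarray]) -> GompertzParams:
    """Gompertz fit per entry of a series of (scale/shear) matrices."""
    series = np.stack([np.asarray(a, dtype=float) for a in affines], axis=0)
    return fit_gompertz_series(window_centers, series)


@dataclass
class Atlas4D:
    """Continuous 4D multi-channel atlas: Gompertz curves per voxel per
    channel, plus fitted curves for the unbiasing warp components and
    the scale/shear affine entries."""

    channel_params: dict[str, GompertzParams]
    channel_kinds: dict[str, tuple[str, int]]  # name -> (scalar|mask|sh, lmax)
    warp_params: "GompertzParams | None"
    affine_params: "GompertzParams | None"
    grid_shape: tuple[int, int, int]
    voxel_to_world: np.ndarray
    t_range: tuple[float, float] = (37.0, 44.0)


def fit_atlas4d(templates, unbias, channel_roles: dict[str, str] | None = None) -> Atlas4D:
    """Fit Gompertz curves to age-windowed templates and unbiasing
    transforms (a :class:`~mcatlas.atlas.TemplateSeries` per channel and
    one :class:`~mcatlas.atlas.UnbiasingTransforms`)."""
    channel_params: dict[str, GompertzParams] = {}
    channel_kinds: dict[str, tuple[str, int]] = {}
    grid_shape = None
    affine = None
    roles = channel_roles or {}
    for name, series in templates.items():
        centers = series.centers
        channel_params[name] = fit_gompertz_maps(centers, series.templates)
        first = series.templates[0]
        grid_shape = first.grid_shape
        affine = first.voxel_to_world
        if isinstance(first, SHImage):
            channel_kinds[name] = ("sh", first.lmax)
        elif roles.get(name) == "mask" or isinstance(first, MaskImage):
            channel_kinds[name] = ("mask", 0)
        else:
            channel_kinds[name] = ("scalar", 0)
    warp_params = None
    affine_params = None
    if unbias is not None and unbias.centers:
        warp_params = fit_gompertz_warps(unbias.centers, unbias.warps)
        affine_params = fit_gompertz_affines(
            unbias.centers, [a.matrix[:3, :3] for a in unbias.affines]
        )
    assert grid_shape is not None and affine is not None
    t_all = [c for s in templates.values() for c in s.centers]
    return Atlas4D(
        channel_params, channel_kinds, warp_params, affine_params,
        grid_shape, affine, (float(min(t_all)), float(max(t_all))),
    )


def evaluate_atlas(
    atlas: Atlas4D,
    t: float,
    channels: list[str] | None = None,
    unbiased: bool = True,
):
    """Evaluate the 4D atlas at an age, optionally unbiased.

    Returns ``(maps, jacobian)``: the per-channel maps after applying
    the fitted inverse warp followed by the scale/shear inverse affine
    (SH channels reoriented), and the Jacobian-determinant map of the
    inverse warp (None when no warp curves are fitted).
    """
    from .images import AffineTransform, Channel, ChannelSet, DisplacementField
    from .registration import apply_affine_to_channelset, jacobian_map, warp_channelset

    lo, hi = atlas.t_range
    if not lo <= t <= hi:
        raise ValueError(f"t={t} outside the fitted range [{lo}, {hi}] (no extrapolation)")
    channels = channels or list(atlas.channel_params)
    chans = []
    for name in channels:
        params = atlas.channel_params[name]
        kind, lmax = atlas.channel_kinds[name]
        values = params.evaluate(t)
        if kind == "sh":
            img: ScalarImage | MaskImage | SHImage = SHImage(values, lmax, atlas.voxel_to_world.copy())
            role = "odf"
        elif kind == "mask":
            img = MaskImage((values >= 0.5).astype(float), atlas.voxel_to_world.copy())
            role = "mask"
        else:
            img = ScalarImage(values, atlas.voxel_to_world.copy())
            role = "intensity"
        chans.append(Channel(name, img, role))
    cs = ChannelSet("atlas", float(np.clip(t, 20, 50)), chans)

    jac = None
    if unbiased and atlas.warp_params is not None:
        warp = DisplacementField(atlas.warp_params.evaluate(t), atlas.voxel_to_world.copy())
        cs = warp_channelset(cs, warp)
        jac = jacobian_map(warp)
        if atlas.affine_params is not None:
            mat = np.eye(4)
            mat[:3, :3] = atlas.affine_params.evaluate(t)
            cs = apply_affine_to_channelset(
                cs, AffineTransform(mat, flags=frozenset({"scale", "shear"})),
                atlas.grid_shape, atlas.voxel_to_world,
            )
    return {ch.name: ch.image for ch in cs}, jac


def growth_peak_offset_map(
    params: GompertzParams,
    reference_t: float = 40.5,
    threshold: float = 0.2,
    voxel_to_world: np.ndarray | None = None,
) -> MaskImage:
    """Binary map of voxels whose growth peak tau is offset from the
    reference time by at least ``threshold`` weeks."""
    values = (np.abs(params.tau - reference_t) >= threshold).astype(float)
    affine = np.eye(4) if voxel_to_world is None else voxel_to_world
    return MaskImage(values, affine)
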