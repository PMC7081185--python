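"""Voxel-wise relaxometry: mono-exponential fitting and microvascular maps.

The measurement model throughout is S = S0·exp(−rate·x), with x either a
diffusion b-value (s·mm⁻², rate = ADC) or an echo time (ms, rate = R2 or
R2*).  Fits are nonlinear least squares initialized from a log-linear
regression and refined by a damped Gauss–Newton iteration, vectorized over
voxels.

Contrast-induced rate changes feed the microvascular index equations

    VSI = 0.424 · (D/Δω_c)^(1/2) · (ΔR2*/ΔR2)^(3/2)      [um]
    Q   = ΔR2 / (ΔR2*)^(2/3)                             [s^(-1/3)]
    MVD ≈ Q³ / (4.725·D)                                 [converted to mm^-2]

with D the water diffusion coefficient (um²/s) and Δω_c = γ·Δχ·B0 the
characteristic frequency of the contrast agent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EchoSeries",
    "ParameterMap",
    "fit_monoexponential",
    "fit_monoexponential_stack",
    "compute_adc_map",
    "compute_rate_map",
    "compute_delta_map",
    "compute_vsi",
    "compute_q",
    "compute_mvd",
    "vsi_from_rates",
    "q_from_rates",
    "mvd_from_q",
    "VSI_PREFACTOR",
    "MVD_DENOMINATOR",
    "DEFAULT_DELTA_R2_SCALE",
]

VSI_PREFACTOR = 0.424
MVD_DENOMINATOR = 4.725
#: calibration factor applied to fitted-echo-train ΔR2 maps
DEFAULT_DELTA_R2_SCALE = 4.375

#: background mask rule: a voxel is background when its maximum series
#: intensity is below this fraction of the series' 99th-percentile intensity
BACKGROUND_FRACTION = 0.05


@dataclass
class EchoSeries:
    """4-D intensity stack indexed by b-value or echo time.

    ``volumes`` has shape (n_points, nx, ny, nz); ``axis_values`` is the
    strictly increasing list of b-values (s·mm⁻²) or TEs (ms).
    """

    volumes: np.ndarray
    axis_values: np.ndarray
    axis_kind: str  # "bvalue" | "te"
    voxel_size: float = 1.0  # mm

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        self.axis_values = np.asarray(self.axis_values, dtype=np.float64)
        if self.axis_kind not in ("bvalue", "te"):
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4-D (points, x, y, z)")
        if len(self.axis_values) != self.volumes.shape[0]:
            raise ValueError("stack length must equal number of axis values")
        if np.any(np.diff(self.axis_values) <= 0):
            raise ValueError("axis_values must be strictly increasing")

    @property
    def shape(self) -> tuple:
        return self.volumes.shape[1:]


@dataclass
class ParameterMap:
    """3-D scalar map with units, validity mask and fit provenance."""

    values: np.ndarray
    units: str
    valid_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def same_geometry(self, other: "ParameterMap") -> bool:
        return self.values.shape == other.values.shape


def fit_monoexponential_stack(
    x: np.ndarray,
    signals: np.ndarray,
    point_mask: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit S = s0·exp(−rate·x) for many voxels at once.

    Parameters
    ----------
    x : (n,) array
        Abscissa values (b-values or TEs).
    signals : (m, n) array
        One row of signals per voxel.
    point_mask : (m, n) boolean array, optional
        Points to include per voxel (e.g. echoes above a noise floor);
        rows with fewer than 3 usable points are marked invalid.

    Returns
    -------
    s0, rate, ok : (m,) arrays
        Fitted amplitude and decay rate (in reciprocal units of x) and a
        validity flag.  Non-convergent or degenerate rows have ok=False.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(signals, dtype=np.float64)
    if y.ndim != 2 or y.shape[1] != x.size:
        raise ValueError("signals must have shape (n_voxels, n_points)")
    m, n = y.shape
    w = np.ones((m, n), dtype=bool) if point_mask is None else point_mask.copy()
    w &= y > 0
    npts = w.sum(axis=1)
    ok = npts >= 3

    # log-linear initialization (plain least squares on ln S)
    logy = np.where(w, np.log(np.where(y > 0, y, 1.0)), 0.0)
    sw = npts.astype(float)
    sx = (w * x).sum(axis=1)
    sxx = (w * x**2).sum(axis=1)
    sy = logy.sum(axis=1)
    sxy = (logy * x).sum(axis=1)
    denom = sw * sxx - sx**2
    safe = ok & (denom > 0)
    rate = np.zeros(m)
    loga = np.zeros(m)
    rate[safe] = -(sw[safe] * sxy[safe] - sx[safe] * sy[safe]) / denom[safe]
    loga[safe] = (sy[safe] - (-rate[safe]) * sx[safe]) / sw[safe]
    s0 = np.exp(loga)
    ok = safe

    # damped Gauss-Newton on (s0, rate)
    lam = np.full(m, 1e-8)
    act = ok.copy()
    model = s0[:, None] * np.exp(-rate[:, None] * x[None, :])
    resid = np.where(w, model - y, 0.0)
    ssr = (resid**2).sum(axis=1)
    for _ in range(max_iter):
        if not act.any():
            break
        e = np.exp(-rate[:, None] * x[None, :])
        j0 = np.where(w, e, 0.0)  # d model / d s0
        j1 = np.where(w, -s0[:, None] * x[None, :] * e, 0.0)  # d model / d rate
        g0 = (j0 * resid).sum(axis=1)
        g1 = (j1 * resid).sum(axis=1)
        h00 = (j0 * j0).sum(axis=1)
        h01 = (j0 * j1).sum(axis=1)
        h11 = (j1 * j1).sum(axis=1)
        a00 = h00 * (1 + lam)
        a11 = h11 * (1 + lam)
        det = a00 * a11 - h01**2
        good = act & (det > 0)
        d0 = np.zeros(m)
        d1 = np.zeros(m)
        d0[good] = (a11[good] * g0[good] - h01[good] * g1[good]) / det[good]
        d1[good] = (a00[good] * g1[good] - h01[good] * g0[good]) / det[good]
        s0_new = np.where(good, s0 - d0, s0)
        rate_new = np.where(good, rate - d1, rate)
        model = s0_new[:, None] * np.exp(-rate_new[:, None] * x[None, :])
        resid_new = np.where(w, model - y, 0.0)
        ssr_new = (resid_new**2).sum(axis=1)
        improved = good & (ssr_new <= ssr)
        s0 = np.where(improved, s0_new, s0)
        rate = np.where(improved, rate_new, rate)
        resid = np.where(improved[:, None], resid_new, resid)
        lam = np.where(improved, lam * 0.3, lam * 10.0)
        step = np.maximum(
            np.abs(d0) / np.maximum(np.abs(s0), 1e-30),
            np.abs(d1) * np.maximum(np.abs(x).max(), 1.0),
        )
        converged = improved & (ssr - ssr_new <= tol * np.maximum(ssr, 1e-300))
        converged |= act & (step < 1e-14)
        ssr = np.where(improved, ssr_new, ssr)
        act &= ~converged
        act &= lam < 1e12
    bad = ~np.isfinite(s0) | ~np.isfinite(rate) | (s0 <= 0)
    ok &= ~bad
    return s0, rate, ok


def fit_monoexponential(x, signals) -> tuple[float, float]:
    """Single-voxel S = s0·exp(−rate·x) fit; raises on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(y <= 0):
        raise ValueError("signals must be positive")
    s0, rate, ok = fit_monoexponential_stack(x, y[None, :])
    if not ok[0]:
        raise RuntimeError("mono-exponential fit did not converge")
    return float(s0[0]), float(rate[0])


def _series_mask(series: EchoSeries) -> np.ndarray:
    """Background mask: max intensity below 5% of the 99th percentile."""
    peak = series.volumes.max(axis=0)
    floor = BACKGROUND_FRACTION * np.percentile(series.volumes, 99)
    return peak >= floor


def _fit_series(
    series: EchoSeries, noise_floor: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    shape = series.shape
    fg = _series_mask(series)
    y = series.volumes.reshape(len(series.axis_values), -1).T  # (m, n)
    sel = fg.ravel()
    pm = None
    if noise_floor is not None and noise_floor > 0:
        pm = y[sel] > noise_floor
    s0v, ratev, okv = fit_monoexponential_stack(series.axis_values, y[sel], pm)
    s0 = np.zeros(shape).ravel()
    rate = np.zeros(shape).ravel()
    ok = np.zeros(y.shape[0], dtype=bool)
    s0[sel] = s0v
    rate[sel] = ratev
    ok[sel] = okv
    return s0.reshape(shape), rate.reshape(shape), ok.reshape(shape)


def compute_adc_map(dwi: EchoSeries) -> ParameterMap:
    """Voxel-wise ADC (um²/s) from a diffusion-weighted series.

    b-values are in s·mm⁻², so the fitted rate is in mm²/s and is scaled
    by 1e6 to um²/s.
    """
    if dwi.axis_kind != "bvalue":
        raise ValueError("compute_adc_map requires a b-value series")
    _, rate, ok = _fit_series(dwi)
    return ParameterMap(
        rate * 1e6, "um^2/s", ok, {"fit": "monoexponential", "unit_scale": 1e6}
    )


def compute_rate_map(
    series: EchoSeries, kind: str = "r2", noise_floor: float | None = None
) -> ParameterMap:
    """Voxel-wise R2 or R2* (s⁻¹) from a multi-echo series (TE in ms).

    ``noise_floor``: optional intensity below which echoes are excluded
    per voxel (threshold fitting near the Rician noise floor); voxels left
    with fewer than 3 echoes become invalid.
    """
    if series.axis_kind != "te":
        raise ValueError("compute_rate_map requires a TE series")
    if kind not in ("r2", "r2star"):
        raise ValueError(f"unknown rate kind {kind!r}")
    _, rate, ok = _fit_series(series, noise_floor=noise_floor)
    return ParameterMap(
        rate * 1e3,
        "s^-1",
        ok,
        {"fit": "monoexponential", "kind": kind, "noise_floor": noise_floor},
    )


def compute_delta_map(
    pre: EchoSeries,
    post: EchoSeries,
    mode: str = "fitted_train",
    scale_factor: float | None = None,
    noise_floor: float | None = None,
) -> ParameterMap:
    """Contrast-induced rate change ΔR2 (or ΔR2*) map, in s⁻¹.

    ``fitted_train``: ΔR = R_post − R_pre from per-voxel echo-train fits,
    multiplied by ``scale_factor`` (default 4.375, the echo-train ΔR2
    calibration; pass 1.0 explicitly for ΔR2*).  ``first_echo``:
    ΔR = −ln(S_post(TE1)/S_pre(TE1))/TE1, scale 1.0 unless overridden.

    Negative-ΔR voxels are kept in the raw map but marked invalid so they
    are excluded from VSI/Q/MVD.
    """
    if mode not in ("fitted_train", "first_echo"):
        raise ValueError(f"unknown delta-map mode {mode!r}")
    if pre.shape != post.shape:
        raise ValueError("pre and post series must share geometry")
    if not np.allclose(pre.axis_values, post.axis_values):
        raise ValueError("pre and post series must share axis values")
    if scale_factor is None:
        scale_factor = DEFAULT_DELTA_R2_SCALE if mode == "fitted_train" else 1.0

    if mode == "fitted_train":
        _, rate_pre, ok_pre = _fit_series(pre, noise_floor=noise_floor)
        _, rate_post, ok_post = _fit_series(post, noise_floor=noise_floor)
        delta = (rate_post - rate_pre) * 1e3 * scale_factor
        ok = ok_pre & ok_post
    else:
        te1 = pre.axis_values[0] * 1e-3
        s_pre = pre.volumes[0]
        s_post = post.volumes[0]
        fg = _series_mask(pre) & _series_mask(post) & (s_pre > 0) & (s_post > 0)
        delta = np.zeros(pre.shape)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(fg, s_post / np.where(s_pre > 0, s_pre, 1.0), 1.0)
        delta[fg] = -np.log(ratio[fg]) / te1
        delta *= scale_factor
        ok = fg
    ok = ok & (delta > 0)
    return ParameterMap(
        delta, "s^-1", ok, {"mode": mode, "scale_factor": scale_factor}
    )


# ---------------------------------------------------------------------------
# microvascular indices


def vsi_from_rates(
    delta_r2: float, delta_r2_star: float, D: float, delta_omega_c: float
) -> float:
    """Vessel size index (um) from scalar rates."""
    if delta_r2 <= 0 or delta_r2_star <= 0:
        raise ValueError("rates must be positive for VSI")
    return (
        VSI_PREFACTOR
        * np.sqrt(D / delta_omega_c)
        * (delta_r2_star / delta_r2) ** 1.5
    )


def q_from_rates(delta_r2: float, delta_r2_star: float) -> float:
    """Microvessel density index Q (s^-1/3) from scalar rates."""
    if delta_r2_star <= 0:
        raise ValueError("delta_r2_star must be positive for Q")
    return delta_r2 / delta_r2_star ** (2.0 / 3.0)


def mvd_from_q(q: float, D: float) -> float:
    """Microvessel density (mm^-2) from Q (s^-1/3) and D (um²/s)."""
    if D <= 0:
        raise ValueError("D must be positive")
    return q**3 / (MVD_DENOMINATOR * D) * 1e6


def _check_geometry(a: ParameterMap, b: ParameterMap) -> None:
    if not a.same_geometry(b):
        raise ValueError(
            f"map geometry mismatch: {a.values.shape} vs {b.values.shape}"
        )


def compute_vsi(
    delta_r2_map: ParameterMap,
    delta_r2_star_map: ParameterMap,
    D: float,
    delta_omega_c: float,
) -> ParameterMap:
    """Voxel-wise vessel size index map (um)."""
    if D <= 0:
        raise ValueError("D must be positive")
    _check_geometry(delta_r2_map, delta_r2_star_map)
    dr2 = delta_r2_map.values
    dr2s = delta_r2_star_map.values
    ok = (
        delta_r2_map.valid_mask
        & delta_r2_star_map.valid_mask
        & (dr2 > 0)
        & (dr2s > 0)
    )
    vsi = np.zeros_like(dr2)
    vsi[ok] = (
        VSI_PREFACTOR * np.sqrt(D / delta_omega_c) * (dr2s[ok] / dr2[ok]) ** 1.5
    )
    return ParameterMap(vsi, "um", ok, {"D": D, "delta_omega_c": delta_omega_c})


def compute_q(
    delta_r2_map: ParameterMap, delta_r2_star_map: ParameterMap
) -> ParameterMap:
    """Voxel-wise Q map (s^-1/3)."""
    _check_geometry(delta_r2_map, delta_r2_star_map)
    dr2 = delta_r2_map.values
    dr2s = delta_r2_star_map.values
    ok = delta_r2_map.valid_mask & delta_r2_star_map.valid_mask & (dr2s > 0)
    # Q = 0 where dR2 = 0 is well-defined; negative dR2 is excluded upstream
    q = np.zeros_like(dr2)
    q[ok] = np.maximum(dr2[ok], 0.0) / dr2s[ok] ** (2.0 / 3.0)
    return ParameterMap(q, "s^-1/3", ok, {})


def compute_mvd(q_map: ParameterMap, D: float) -> ParameterMap:
    """Voxel-wise microvessel density map (mm^-2)."""
    if D <= 0:
        raise ValueError("D must be positive")
    mvd = q_map.values**3 / (MVD_DENOMINATOR * D) * 1e6
    return ParameterMap(mvd, "mm^-2", q_map.valid_mask.copy(), {"D": D})
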