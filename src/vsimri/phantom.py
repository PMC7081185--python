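"""Seeded synthetic phantoms with known ground truth.

Two generator families cover every pipeline input:

* a brain-like multi-contrast phantom — two half-ellipsoid hemispheres
  with a cortical shell, a subcortical ischemic-edema lesion (lower ADC,
  higher VSI, lower Q), and pre/post-contrast relaxation-rate truth maps
  constructed by *inverting* the VSI and Q equations, so the mapping
  stage has an exact target; and
* tubular vascular phantoms of known radius for segmentation and
  diameter morphometry.

All generators are pure functions of (spec, seed).  Noise is Rician
(magnitude MRI): sqrt((S + n1)^2 + n2^2) with n1, n2 ~ N(0, sigma) and
sigma = S0 / SNR.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .physics import PhysicsConfig, characteristic_frequency
from .relaxometry import (
    DEFAULT_DELTA_R2_SCALE,
    EchoSeries,
    MVD_DENOMINATOR,
    VSI_PREFACTOR,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_brain_phantom",
    "render_series",
    "make_vascular_tree",
    "rates_from_indices",
    "PROTOCOLS",
]

#: acquisition axes: DWI b-values (s mm^-2), spin-echo and gradient-echo
#: echo trains (ms)
DWI_BVALUES = np.array([100.0, 200.0, 400.0, 600.0, 800.0, 1000.0])
MSME_TES = np.arange(8.0, 160.0 + 1e-9, 8.0)
MEGE_TES = np.arange(3.0, 59.0 + 1e-9, 4.0)

PROTOCOLS = {
    "dwi": ("bvalue", DWI_BVALUES),
    "msme_pre": ("te", MSME_TES),
    "msme_post": ("te", MSME_TES),
    "mege_pre": ("te", MEGE_TES),
    "mege_post": ("te", MEGE_TES),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue values and noise level of the brain phantom.

    ADC in um²/s, VSI in um, Q in s^(-1/3); the defaults straddle the
    printed cutoffs (650 um²/s, 10 um, 200 mm⁻²) in the directions seen
    in subcortical ischemic edema: lower ADC, higher VSI, lower Q.
    """

    grid_dims: tuple = (96, 96, 48)
    voxel_size: float = 0.3  # mm
    semi_axes: tuple = (40.0, 32.0, 20.0)  # voxels
    midline_gap: float = 1.0  # voxels
    cortex_fraction: float = 0.14  # outer shell of the ellipsoid radius
    lesion_center: tuple = (30.0, 48.0, 24.0)  # voxels, ipsilateral side
    lesion_radius: float = 9.0  # voxels
    adc_normal: float = 750.0
    adc_lesion: float = 500.0
    vsi_normal: float = 4.0
    vsi_lesion: float = 12.0
    q_normal: float = 1.07
    q_lesion: float = 0.6
    r2_pre: float = 15.0  # s^-1
    r2star_pre: float = 30.0  # s^-1
    D: float = 800.0  # um^2/s
    delta_r2_scale: float = DEFAULT_DELTA_R2_SCALE
    s0: float = 1000.0
    snr: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.adc_lesion < 650.0 < self.adc_normal):
            raise ValueError("lesion/normal ADC must straddle 650 um^2/s")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")


@dataclass
class PhantomTruth:
    """Ground-truth maps, ROI masks and the generating spec."""

    spec: PhantomSpec
    brain_mask: np.ndarray
    maps: dict  # adc, r2_pre, r2_post, r2star_pre, r2star_post,
    #              vsi, q, mvd, delta_r2, delta_r2_star
    rois: dict  # ipsi/contra x cortex/subcortex, lesion


def rates_from_indices(
    vsi_um: float, q: float, D: float, delta_omega_c: float
) -> tuple[float, float]:
    """Invert the VSI and Q equations: (VSI, Q) -> (ΔR2, ΔR2*).

    With ρ = (VSI / (0.424·sqrt(D/Δω_c)))^(2/3) the rate ratio, the
    equations give ΔR2* = (ρ·Q)³ and ΔR2 = ΔR2*/ρ.
    """
    if vsi_um <= 0 or q <= 0:
        raise ValueError("VSI and Q must be positive")
    rho = (vsi_um / (VSI_PREFACTOR * np.sqrt(D / delta_omega_c))) ** (2.0 / 3.0)
    if rho < 1.0:
        raise ValueError(
            f"VSI {vsi_um} um implies rate ratio {rho:.3f} < 1 (ΔR2* < ΔR2)"
        )
    delta_r2_star = (rho * q) ** 3
    delta_r2 = delta_r2_star / rho
    if delta_r2 <= 0 or delta_r2_star <= 0:
        raise ValueError("inconsistent lesion spec: non-positive rates")
    return float(delta_r2), float(delta_r2_star)


def _ellipsoid_rho(spec: PhantomSpec) -> np.ndarray:
    dims = spec.grid_dims
    center = (np.asarray(dims, float) - 1.0) / 2.0
    ax = np.asarray(spec.semi_axes, float)
    x, y, z = np.ogrid[0 : dims[0], 0 : dims[1], 0 : dims[2]]
    return np.sqrt(
        ((x - center[0]) / ax[0]) ** 2
        + ((y - center[1]) / ax[1]) ** 2
        + ((z - center[2]) / ax[2]) ** 2
    )


def make_brain_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build the piecewise-constant truth maps and ROI masks."""
    dims = spec.grid_dims
    rho = _ellipsoid_rho(spec)
    brain = rho <= 1.0
    xmid = (dims[0] - 1) / 2.0
    x = np.arange(dims[0], dtype=float)[:, None, None]
    gap = np.abs(x - xmid) <= spec.midline_gap / 2.0
    brain &= ~np.broadcast_to(gap, dims)
    ipsi = np.broadcast_to(x < xmid, dims) & brain
    contra = brain & ~ipsi

    cortex = brain & (rho > 1.0 - spec.cortex_fraction)
    subcortex = brain & ~cortex

    if spec.lesion_radius > 0:
        cx, cy, cz = spec.lesion_center
        gx, gy, gz = np.ogrid[0 : dims[0], 0 : dims[1], 0 : dims[2]]
        lesion = (
            (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2 <= spec.lesion_radius**2
        )
        if not lesion.any():
            raise ValueError("lesion sphere contains no voxels")
        if not np.all(subcortex[lesion] & ipsi[lesion]):
            raise ValueError("lesion must lie inside the ipsilateral subcortex")
    else:
        lesion = np.zeros(dims, dtype=bool)

    physics = PhysicsConfig()
    dwc = characteristic_frequency(physics)
    dr2_n, dr2s_n = rates_from_indices(spec.vsi_normal, spec.q_normal, spec.D, dwc)
    dr2_l, dr2s_l = rates_from_indices(spec.vsi_lesion, spec.q_lesion, spec.D, dwc)

    def paint(normal_val: float, lesion_val: float) -> np.ndarray:
        m = np.zeros(dims)
        m[brain] = normal_val
        m[lesion] = lesion_val
        return m

    adc = paint(spec.adc_normal, spec.adc_lesion)
    vsi = paint(spec.vsi_normal, spec.vsi_lesion)
    q = paint(spec.q_normal, spec.q_lesion)
    delta_r2 = paint(dr2_n, dr2_l)
    delta_r2_star = paint(dr2s_n, dr2s_l)
    mvd = q**3 / (MVD_DENOMINATOR * spec.D) * 1e6
    mvd[~brain] = 0.0

    maps = {
        "adc": adc,
        "vsi": vsi,
        "q": q,
        "mvd": mvd,
        "delta_r2": delta_r2,
        "delta_r2_star": delta_r2_star,
        "r2_pre": np.where(brain, spec.r2_pre, 0.0),
        # the echo-train-fitted ΔR2 underestimates the simulation-scale ΔR2
        # by the calibration factor, so the rendered post-contrast R2 grows
        # by ΔR2 / scale
        "r2_post": np.where(brain, spec.r2_pre, 0.0)
        + delta_r2 / spec.delta_r2_scale,
        "r2star_pre": np.where(brain, spec.r2star_pre, 0.0),
        "r2star_post": np.where(brain, spec.r2star_pre, 0.0) + delta_r2_star,
    }
    rois = {
        "ipsi_cortex": ipsi & cortex,
        "contra_cortex": contra & cortex,
        "ipsi_subcortex": ipsi & subcortex,
        "contra_subcortex": contra & subcortex,
        "lesion": lesion,
    }
    return PhantomTruth(spec=spec, brain_mask=brain, maps=maps, rois=rois)


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def render_series(
    truth: PhantomTruth,
    protocol: str,
    snr: float | None = None,
    seed: int | None = None,
) -> EchoSeries:
    """Render a noisy acquisition series from the truth maps.

    ``snr=inf`` (or None with spec.snr=inf) renders noiseless signals.
    DWI decays with the ADC map over the b-value axis; the multi-echo
    spin-echo (msme) and gradient-echo (mege) series decay with the
    corresponding pre/post R2(*) maps over their echo trains.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected {sorted(PROTOCOLS)}")
    axis_kind, axis = PROTOCOLS[protocol]
    spec = truth.spec
    snr = spec.snr if snr is None else snr
    seed = spec.seed if seed is None else seed

    if protocol == "dwi":
        rate = truth.maps["adc"] * 1e-6  # um^2/s -> mm^2/s, per b in s/mm^2
    else:
        key = {
            "msme_pre": "r2_pre",
            "msme_post": "r2_post",
            "mege_pre": "r2star_pre",
            "mege_post": "r2star_post",
        }[protocol]
        rate = truth.maps[key] * 1e-3  # s^-1 -> per ms of TE
    s0 = np.where(truth.brain_mask, spec.s0, 0.0)
    signal = s0[None, ...] * np.exp(-rate[None, ...] * axis[:, None, None, None])
    if np.isfinite(snr):
        # stable per-protocol stream (string hash is process-randomized)
        tag = zlib.crc32(protocol.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng((seed, tag))
        signal = _rician(rng, signal, spec.s0 / snr)
    return EchoSeries(signal, axis, axis_kind, voxel_size=spec.voxel_size)


def make_vascular_tree(
    grid_dims,
    voxel_size: float,
    segments,
    intensities: tuple = (100.0, 10.0),
    noise: float = 0.0,
    seed: int = 0,
):
    """Rasterize tubular segments of known radius.

    ``segments`` is a list of (start, end, radius) in voxel coordinates /
    voxel units.  Returns (intensity volume, exact boolean mask,
    per-segment truth dicts with radius, length and voxel count).
    Overlapping segments are allowed; a zero radius raises.
    """
    dims = np.asarray(grid_dims, dtype=int)
    fg, bg = intensities
    mask = np.zeros(tuple(dims), dtype=bool)
    gx, gy, gz = np.meshgrid(*(np.arange(d, dtype=float) for d in dims), indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    truth = []
    for start, end, radius in segments:
        if radius <= 0:
            raise ValueError("segment radius must be positive")
        a = np.asarray(start, float)
        b = np.asarray(end, float)
        if np.any(a < 0) or np.any(b < 0) or np.any(a >= dims) or np.any(b >= dims):
            raise ValueError("segments must lie inside the grid")
        ab = b - a
        ab2 = float(ab @ ab)
        d = pts - a
        t = np.clip((d @ ab) / ab2 if ab2 > 0 else 0.0, 0.0, 1.0)
        closest = a + t[..., None] * ab
        dist2 = ((pts - closest) ** 2).sum(axis=-1)
        seg_mask = dist2 <= radius**2
        mask |= seg_mask
        truth.append(
            {
                "radius": float(radius),
                "length": float(np.sqrt(ab2)),
                "n_voxels": int(seg_mask.sum()),
                "mask": seg_mask,
            }
        )
    volume = np.where(mask, fg, bg).astype(float)
    if noise > 0:
        rng = np.random.default_rng(seed)
        volume = volume + rng.normal(0.0, noise, size=volume.shape)
    return volume, mask, truth
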