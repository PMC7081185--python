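"""Random cylinder substrates representing microvessel networks.

Vessels are modelled as randomly oriented, randomly positioned cylinders of
a single radius inside a periodic cubic grid.  Cylinders are added one at a
time until the occupied volume fraction first reaches the requested blood
volume fraction (Bvf); the last cylinder is trimmed in length so the
achieved Bvf lands close to the target even when a single full-length
cylinder would overshoot it (which happens for large radii on small grids).

Rasterization stamps each cylinder as a dense union of digital balls along
its axis (sample spacing 0.5 voxel), wrapped periodically.  A voxel with
integer centre v is occupied when ``|v - p| <= r`` for some axis sample p,
the same digital-ball convention used by the morphometry module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CylinderSubstrate", "generate_cylinder_substrate"]

_AXIS_SAMPLE_SPACING = 0.5  # voxels


@dataclass
class CylinderSubstrate:
    """A periodic binary vessel grid plus the generating cylinders.

    ``cylinders`` holds (point-on-axis [um], unit direction, radius [um],
    length [um]) tuples.  ``line_density_per_um2`` is the stereological
    areal vessel density: for isotropically oriented lines of total length
    density L_V (length per volume), a random unit-area cross-section
    intersects L_V / 2 of them.
    """

    cylinders: list
    occupancy: np.ndarray
    achieved_bvf: float
    target_bvf: float
    radius: float
    voxel_size: float
    grid_dims: tuple

    @property
    def total_length_um(self) -> float:
        return float(sum(c[3] for c in self.cylinders))

    @property
    def line_density_per_um2(self) -> float:
        vol = float(np.prod(self.grid_dims)) * self.voxel_size**3
        return 0.5 * self.total_length_um / vol

    @property
    def density_per_mm2(self) -> float:
        """Ground-truth areal vessel density in mm^-2."""
        return self.line_density_per_um2 * 1e6


def _ball_offsets(radius_vox: float) -> np.ndarray:
    """Integer offsets within radius_vox + 1 of the origin (margin for the
    fractional part of sample positions)."""
    m = int(np.ceil(radius_vox)) + 1
    ax = np.arange(-m, m + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    keep = (offs**2).sum(axis=1) <= (radius_vox + 1.0) ** 2
    return offs[keep]


def _stamp_indices(
    samples: np.ndarray, radius_vox: float, dims: np.ndarray, offs: np.ndarray
) -> list[np.ndarray]:
    """Flat voxel indices covered by a ball around each axis sample.

    Returns one index array per sample so callers can trim the cylinder to
    a sample prefix.  Periodic wrap via modulo.
    """
    out = []
    chunk = max(1, int(2e6 // max(len(offs), 1)))
    r2 = radius_vox**2
    for s0 in range(0, len(samples), chunk):
        pts = samples[s0 : s0 + chunk]
        base = np.floor(pts).astype(np.int64)
        frac = pts - base
        # (S, M, 3) displacement of candidate voxel centres from the sample
        d = offs[None, :, :] - frac[:, None, :]
        inside = (d**2).sum(axis=2) <= r2
        vox = (base[:, None, :] + offs[None, :, :]) % dims
        flat = vox[..., 0] * dims[1] * dims[2] + vox[..., 1] * dims[2] + vox[..., 2]
        for i in range(len(pts)):
            out.append(flat[i][inside[i]])
    return out


def generate_cylinder_substrate(
    grid_dims,
    voxel_size: float,
    radius: float,
    target_bvf: float,
    seed: int | np.random.SeedSequence = 0,
    bvf_tolerance: float = 0.10,
    max_cylinders: int = 100_000,
    orientation=None,
) -> CylinderSubstrate:
    """Generate a periodic substrate of randomly oriented cylinders.

    Parameters
    ----------
    grid_dims : tuple of int
        Grid size in voxels.
    voxel_size : float
        Isotropic voxel edge, micrometres.
    radius : float
        Cylinder radius, micrometres (must be >= voxel_size).
    target_bvf : float
        Target occupied volume fraction, in [0, 0.5).
    seed : int or numpy SeedSequence
        RNG seed.
    bvf_tolerance : float
        Maximum allowed relative deviation of achieved from target Bvf.
    orientation : 3-vector, optional
        Force every cylinder to this axis direction (testing aid, e.g.
        axis-aligned analytic cases); default random orientations.

    Raises
    ------
    RuntimeError
        If the target cannot be reached within ``max_cylinders`` or the
        achieved Bvf falls outside the tolerance.
    """
    dims = np.asarray(grid_dims, dtype=np.int64)
    if dims.shape != (3,) or np.any(dims < 1):
        raise ValueError("grid_dims must be three positive integers")
    occupancy = np.zeros(tuple(dims), dtype=bool)
    if target_bvf == 0:
        return CylinderSubstrate(
            [], occupancy, 0.0, 0.0, radius, voxel_size, tuple(int(d) for d in dims)
        )
    if not (0 < target_bvf < 0.5):
        raise ValueError("target_bvf must be in (0, 0.5)")
    if radius < voxel_size:
        raise ValueError(
            f"radius ({radius} um) must be at least one voxel ({voxel_size} um)"
        )

    rng = np.random.default_rng(seed)
    n_total = int(np.prod(dims))
    target_count = target_bvf * n_total
    r_vox = radius / voxel_size
    offs = _ball_offsets(r_vox)
    flat = occupancy.ravel()
    # full cylinder length: the longest chord of the box, so any orientation
    # can cross it completely
    full_len_vox = float(np.sqrt(3.0) * dims.max())
    n_samples_full = int(np.ceil(full_len_vox / _AXIS_SAMPLE_SPACING)) + 1

    cylinders: list = []
    count = 0
    for _ in range(max_cylinders):
        if count >= target_count:
            break
        point = rng.uniform(0.0, dims.astype(float))
        if orientation is not None:
            direction = np.asarray(orientation, float)
            direction = direction / np.linalg.norm(direction)
        else:
            v = rng.normal(size=3)
            direction = v / np.linalg.norm(v)
        t = np.arange(n_samples_full) * _AXIS_SAMPLE_SPACING
        t = t - t[-1] / 2.0
        samples = point[None, :] + t[:, None] * direction[None, :]
        per_sample = _stamp_indices(samples, r_vox, dims, offs)

        # count newly occupied voxels sample by sample so the final
        # cylinder can be trimmed to a sample prefix
        new_per_sample = np.empty(len(per_sample), dtype=np.int64)
        touched: list[np.ndarray] = []
        for i, idx in enumerate(per_sample):
            fresh = idx[~flat[idx]]
            flat[fresh] = True
            new_per_sample[i] = fresh.size
            touched.append(fresh)
        cum = count + np.cumsum(new_per_sample)

        if cum[-1] < target_count:
            count = int(cum[-1])
            cylinders.append(
                (point * voxel_size, direction, radius, full_len_vox * voxel_size)
            )
            continue

        # trim: keep the shortest prefix of samples whose cumulative count
        # is closest to the target
        k = int(np.searchsorted(cum, target_count))
        if k > 0 and abs(cum[k - 1] - target_count) <= abs(cum[k] - target_count):
            k -= 1
        for fresh in touched[k + 1 :]:
            flat[fresh] = False
        count = int(cum[k])
        length_vox = max((k + 1) * _AXIS_SAMPLE_SPACING, 2.0 * r_vox)
        cylinders.append((point * voxel_size, direction, radius, length_vox * voxel_size))
        break
    else:
        raise RuntimeError(
            f"could not reach target Bvf {target_bvf:.4f} within "
            f"{max_cylinders} cylinders (achieved {count / n_total:.4f})"
        )

    achieved = count / n_total
    if abs(achieved - target_bvf) > bvf_tolerance * target_bvf:
        raise RuntimeError(
            f"achieved Bvf {achieved:.4f} outside +-{bvf_tolerance:.0%} of "
            f"target {target_bvf:.4f}"
        )
    return CylinderSubstrate(
        cylinders,
        occupancy,
        float(achieved),
        float(target_bvf),
        float(radius),
        float(voxel_size),
        tuple(int(d) for d in dims),
    )
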