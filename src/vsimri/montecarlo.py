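"""Random-walk proton simulation over a perturber field map.

Protons diffuse through the extravascular space of a periodic substrate
while accumulating phase from the local frequency shift.  The normalized
signal magnitude at the echo time gives the contrast-induced relaxation
rate via ΔR2(*) = −ln S(TE) / TE.

Vessels are impermeable: walkers are initialized extravascular and a step
that would land inside a vessel is rejected (the walker stays in place for
that interval).
"""

from __future__ import annotations

import numpy as np

from .fieldshift import FieldMap
from .physics import SimulationConfig
from .substrate import CylinderSubstrate

__all__ = ["simulate_echo", "rates_from_signals"]


def _steps(rng: np.random.Generator, n: int, length: float, mode: str) -> np.ndarray:
    if mode == "lattice":
        axis = rng.integers(0, 3, size=n)
        sign = rng.choice((-1.0, 1.0), size=n)
        out = np.zeros((n, 3))
        out[np.arange(n), axis] = sign * length
        return out
    # uniformly random direction on the sphere, fixed length
    v = rng.normal(size=(n, 3))
    v *= length / np.linalg.norm(v, axis=1, keepdims=True)
    return v


def _init_positions(
    rng: np.random.Generator, n: int, dims: np.ndarray, occupancy: np.ndarray | None
) -> np.ndarray:
    pos = rng.uniform(0.0, dims.astype(float), size=(n, 3))
    if occupancy is None:
        return pos
    for _ in range(200):
        vox = _voxel_of(pos, dims)
        inside = occupancy[vox[:, 0], vox[:, 1], vox[:, 2]]
        n_bad = int(inside.sum())
        if n_bad == 0:
            return pos
        pos[inside] = rng.uniform(0.0, dims.astype(float), size=(n_bad, 3))
    raise RuntimeError("could not place walkers outside vessels (Bvf too high?)")


def _voxel_of(pos: np.ndarray, dims: np.ndarray) -> np.ndarray:
    """Nearest voxel (centres at integer coordinates), periodic wrap."""
    return np.floor(pos + 0.5).astype(np.int64) % dims


def simulate_echo(
    field: FieldMap,
    substrate: CylinderSubstrate | None,
    sim: SimulationConfig,
    echo_type: str,
    te: float,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Normalized signal magnitude S(TE) for one echo.

    Parameters
    ----------
    field : FieldMap
        Angular frequency shift grid, rad/s.
    substrate : CylinderSubstrate or None
        Supplies the impermeable-vessel occupancy; None disables exclusion
        (walkers roam the whole grid).
    echo_type : {"spin_echo", "gradient_echo"}
        Spin echo inverts the accumulated phase once at TE/2.
    te : float
        Echo time, ms; must be a multiple of dt (and TE/2 for spin echo).

    Returns
    -------
    float
        S = |⟨exp(iφ)⟩| over walkers, equal to 1 when Δω ≡ 0.
    """
    if echo_type not in ("spin_echo", "gradient_echo"):
        raise ValueError(f"unknown echo_type {echo_type!r}")
    if sim.n_walkers < 1:
        raise ValueError("n_walkers must be >= 1")
    n_steps = te / sim.dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"te={te} is not a multiple of dt={sim.dt}")
    n_steps = int(round(n_steps)) * sim.substeps
    if echo_type == "spin_echo":
        if n_steps % 2:
            raise ValueError(f"spin echo needs te/2 a multiple of dt (te={te})")
        flip_at = n_steps // 2
    else:
        flip_at = -1

    omega = field.delta_omega
    dims = np.asarray(omega.shape, dtype=np.int64)
    occupancy = substrate.occupancy if substrate is not None else None
    rng = np.random.default_rng(seed)
    pos = _init_positions(rng, sim.n_walkers, dims, occupancy)

    dt_s = sim.dt * 1e-3 / sim.substeps
    step_len_vox = sim.step_length / (
        substrate.voxel_size if substrate is not None else field.voxel_size
    )
    phase = np.zeros(sim.n_walkers)
    for k in range(n_steps):
        vox = _voxel_of(pos, dims)
        phase += omega[vox[:, 0], vox[:, 1], vox[:, 2]] * dt_s
        if k == flip_at - 1:
            # 180 deg refocusing pulse at TE/2
            np.negative(phase, out=phase)
        if sim.D > 0:
            proposal = (pos + _steps(rng, sim.n_walkers, step_len_vox, sim.step_mode)) % dims
            if occupancy is not None:
                pvox = _voxel_of(proposal, dims)
                blocked = occupancy[pvox[:, 0], pvox[:, 1], pvox[:, 2]]
                proposal[blocked] = pos[blocked]
            pos = proposal
    return float(np.abs(np.exp(1j * phase).mean()))


def rates_from_signals(
    s_se: float, s_gre: float, te_se: float, te_gre: float
) -> tuple[float, float]:
    """(ΔR2, ΔR2*) in s^-1 from signal magnitudes at TE in ms."""
    for s, name in ((s_se, "s_se"), (s_gre, "s_gre")):
        if s <= 0:
            raise ValueError(f"{name} must be positive (got {s})")
        if s > 1:
            raise ValueError(f"{name} must be <= 1 (got {s})")
    delta_r2 = -np.log(s_se) / (te_se * 1e-3)
    delta_r2_star = -np.log(s_gre) / (te_gre * 1e-3)
    return float(delta_r2), float(delta_r2_star)
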