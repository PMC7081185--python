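"""Physical constants and configuration for susceptibility-contrast simulation.

The contrast mechanism is the susceptibility difference Δχ between
SPION-loaded blood and surrounding tissue in a main field B0.  Two distinct
frequency scales appear in this problem and are easy to conflate:

* the *characteristic frequency* Δω_c = γ·Δχ·B0 that enters the vessel size
  index equation (``characteristic_frequency``), conventionally evaluated
  with the CGS susceptibility value plugged in verbatim; and
* the *physical field scale* of the perturber field itself, which in SI
  requires Δχ_SI = 4π·Δχ_CGS (``delta_chi_field``).

``chi_convention`` selects how Δω_c is computed; the dipole field is always
the physical one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON = 2.675e8

#: molar mass of iron, g/mol (4 significant figures)
FE_MOLAR_MASS_G_PER_MOL = 55.85

FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class PhysicsConfig:
    """Field strength, susceptibility difference and gyromagnetic ratio.

    Parameters
    ----------
    B0 : float
        Main magnetic field, tesla.
    delta_chi : float
        Susceptibility difference between intravascular contrast-loaded
        blood and tissue, dimensionless, in the unit system implied by
        ``chi_convention`` (default: the CGS value, e.g. 4.5e-7 for a
        360 umol Fe/kg SPION dose at 7 T).
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1.
    chi_convention : str
        ``"as_given"`` — Δω_c = γ·Δχ·B0 with ``delta_chi`` used verbatim
        (the convention of the VSI equation with its 0.424 prefactor);
        ``"si_from_cgs"`` — Δω_c computed with Δχ_SI = 4π·Δχ.
    """

    B0: float = 7.0
    delta_chi: float = 4.5e-7
    gamma: float = GAMMA_PROTON
    chi_convention: str = "as_given"

    def __post_init__(self) -> None:
        if self.B0 <= 0:
            raise ValueError("B0 must be positive")
        if self.delta_chi < 0:
            raise ValueError("delta_chi must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.chi_convention not in ("as_given", "si_from_cgs"):
            raise ValueError(
                f"unknown chi_convention {self.chi_convention!r}; "
                "expected 'as_given' or 'si_from_cgs'"
            )

    @property
    def delta_chi_field(self) -> float:
        """SI susceptibility difference driving the physical dipole field.

        ``delta_chi`` is interpreted as a CGS susceptibility, so the SI
        value entering the field computation is 4π times larger.
        """
        return FOUR_PI * self.delta_chi


def characteristic_frequency(physics: PhysicsConfig) -> float:
    """Characteristic angular frequency shift Δω_c = γ·Δχ·B0 (rad/s).

    This is the frequency scale of the vessel size index equation
    VSI = 0.424·(D/Δω_c)^(1/2)·(ΔR2*/ΔR2)^(3/2).  Under ``as_given`` the
    stored (CGS) Δχ is used verbatim, reproducing the constant the VSI
    literature calibrated the 0.424 prefactor against; ``si_from_cgs``
    multiplies by 4π.
    """
    chi = physics.delta_chi
    if physics.chi_convention == "si_from_cgs":
        chi = FOUR_PI * chi
    return physics.gamma * chi * physics.B0


def spion_mass_dose_mg_per_kg(
    dose_umol_fe_per_kg: float, molar_mass_g_per_mol: float = FE_MOLAR_MASS_G_PER_MOL
) -> float:
    """Convert a molar iron dose (umol Fe/kg) to a mass dose (mg/kg)."""
    if dose_umol_fe_per_kg < 0:
        raise ValueError("dose must be non-negative")
    return dose_umol_fe_per_kg * molar_mass_g_per_mol * 1e-3


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo random-walk settings for the finite-perturber simulator.

    Attributes
    ----------
    grid_dims : tuple of int
        Substrate grid size in voxels.
    voxel_size : float
        Isotropic voxel edge, micrometres.
    n_walkers : int
        Number of diffusing protons.
    dt : float
        Time step, milliseconds.
    D : float
        Water diffusion coefficient, um^2/s.
    te_se, te_gre : float
        Spin-echo and gradient-echo echo times, milliseconds.
    n_reps : int
        Independent substrate repetitions per condition.
    seed : int
        Master RNG seed; per-repetition child seeds are seed + rep index.
    step_mode : str
        ``"isotropic_3d"`` — fixed step length sqrt(6 D dt), uniformly
        random direction (realizes diffusivity D in 3-D; default);
        ``"fixed_1d"`` — fixed length sqrt(2 D dt), random direction (the
        1-D diffusion-length convention; realizes D/3);
        ``"lattice"`` — one of the six axis neighbours at sqrt(2 D dt).
    substeps : int
        Phase-accrual sub-stepping factor per dt (1 = no sub-stepping).
    """

    grid_dims: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 1.0
    n_walkers: int = 200_000
    dt: float = 1.0
    D: float = 800.0
    te_se: float = 8.0
    te_gre: float = 3.0
    n_reps: int = 3
    seed: int = 0
    step_mode: str = "isotropic_3d"
    substeps: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_walkers < 1:
            raise ValueError("n_walkers must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        for te, name in ((self.te_se, "te_se"), (self.te_gre, "te_gre")):
            n = te / self.dt
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name}={te} is not an integer multiple of dt={self.dt}")
        if self.step_mode not in ("isotropic_3d", "fixed_1d", "lattice"):
            raise ValueError(f"unknown step_mode {self.step_mode!r}")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")

    @property
    def step_length(self) -> float:
        """Walker step length in micrometres for one dt."""
        # D um^2/s, dt ms -> 1e-3 s
        dt_s = self.dt * 1e-3 / self.substeps
        if self.step_mode == "isotropic_3d":
            return float(np.sqrt(6.0 * self.D * dt_s))
        return float(np.sqrt(2.0 * self.D * dt_s))


def full_scale_walker_count(grid_dims: tuple[int, int, int] = (400, 400, 400)) -> int:
    """Walker count of the full-scale protocol: one proton per grid voxel."""
    return int(np.prod(grid_dims))
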