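"""Static-dephasing closed form for randomly oriented cylinder networks.

In the diffusion-free (static dephasing) limit the gradient-echo signal of
spins around a dilute network of randomly oriented, randomly placed
cylinders has a closed form.  For a single orientation at angle θ to B0 the
external field is δω(ρ,φ) = C(θ)·(a/ρ)²·cos2φ with
C(θ) = ½·γ·Δχ_SI·B0·sin²θ, and integrating 1 − exp(iδω t) over the
exterior cross-section gives

    ln s(t) = −ζ · g(C(θ)·t),    g(x) = x ∫₀ˣ (1 − J0(v)) / v² dv,

with ζ the vessel volume fraction.  g(x) → x for large x, so the
long-time rate per orientation is ζ·C(θ); averaged over isotropic
orientations (⟨sin²θ⟩ = 2/3):

    ΔR2*_static = ζ · γ · Δχ_SI · B0 / 3.

These expressions are evaluated here by quadrature only — no Monte Carlo —
so they serve as an independent oracle for the walker simulation.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special

from .physics import PhysicsConfig

__all__ = [
    "static_dephasing_rate_asymptotic",
    "static_dephasing_delta_r2star",
]


def _g(x: float) -> float:
    """g(x) = x * int_0^x (1 - J0(v)) / v^2 dv (finite at 0, -> x at inf)."""
    if x <= 0:
        return 0.0

    def integrand(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v)
        out = np.empty_like(v, dtype=float)
        small = v < 1e-6
        out[small] = 0.25  # limit of (1 - J0)/v^2
        vs = v[~small]
        out[~small] = (1.0 - special.j0(vs)) / vs**2
        return out

    val, _ = integrate.quad(integrand, 0.0, x, limit=400)
    return float(x * val)


def static_dephasing_rate_asymptotic(bvf: float, physics: PhysicsConfig) -> float:
    """Long-time static-dephasing ΔR2* (s^-1) of a random cylinder network."""
    return bvf * physics.gamma * physics.delta_chi_field * physics.B0 / 3.0


def static_dephasing_delta_r2star(
    bvf: float, physics: PhysicsConfig, te: float, n_theta: int = 64
) -> float:
    """Finite-TE static-dephasing ΔR2* = −ln S(TE)/TE (s^-1).

    Averages ln s over isotropic cylinder orientations (Gauss–Legendre in
    cosθ).  ``te`` in ms.
    """
    if te <= 0:
        raise ValueError("te must be positive")
    te_s = te * 1e-3
    c_perp = 0.5 * physics.gamma * physics.delta_chi_field * physics.B0
    u, w = np.polynomial.legendre.leggauss(n_theta)
    u = 0.5 * (u + 1.0)  # cos(theta) in [0, 1]
    w = 0.5 * w
    g_vals = np.array([_g(c_perp * (1.0 - ui**2) * te_s) for ui in u])
    mean_g = float((w * g_vals).sum())
    return bvf * mean_g / te_s
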