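"""Stokes/Perrin friction and diffusion coefficients for prolate spheroids.

Cells are modelled as prolate ellipsoids of revolution with semi-major
axis ``a`` and semi-minor axis ``b`` (a >= b), in a fluid of viscosity
``eta``.  Friction coefficients follow from the Perrin shape integrals

    chi = int_0^inf ds / (sqrt(a^2+s) (b^2+s)),
    P   = int_0^inf ds / ((a^2+s)^{3/2} (b^2+s)),
    Q   = int_0^inf ds / (sqrt(a^2+s) (b^2+s)^2),

which for a prolate spheroid reduce to closed forms in
``c = sqrt(a^2 - b^2)``::

    chi = (2/c) ln((a + c)/b)
    P   = (chi - 2/a) / c^2
    Q   = (a/b^2 - chi/2) / c^2

giving translational frictions gamma_par = 16 pi eta / (chi + a^2 P)
(along the long axis), gamma_perp = 16 pi eta / (chi + b^2 Q), and the
rotational friction about the short axes
gamma_rot = 16 pi eta (a^2 + b^2) / (3 (a^2 P + b^2 Q)).  Diffusivities
are D = kT / gamma.  The sphere limit a = b recovers Stokes' law
gamma = 6 pi eta a and gamma_rot = 8 pi eta a^3.

Units: lengths in micrometres, eta in mPa s (= cP), temperatures in K.
Outputs: translational friction in pN s / um, translational diffusivity in
um^2/s, rotational diffusivity in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["FrictionResult", "perrin_friction", "BOLTZMANN_J_PER_K"]

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class FrictionResult:
    """Friction/diffusion coefficients of a prolate spheroid.

    ``gamma_*`` in pN s / um, ``D_parallel``/``D_perpendicular``/``D_mean``
    in um^2/s, ``D_r`` (about the short axes) in 1/s.  ``gamma_mean`` is
    the orientation-averaged translational friction, defined through the
    averaged mobility: 1/gamma_mean = (1/gamma_par + 2/gamma_perp)/3.
    """

    semi_major_um: float
    semi_minor_um: float
    viscosity_mPas: float
    temperature_K: float
    gamma_parallel: float
    gamma_perpendicular: float
    gamma_mean: float
    D_parallel: float
    D_perpendicular: float
    D_mean: float
    D_r: float


def perrin_friction(
    semi_major_um: float,
    semi_minor_um: float,
    viscosity_mPas: float = 1.82,
    temperature_K: float = 298.0,
) -> FrictionResult:
    """Perrin friction factors and diffusivities for a prolate spheroid.

    Parameters
    ----------
    semi_major_um, semi_minor_um : semi-axes a >= b > 0 in micrometres.
        For a flagellated cell, ``a`` is an *effective* half-length that
        absorbs the stabilising contribution of the filament.
    viscosity_mPas : dynamic viscosity in mPa s (default 1.82, the growth
        medium of the halophile experiments this package models).
    temperature_K : temperature for D = kT/gamma (default 298 K).
    """
    a_um, b_um = float(semi_major_um), float(semi_minor_um)
    if not (a_um >= b_um > 0):
        raise ParameterError("require semi_major >= semi_minor > 0")
    if viscosity_mPas <= 0 or temperature_K <= 0:
        raise ParameterError("viscosity and temperature must be positive")

    a = a_um * 1e-6  # m
    b = b_um * 1e-6
    eta = viscosity_mPas * 1e-3  # Pa s
    kT = BOLTZMANN_J_PER_K * temperature_K

    if (a_um - b_um) / a_um < 1e-12:
        # sphere limit (Stokes)
        g_par = g_perp = 6.0 * np.pi * eta * a
        g_rot = 8.0 * np.pi * eta * a**3
    else:
        c = np.sqrt(a * a - b * b)
        chi = (2.0 / c) * np.log((a + c) / b)
        P = (chi - 2.0 / a) / (c * c)
        Q = (a / (b * b) - chi / 2.0) / (c * c)
        g_par = 16.0 * np.pi * eta / (chi + a * a * P)
        g_perp = 16.0 * np.pi * eta / (chi + b * b * Q)
        g_rot = 16.0 * np.pi * eta * (a * a + b * b) / (3.0 * (a * a * P + b * b * Q))

    D_par = kT / g_par * 1e12  # um^2/s
    D_perp = kT / g_perp * 1e12
    D_mean = (D_par + 2.0 * D_perp) / 3.0
    g_mean = kT / (D_mean * 1e-12)  # N s/m, from averaged mobility
    return FrictionResult(
        semi_major_um=a_um,
        semi_minor_um=b_um,
        viscosity_mPas=viscosity_mPas,
        temperature_K=temperature_K,
        gamma_parallel=g_par * 1e6,  # pN s / um
        gamma_perpendicular=g_perp * 1e6,
        gamma_mean=g_mean * 1e6,
        D_parallel=D_par,
        D_perpendicular=D_perp,
        D_mean=D_mean,
        D_r=kT / g_rot,
    )
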