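"""Settling/rise velocity of a (possibly fouled) sphere.

The velocity magnitude follows the dimensionless settling law of Dietrich
(1982) as used by the Kooi biofouling model: the dimensionless particle
diameter

    D* = |rho_tot - rho_sw| g d³ / (rho_sw nu²)

maps to a dimensionless settling velocity w* through a quadratic branch for
small D* (the Stokes regime) and a quartic-in-log10 polynomial above it, and

    |V_s| = (|rho_tot - rho_sw| / rho_sw * g * w* * nu)^(1/3).

Sign convention at this interface: the returned velocity is positive upward
(rise) and negative downward (sink); elsewhere in the package depth is
stored positive down, and the conversion happens in one place in the
integrator.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DomainError

__all__ = [
    "DSTAR_BREAKPOINT",
    "DSTAR_MAX",
    "dimensionless_diameter",
    "dimensionless_settling",
    "settling_velocity",
]

#: branch switch of the Dietrich law
DSTAR_BREAKPOINT = 0.05
#: stated upper validity bound; larger D* is clamped (with a warning)
DSTAR_MAX = 5.0e9

_QUAD_COEFF = 1.71e-4
_P = (-3.76715, 1.92944, -0.09815, -0.00575, 0.00056)


def dimensionless_diameter(rho_tot, rho_sw, diameter, nu_sw, g=9.81):
    """Dimensionless particle diameter D* (0 iff neutrally buoyant)."""
    rho_tot = np.asarray(rho_tot, dtype=float)
    rho_sw = np.asarray(rho_sw, dtype=float)
    d = np.asarray(diameter, dtype=float)
    nu = np.asarray(nu_sw, dtype=float)
    if np.any(rho_sw <= 0) or np.any(d <= 0) or np.any(nu <= 0):
        raise DomainError("rho_sw, diameter and nu_sw must be > 0")
    return np.abs(rho_tot - rho_sw) * g * d**3 / (rho_sw * nu**2)


def dimensionless_settling(dstar):
    """Dimensionless settling velocity w*(D*).

    Quadratic (Stokes) branch below ``DSTAR_BREAKPOINT``, Dietrich log10
    polynomial up to ``DSTAR_MAX``; beyond that the law is clamped at the
    bound (extrapolating the polynomial produces runaway velocities for
    centimetre-scale particles) and a warning is emitted.
    """
    dstar = np.asarray(dstar, dtype=float)
    if np.any(dstar < 0):
        raise DomainError("dstar must be >= 0")
    if np.any(dstar > DSTAR_MAX):
        warnings.warn(
            "D* beyond the settling law's validity bound; clamping at "
            f"{DSTAR_MAX:g}",
            stacklevel=2,
        )
    d = np.minimum(dstar, DSTAR_MAX)
    quad = _QUAD_COEFF * d**2
    with np.errstate(divide="ignore"):
        ld = np.log10(np.where(d > 0, d, 1.0))
    poly = 10.0 ** (
        _P[0] + _P[1] * ld + _P[2] * ld**2 + _P[3] * ld**3 + _P[4] * ld**4
    )
    return np.where(d < DSTAR_BREAKPOINT, quad, poly)


def settling_velocity(rho_tot, rho_sw, diameter, nu_sw, g=9.81):
    """Signed settling velocity, m s⁻¹; negative = downward (sinking).

    Zero at neutral buoyancy; positive (rise) when the particle is lighter
    than seawater.
    """
    rho_tot = np.asarray(rho_tot, dtype=float)
    rho_sw = np.asarray(rho_sw, dtype=float)
    nu = np.asarray(nu_sw, dtype=float)
    dstar = dimensionless_diameter(rho_tot, rho_sw, diameter, nu, g)
    wstar = dimensionless_settling(dstar)
    magnitude = (np.abs(rho_tot - rho_sw) / rho_sw * g * wstar * nu) ** (1.0 / 3.0)
    return np.sign(rho_sw - rho_tot) * magnitude
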