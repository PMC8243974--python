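"""Seawater density and viscosity.

Density follows the TEOS-10 polynomial equation of state of Roquet et
al. (2015): the 55-term Boussinesq expansion of in-situ density in absolute
salinity, conservative temperature and depth, plus the vertical reference
profile.  Model temperature and salinity are treated directly as conservative
temperature (°C) and absolute salinity (g kg⁻¹); pressure is derived from
depth with the surface-ocean approximation 1 dbar per metre.

Dynamic viscosity follows the Sharqawy, Lienhard & Zubair (2010) seawater
correlation; kinematic viscosity is the quotient of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "SeawaterPoint",
    "density_teos10",
    "dynamic_viscosity",
    "kinematic_viscosity",
]

# Valid oceanic input ranges (bounds inclusive)
SALINITY_RANGE = (0.0, 45.0)  # g/kg
TEMPERATURE_RANGE = (-3.0, 40.0)  # deg C
MAX_DEPTH = 11_000.0  # m

# --- Roquet et al. (2015) 55-term polynomial, Boussinesq form -------------
# Scaled variables: ss = sqrt((SA + deltaS)/SAu), tt = CT/CTu, zz = depth/Zu.
_SAU = 40.0 * 35.16504 / 35.0
_CTU = 40.0
_ZU = 1.0e4
_DELTAS = 32.0

_R000 = 8.0189615746e02; _R100 = 8.6672408165e02; _R200 = -1.7864682637e03
_R300 = 2.0375295546e03; _R400 = -1.2849161071e03; _R500 = 4.3227585684e02
_R600 = -6.0579916612e01; _R010 = 2.6010145068e01; _R110 = -6.5281885265e01
_R210 = 8.1770425108e01; _R310 = -5.6888046321e01; _R410 = 1.7681814114e01
_R510 = -1.9193502195e00; _R020 = -3.7074170417e01; _R120 = 6.1548258127e01
_R220 = -6.0362551501e01; _R320 = 2.9130021253e01; _R420 = -5.4723692739e00
_R030 = 2.1661789529e01; _R130 = -3.3449108469e01; _R230 = 1.9717078466e01
_R330 = -3.1742946532e00; _R040 = -8.3627885467e00; _R140 = 1.1311538584e01
_R240 = -5.3563304045e00; _R050 = 5.4048723791e-01; _R150 = 4.8169980163e-01
_R060 = -1.9083568888e-01; _R001 = 1.9681925209e01; _R101 = -4.2549998214e01
_R201 = 5.0774768218e01; _R301 = -3.0938076334e01; _R401 = 6.6051753097e00
_R011 = -1.3336301113e01; _R111 = -4.4870114575e00; _R211 = 5.0042598061e00
_R311 = -6.5399043664e-01; _R021 = 6.7080479603e00; _R121 = 3.5063081279e00
_R221 = -1.8795372996e00; _R031 = -2.4649669534e00; _R131 = -5.5077101279e-01
_R041 = 5.5927935970e-01; _R002 = 2.0660924175e00; _R102 = -4.9527603989e00
_R202 = 2.5019633244e00; _R012 = 2.0564311499e00; _R112 = -2.1311365518e-01
_R022 = -1.2419983026e00; _R003 = -2.3342758797e-02; _R103 = -1.8507636718e-02
_R013 = 3.7969820455e-01

# Vertical reference density profile r0(zz)
_R00 = 4.6494977072e01; _R01 = -5.2099962525e00; _R02 = 2.2601900708e-01
_R03 = 6.4326772569e-02; _R04 = -2.9203318398e-02; _R05 = 6.9183155806e-03


@dataclass
class SeawaterPoint:
    """A local seawater state.

    Attributes
    ----------
    absolute_salinity : float
        g kg⁻¹, valid range [0, 45].
    conservative_temperature : float
        °C, valid range [-3, 40].
    depth : float
        m, positive down, >= 0.
    """

    absolute_salinity: float
    conservative_temperature: float
    depth: float = 0.0

    @property
    def pressure(self) -> float:
        """Sea pressure in dbar (surface-ocean approximation 1 dbar per m)."""
        return float(self.depth)

    def density(self) -> float:
        return float(
            density_teos10(
                self.absolute_salinity, self.conservative_temperature, self.depth
            )
        )

    def dynamic_viscosity(self) -> float:
        return float(
            dynamic_viscosity(
                self.conservative_temperature, self.absolute_salinity
            )
        )

    def kinematic_viscosity(self) -> float:
        return float(
            kinematic_viscosity(
                self.absolute_salinity, self.conservative_temperature, self.depth
            )
        )


def _validate(salinity, temperature, depth) -> None:
    if np.any(salinity < SALINITY_RANGE[0]) or np.any(salinity > SALINITY_RANGE[1]):
        raise DomainError(
            f"absolute_salinity outside [{SALINITY_RANGE[0]}, {SALINITY_RANGE[1]}] g/kg"
        )
    if np.any(temperature < TEMPERATURE_RANGE[0]) or np.any(
        temperature > TEMPERATURE_RANGE[1]
    ):
        raise DomainError(
            "conservative_temperature outside "
            f"[{TEMPERATURE_RANGE[0]}, {TEMPERATURE_RANGE[1]}] degC"
        )
    if np.any(depth < 0) or np.any(depth > MAX_DEPTH):
        raise DomainError(f"depth outside [0, {MAX_DEPTH}] m")


def density_teos10(salinity, temperature, depth=0.0):
    """In-situ seawater density, kg m⁻³.

    Parameters are absolute salinity (g kg⁻¹), conservative temperature (°C)
    and depth (m, positive down); array inputs broadcast.
    """
    salinity = np.asarray(salinity, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    depth = np.asarray(depth, dtype=float)
    _validate(salinity, temperature, depth)

    ss = np.sqrt((salinity + _DELTAS) / _SAU)
    tt = temperature / _CTU
    zz = depth / _ZU

    rz3 = _R013 * tt + _R103 * ss + _R003
    rz2 = (_R022 * tt + _R112 * ss + _R012) * tt + (_R202 * ss + _R102) * ss + _R002
    rz1 = (
        (
            ((_R041 * tt + _R131 * ss + _R031) * tt + (_R221 * ss + _R121) * ss + _R021)
            * tt
            + ((_R311 * ss + _R211) * ss + _R111) * ss
            + _R011
        )
        * tt
        + (((_R401 * ss + _R301) * ss + _R201) * ss + _R101) * ss
        + _R001
    )
    rz0 = (
        (
            (
                (
                    (
                        (_R060 * tt + _R150 * ss + _R050) * tt
                        + (_R240 * ss + _R140) * ss
                        + _R040
                    )
                    * tt
                    + ((_R330 * ss + _R230) * ss + _R130) * ss
                    + _R030
                )
                * tt
                + (((_R420 * ss + _R320) * ss + _R220) * ss + _R120) * ss
                + _R020
            )
            * tt
            + ((((_R510 * ss + _R410) * ss + _R310) * ss + _R210) * ss + _R110) * ss
            + _R010
        )
        * tt
        + (((((_R600 * ss + _R500) * ss + _R400) * ss + _R300) * ss + _R200) * ss + _R100)
        * ss
        + _R000
    )
    r_anom = ((rz3 * zz + rz2) * zz + rz1) * zz + rz0
    r0 = (((((_R05 * zz + _R04) * zz + _R03) * zz + _R02) * zz + _R01) * zz + _R00) * zz
    return r_anom + r0


def dynamic_viscosity(temperature, salinity=0.0):
    """Dynamic viscosity of seawater, Pa s (Sharqawy et al. 2010).

    ``temperature`` in °C, ``salinity`` in g kg⁻¹.  The correlation takes
    salinity in kg kg⁻¹ internally.  Accuracy is a few percent over oceanic
    ranges, ample given that viscosity varies weakly in the ocean.
    """
    temperature = np.asarray(temperature, dtype=float)
    salinity = np.asarray(salinity, dtype=float)
    _validate(salinity, temperature, np.asarray(0.0))

    # pure water part (IAPWS-based correlation)
    mu_w = 4.2844e-5 + 1.0 / (0.157 * (temperature + 64.993) ** 2 - 91.296)
    s = salinity / 1000.0  # kg/kg
    a = 1.541 + 1.998e-2 * temperature - 9.52e-5 * temperature**2
    b = 7.974 - 7.561e-2 * temperature + 4.724e-4 * temperature**2
    return mu_w * (1.0 + a * s + b * s**2)


def kinematic_viscosity(salinity, temperature, depth=0.0):
    """Kinematic viscosity nu = mu/rho, m² s⁻¹ (order 1e-6 in the ocean)."""
    return dynamic_viscosity(temperature, salinity) / density_teos10(
        salinity, temperature, depth
    )
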