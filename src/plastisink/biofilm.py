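"""Attached-algae (biofilm) dynamics on a spherical particle.

The biofilm grows by encounter with ambient algal cells (Brownian motion,
differential settling and advective shear), by in-situ growth at the local
specific growth rate, and shrinks by grazing/mortality and by
temperature-dependent (Q10) respiration:

    dA/dt = A_A * beta_A / theta_pl + (mu_A - m_A - Q10^((T-20)/10) R20) * A

where ``A`` is attached cells per m² of pristine particle surface, ``A_A``
ambient cells per m³, ``beta_A`` the encounter kernel (m³ s⁻¹) and
``theta_pl`` the pristine particle surface area.  Attachment is irreversible
and instantaneous on encounter; there is no detachment term.

All functions broadcast over numpy arrays so the simulator can advance many
particles at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError
from .params import SECONDS_PER_DAY, KooiParams

__all__ = [
    "BiofoulState",
    "surface_area",
    "biofilm_geometry",
    "total_density",
    "ambient_algae",
    "specific_growth",
    "respiration_loss_rate",
    "encounter_kernel",
    "dA_dt",
    "step_attached_algae",
]

KELVIN_OFFSET = 273.16  # as used by the reference biofouling model


@dataclass
class BiofoulState:
    """One particle: pristine geometry, biofilm load and position.

    ``A`` is the attached algal surface density (cells m⁻²); ``depth`` is
    positive down and at least the model surface depth while "at the
    surface"; ``time`` is seconds since release.
    """

    r_pl: float
    rho_pl: float
    A: float = 0.0
    lon: float = 0.0
    lat: float = 0.0
    depth: float = 0.6
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.r_pl <= 0:
            raise DomainError("r_pl must be > 0")
        if self.rho_pl <= 0:
            raise DomainError("rho_pl must be > 0")
        if np.any(np.asarray(self.A) < 0):
            raise DomainError("A must be >= 0")


def surface_area(r_pl):
    """Surface area theta_pl = 4 pi r² of the pristine sphere, m²."""
    r_pl = np.asarray(r_pl, dtype=float)
    if np.any(r_pl <= 0):
        raise DomainError("r_pl must be > 0")
    return 4.0 * np.pi * r_pl**2


def biofilm_geometry(r_pl, A, params: KooiParams):
    """Biofilm volume, thickness and fouled total radius.

    The attached cells form a shell of volume ``V_bf = V_A * A * theta_pl``
    around the pristine sphere; the total radius is that of the sphere with
    the combined volume.

    Returns
    -------
    (biofilm_volume m³, biofilm_thickness m, total_radius m)
    """
    r_pl = np.asarray(r_pl, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise DomainError("A must be >= 0")
    theta = surface_area(r_pl)
    v_bf = params.algal_volume * A * theta
    v_pl = (4.0 / 3.0) * np.pi * r_pl**3
    # r_pl (1 + V_bf/V_pl)^(1/3): exact at A=0, well-conditioned for thin films
    r_tot = r_pl * (1.0 + v_bf / v_pl) ** (1.0 / 3.0)
    return v_bf, r_tot - r_pl, r_tot


def total_density(r_pl, rho_pl, A, params: KooiParams):
    """Volume-weighted density of particle plus biofilm, kg m⁻³.

    Runs monotonically from the polymer density at ``A = 0`` toward the
    biofilm density as the biofilm dominates the volume.
    """
    r_pl = np.asarray(r_pl, dtype=float)
    v_bf, _, _ = biofilm_geometry(r_pl, A, params)
    v_pl = (4.0 / 3.0) * np.pi * r_pl**3
    return (v_pl * np.asarray(rho_pl, dtype=float) + v_bf * params.biofilm_density) / (
        v_pl + v_bf
    )


def ambient_algae(phyto_mmol_n, params: KooiParams):
    """Ambient algal concentration A_A (cells m⁻³) from phytoplankton nitrogen.

    mmol N m⁻³ -> mg N m⁻³ (x 14.007) -> cells m⁻³ (x cells per mg N).
    """
    phyto = np.asarray(phyto_mmol_n, dtype=float)
    if np.any(phyto < 0):
        raise DomainError("phyto must be >= 0")
    return phyto * params.nitrogen_mg_per_mmol * params.cells_per_mg_nitrogen


def specific_growth(pp_mmol_n_per_day, phyto_mmol_n):
    """Specific growth rate mu_A of the attached algae, s⁻¹.

    Primary productivity and biomass pass through the same nitrogen-to-cell
    conversion, which cancels, leaving pp/phyto (d⁻¹) converted to s⁻¹.
    Zero biomass carries no growth signal and returns 0.
    """
    pp = np.asarray(pp_mmol_n_per_day, dtype=float)
    phyto = np.asarray(phyto_mmol_n, dtype=float)
    if np.any(pp < 0):
        raise DomainError("pp must be >= 0")
    if np.any(phyto < 0):
        raise DomainError("phyto must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(phyto > 0, pp / np.where(phyto > 0, phyto, 1.0), 0.0)
    return mu / SECONDS_PER_DAY


def respiration_loss_rate(temperature, params: KooiParams):
    """Temperature-dependent respiration loss rate, s⁻¹ (Q10 scaling of R20)."""
    t = np.asarray(temperature, dtype=float)
    return params.q10 ** ((t - 20.0) / 10.0) * params.r20


def encounter_kernel(
    r_tot,
    settling_speed,
    temperature,
    mu_dynamic,
    params: KooiParams,
):
    """Encounter kernel beta_A (m³ s⁻¹) between a particle and algal cells.

    Sum of the Brownian, differential-settling and advective-shear collision
    frequencies:

        beta_brown    = 4 pi (D_pl + D_A) (r_tot + r_A)
        beta_settling = 1/2 pi r_tot² |V_s|
        beta_shear    = 1.3 gamma (r_tot + r_A)³

    with Stokes-Einstein diffusivities ``D = k_B T_K / (6 pi mu r)`` and the
    algal radius taken as the equivalent sphere of one cell volume.

    Parameters
    ----------
    r_tot : total (fouled) particle radius, m
    settling_speed : settling speed magnitude |V_s|, m s⁻¹ (>= 0)
    temperature : °C
    mu_dynamic : dynamic viscosity of seawater, Pa s
    """
    r_tot = np.asarray(r_tot, dtype=float)
    v_s = np.abs(np.asarray(settling_speed, dtype=float))
    t_k = np.asarray(temperature, dtype=float) + KELVIN_OFFSET
    mu = np.asarray(mu_dynamic, dtype=float)
    r_a = params.algal_radius

    d_pl = params.boltzmann * t_k / (6.0 * np.pi * mu * r_tot)
    d_a = params.boltzmann * t_k / (6.0 * np.pi * mu * r_a)
    beta_brown = 4.0 * np.pi * (d_pl + d_a) * (r_tot + r_a)
    beta_settling = 0.5 * np.pi * r_tot**2 * v_s
    beta_shear = 1.3 * params.shear_rate * (r_tot + r_a) ** 3
    return beta_brown + beta_settling + beta_shear


def dA_dt(
    A,
    r_pl,
    ambient_cells,
    growth_rate,
    temperature,
    mu_dynamic,
    settling_speed,
    params: KooiParams,
    r_tot=None,
):
    """Net rate of change of the attached algal surface density, cells m⁻² s⁻¹.

    Collision source (independent of ``A``) plus linear growth, mortality and
    respiration terms.  ``growth_rate`` is the specific growth rate in s⁻¹;
    ``r_tot`` may be passed to avoid recomputing the fouled geometry.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise DomainError("A must be >= 0")
    if r_tot is None:
        _, _, r_tot = biofilm_geometry(r_pl, A, params)
    beta = encounter_kernel(r_tot, settling_speed, temperature, mu_dynamic, params)
    collision = np.asarray(ambient_cells, dtype=float) * beta / surface_area(r_pl)
    net_linear = (
        np.asarray(growth_rate, dtype=float)
        - params.m_a
        - respiration_loss_rate(temperature, params)
    )
    return collision + net_linear * A


def step_attached_algae(
    state: BiofoulState,
    ambient_cells,
    growth_rate,
    temperature,
    mu_dynamic,
    settling_speed,
    dt,
    params: KooiParams,
) -> BiofoulState:
    """Advance ``A`` by one forward-Euler step of ``dt`` seconds, floored at 0."""
    if dt <= 0:
        raise DomainError("dt must be > 0")
    rate = dA_dt(
        state.A,
        state.r_pl,
        ambient_cells,
        growth_rate,
        temperature,
        mu_dynamic,
        settling_speed,
        params,
    )
    new_a = max(0.0, float(state.A + dt * rate))
    return replace(state, A=new_a, time=state.time + dt)
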