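"""Lagrangian integration of biofouling microplastic particles.

Particles are released pristine (no biofilm) at the model surface depth and
advanced with a fourth-order Runge-Kutta step on the 3-D velocity
(horizontal currents plus vertical advection plus the particle's own
settling velocity).  The settling velocity is recomputed at every RK4
substage from the local seawater state; the attached-algae load ``A`` is
held fixed within a step and advanced afterwards by one forward-Euler step
of the biofilm equation (operator splitting — ``A`` varies slowly relative
to the 30 s default step).

Initially buoyant particles are clamped at the surface depth (0.6 m) with
zero recorded vertical velocity until their net vertical velocity first
points downward.  Depth is positive down everywhere in this module; the
settling module's signed velocity (positive up) is converted at a single
point in the stage function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import xarray as xr

from . import seawater
from .biofilm import KELVIN_OFFSET, ambient_algae, specific_growth
from .errors import ConfigError
from .fields import EnvironmentSample
from .params import SECONDS_PER_DAY, KooiParams
from .settling import settling_velocity

__all__ = [
    "ReleaseSpec",
    "SimulationConfig",
    "NPSG",
    "EQPAC",
    "build_release_grid",
    "apply_surface_clamp",
    "run_simulation",
]

EARTH_RADIUS = 6_371_000.0  # m
_DEG_PER_M = 180.0 / (math.pi * EARTH_RADIUS)
_SURFACE_TOL = 1e-6  # m, tolerance for "at the surface" comparisons

#: default particle radii: 1 mm down to 0.1 um by decades
DEFAULT_RADII = (1e-3, 1e-4, 1e-5, 1e-6, 1e-7)
#: initially buoyant polymer densities: EPS, PP, LDPE (kg/m3)
DEFAULT_DENSITIES = (30.0, 840.0, 920.0)


@dataclass(frozen=True)
class ReleaseSpec:
    """A lat/lon lattice of release positions (bounds inclusive)."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    spacing: float = 2.0


#: North Pacific subtropical gyre regional box (25 points at 2° spacing)
NPSG = ReleaseSpec(lon_min=-143.0, lon_max=-135.0, lat_min=28.0, lat_max=36.0)
#: equatorial Pacific regional box
EQPAC = ReleaseSpec(lon_min=-148.0, lon_max=-140.0, lat_min=-4.0, lat_max=4.0)
#: global release lattice
GLOBAL = ReleaseSpec(lon_min=0.0, lon_max=358.0, lat_min=-70.0, lat_max=80.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Run protocol: particle classes, release, clock and process toggles."""

    radii: tuple = DEFAULT_RADII  # m
    densities: tuple = DEFAULT_DENSITIES  # kg/m3
    release: ReleaseSpec = GLOBAL
    release_depth: float = 0.6  # m
    start_time: float = 0.0  # s into the forcing calendar
    horizon_days: float = 90.0
    dt: float = 30.0  # s
    output_interval: float = 12.0 * 3600.0  # s
    biofouling: bool = True
    advection: bool = True
    horizontal_only: bool = False
    vertical_only: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.horizon_days <= 0:
            raise ConfigError("horizon_days must be > 0")
        ratio = self.output_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ConfigError("output_interval must be a positive multiple of dt")
        if self.horizontal_only and self.vertical_only:
            raise ConfigError("horizontal_only and vertical_only are exclusive")
        if not self.radii or not self.densities:
            raise ConfigError("radii and densities must be non-empty")


def build_release_grid(spec: ReleaseSpec, provider) -> tuple[np.ndarray, np.ndarray]:
    """Release lattice positions (lon, lat arrays), land points dropped.

    Deterministic ordering: latitude-major, longitude ascending.
    """
    lons = np.arange(spec.lon_min, spec.lon_max + spec.spacing * 1e-6, spec.spacing)
    lats = np.arange(spec.lat_min, spec.lat_max + spec.spacing * 1e-6, spec.spacing)
    glon, glat = np.meshgrid(lons, lats)
    glon, glat = glon.ravel(), glat.ravel()
    ocean = np.asarray(provider.is_ocean(glon, glat), dtype=bool)
    if not ocean.any():
        raise ConfigError("release grid contains no ocean positions")
    return glon[ocean], glat[ocean]


def apply_surface_clamp(depth, net_w_up, surface_depth=0.6):
    """Hold rising particles at the surface depth with zero vertical velocity.

    ``net_w_up`` is the net vertical velocity positive up.  Returns
    (depth, net_w_up, clamped).  A downward net velocity releases the clamp.
    """
    depth = np.asarray(depth, dtype=float)
    net_w_up = np.asarray(net_w_up, dtype=float)
    clamped = (depth <= surface_depth + _SURFACE_TOL) & (net_w_up > 0)
    return (
        np.where(clamped, surface_depth, depth),
        np.where(clamped, 0.0, net_w_up),
        clamped,
    )


class _ParticleEnsemble:
    """Vectorized integrator state for all particles of one run."""

    def __init__(self, config, provider, params):
        self.cfg = config
        self.provider = provider
        self.params = params
        rel_lon, rel_lat = build_release_grid(config.release, provider)
        n_rel = rel_lon.size
        combos = [(r, rho) for r in config.radii for rho in config.densities]
        self.r_pl = np.repeat([c[0] for c in combos], n_rel)
        self.rho_pl = np.repeat([c[1] for c in combos], n_rel)
        self.release_lon = np.tile(rel_lon, len(combos))
        self.release_lat = np.tile(rel_lat, len(combos))
        self.n = self.r_pl.size

        self.lon = self.release_lon.astype(float).copy()
        self.lat = self.release_lat.astype(float).copy()
        self.depth = np.full(self.n, config.release_depth)
        self.A = np.zeros(self.n)
        self.frozen = np.zeros(self.n, dtype=bool)
        self.max_abs_vs = np.zeros(self.n)

        self.surface = config.release_depth
        self.seafloor = np.asarray(provider.seafloor(self.lon, self.lat), dtype=float)
        self.lat_lo, self.lat_hi = provider.lat_bounds
        # pristine geometry constants
        self.v_pl = (4.0 / 3.0) * np.pi * self.r_pl**3
        self.theta_pl = 4.0 * np.pi * self.r_pl**2

    # -- local physics -----------------------------------------------------

    def _environment(self, lon, lat, depth, t) -> EnvironmentSample:
        depth_c = np.clip(depth, self.surface, self.seafloor)
        lat_c = np.clip(lat, self.lat_lo, self.lat_hi)
        return self.provider.sample(lon, lat_c, depth_c, t)

    def _local_state(self, env, depth):
        """Seawater density/viscosity and fouled-particle density/radius."""
        sal = np.clip(env.salinity, *seawater.SALINITY_RANGE)
        temp = np.clip(env.temperature, *seawater.TEMPERATURE_RANGE)
        depth_c = np.clip(depth, 0.0, None)
        rho_sw = seawater.density_teos10(sal, temp, depth_c)
        mu = seawater.dynamic_viscosity(temp, sal)
        v_bf = self.params.algal_volume * self.A * self.theta_pl
        v_tot = self.v_pl + v_bf
        rho_tot = (self.v_pl * self.rho_pl + v_bf * self.params.biofilm_density) / v_tot
        r_tot = ((3.0 / (4.0 * np.pi)) * v_tot) ** (1.0 / 3.0)
        return rho_sw, mu, rho_tot, r_tot, temp

    def _derivatives(self, lon, lat, depth, t):
        """Stage function: d(lon,lat,depth)/dt plus the local velocities."""
        cfg = self.cfg
        env = self._environment(lon, lat, depth, t)
        rho_sw, mu, rho_tot, r_tot, temp = self._local_state(env, depth)
        nu = mu / rho_sw
        vs = settling_velocity(
            rho_tot, rho_sw, 2.0 * r_tot, nu, self.params.gravity
        )  # positive up

        if cfg.advection:
            u = np.where(self.frozen, 0.0, env.u)
            v = np.where(self.frozen, 0.0, env.v)
            w_env = np.where(self.frozen, 0.0, env.w)
            if cfg.horizontal_only:
                w_env = np.zeros_like(w_env)
            if cfg.vertical_only:
                u = np.zeros_like(u)
                v = np.zeros_like(v)
        else:
            u = v = w_env = np.zeros_like(vs)

        w_up = w_env + vs
        at_surface = depth <= self.surface + _SURFACE_TOL
        clamped = at_surface & (w_up > 0)
        w_eff = np.where(clamped | self.frozen, 0.0, w_up)

        coslat = np.maximum(np.cos(np.deg2rad(lat)), 0.05)
        dlon = np.where(self.frozen, 0.0, u * _DEG_PER_M / coslat)
        dlat = np.where(self.frozen, 0.0, v * _DEG_PER_M)
        ddepth = -w_eff  # depth positive down
        return dlon, dlat, ddepth, vs, w_eff, clamped, env, mu, temp

    # -- stepping ----------------------------------------------------------

    def rk4_step(self, t):
        dt = self.cfg.dt
        l1, f1, d1, vs1, _, _, env1, mu1, temp1 = self._derivatives(
            self.lon, self.lat, self.depth, t
        )
        l2, f2, d2, vs2, _, _, _, _, _ = self._derivatives(
            self.lon + 0.5 * dt * l1, self.lat + 0.5 * dt * f1,
            np.clip(self.depth + 0.5 * dt * d1, self.surface, self.seafloor),
            t + 0.5 * dt,
        )
        l3, f3, d3, vs3, _, _, _, _, _ = self._derivatives(
            self.lon + 0.5 * dt * l2, self.lat + 0.5 * dt * f2,
            np.clip(self.depth + 0.5 * dt * d2, self.surface, self.seafloor),
            t + 0.5 * dt,
        )
        l4, f4, d4, vs4, _, _, _, _, _ = self._derivatives(
            self.lon + dt * l3, self.lat + dt * f3,
            np.clip(self.depth + dt * d3, self.surface, self.seafloor),
            t + dt,
        )
        self.lon = self.lon + (dt / 6.0) * (l1 + 2 * l2 + 2 * l3 + l4)
        self.lat = self.lat + (dt / 6.0) * (f1 + 2 * f2 + 2 * f3 + f4)
        self.depth = np.clip(
            self.depth + (dt / 6.0) * (d1 + 2 * d2 + 2 * d3 + d4),
            self.surface,
            None,
        )
        self.max_abs_vs = np.maximum.reduce(
            [self.max_abs_vs, np.abs(vs1), np.abs(vs2), np.abs(vs3), np.abs(vs4)]
        )

        # biofilm update from the step-start environment (operator splitting)
        if self.cfg.biofouling:
            cells = ambient_algae(env1.phyto, self.params)
            growth = specific_growth(env1.pp, env1.phyto)
            resp = self.params.q10 ** ((temp1 - 20.0) / 10.0) * self.params.r20
            v_bf = self.params.algal_volume * self.A * self.theta_pl
            r_tot = ((3.0 / (4.0 * np.pi)) * (self.v_pl + v_bf)) ** (1.0 / 3.0)
            r_a = self.params.algal_radius
            t_k = temp1 + KELVIN_OFFSET
            d_pl = self.params.boltzmann * t_k / (6.0 * np.pi * mu1 * r_tot)
            d_a = self.params.boltzmann * t_k / (6.0 * np.pi * mu1 * r_a)
            beta = (
                4.0 * np.pi * (d_pl + d_a) * (r_tot + r_a)
                + 0.5 * np.pi * r_tot**2 * np.abs(vs1)
                + 1.3 * self.params.shear_rate * (r_tot + r_a) ** 3
            )
            rate = cells * beta / self.theta_pl + (
                growth - self.params.m_a - resp
            ) * self.A
            self.A = np.where(
                self.frozen, self.A, np.maximum(self.A + self.cfg.dt * rate, 0.0)
            )

        # domain handling: freeze at the seafloor or the grid's latitude edge
        hit_floor = self.depth >= self.seafloor - _SURFACE_TOL
        out_lat = (self.lat < self.lat_lo) | (self.lat > self.lat_hi)
        self.depth = np.minimum(self.depth, self.seafloor)
        self.lat = np.clip(self.lat, self.lat_lo, self.lat_hi)
        self.frozen |= hit_floor | out_lat

    def snapshot(self, t):
        """Record the state plus the net vertical velocity at time ``t``."""
        _, _, _, vs, w_eff, clamped, _, _, _ = self._derivatives(
            self.lon, self.lat, self.depth, t
        )
        return dict(
            lon=self.lon.copy(),
            lat=self.lat.copy(),
            z=self.depth.copy(),
            attached_algae=self.A.copy(),
            net_w=np.where(self.frozen, 0.0, w_eff),
            settling_w=vs.copy(),
            clamped=(clamped & ~self.frozen).astype(np.int8),
            frozen=self.frozen.astype(np.int8),
        )


def run_simulation(
    config: SimulationConfig,
    provider,
    params: KooiParams | None = None,
) -> xr.Dataset:
    """Integrate all particles of ``config`` through ``provider`` forcing.

    Returns a trajectory dataset with dims ``(traj, obs)``; snapshots are
    stored every ``output_interval`` seconds starting one interval after
    release, ``horizon/interval`` of them in total.  ``net_w`` is the net
    vertical velocity (settling plus vertical advection, m s⁻¹, positive
    up; zero while surface-clamped or frozen).
    """
    config.validate()
    params = params or KooiParams()
    ens = _ParticleEnsemble(config, provider, params)

    n_steps = int(round(config.horizon_days * SECONDS_PER_DAY / config.dt))
    out_every = int(round(config.output_interval / config.dt))
    n_out = n_steps // out_every
    records = []
    out_times = []

    for k in range(n_steps):
        t = config.start_time + k * config.dt
        ens.rk4_step(t)
        if (k + 1) % out_every == 0:
            t_new = config.start_time + (k + 1) * config.dt
            records.append(ens.snapshot(t_new))
            out_times.append((k + 1) * config.dt)
    assert len(records) == n_out

    data_vars = {}
    for name in records[0]:
        stacked = np.stack([rec[name] for rec in records], axis=1)  # (traj, obs)
        data_vars[name] = (("traj", "obs"), stacked)
    data_vars["radius"] = (("traj",), ens.r_pl)
    data_vars["density"] = (("traj",), ens.rho_pl)
    data_vars["release_lon"] = (("traj",), ens.release_lon)
    data_vars["release_lat"] = (("traj",), ens.release_lat)
    data_vars["max_abs_settling_w"] = (("traj",), ens.max_abs_vs)

    ds = xr.Dataset(
        data_vars,
        coords={
            "traj": np.arange(ens.n),
            "time": ("obs", np.asarray(out_times)),
        },
        attrs={
            "dt": config.dt,
            "output_interval": config.output_interval,
            "horizon_days": config.horizon_days,
            "start_time": config.start_time,
            "release_depth": config.release_depth,
            "biofouling": int(config.biofouling),
            "advection": int(config.advection),
            "horizontal_only": int(config.horizontal_only),
            "vertical_only": int(config.vertical_only),
            "seed": config.seed,
        },
    )
    ds["time"].attrs["units"] = "s"
    ds["time"].attrs["long_name"] = "elapsed seconds since release"
    return ds
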