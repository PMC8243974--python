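"""Environment providers.

Three ways to obtain the local ocean state (temperature, salinity, velocity,
phytoplankton biomass and primary productivity) at a particle position:

* :class:`IdealizedProvider` — horizontally uniform analytic depth profiles
  (a mixed layer of constant properties, exponential decay of the biology
  below it, linear temperature decrease), no advection;
* :class:`GriddedFieldSet` — regular lon/lat/depth/time grids with trilinear
  spatial and linear temporal interpolation, periodic in longitude (and
  optionally in time, for climatological forcing);
* :func:`generate_synthetic_ocean` — a deterministic, seeded synthetic
  global ocean with the large-scale structure that drives biofouling:
  oligotrophic subtropical gyres, a high-algae equatorial band, hemispheric
  spring blooms, seasonal mixed-layer depth, gyre-scale circulation with
  downwelling interiors, near-zero vertical velocity at the surface, and an
  idealized land mask.

The synthetic generator is parameterized directly in ambient algal cell
concentration (cells m⁻³) and specific growth rate (d⁻¹) — the quantities
the biofilm equation consumes — and derives the stored phytoplankton
nitrogen fields through the configured nitrogen-to-cell conversion, so the
simulated dynamics do not depend on the units convention of that conversion
constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .errors import ConfigError, DomainError
from .params import SECONDS_PER_DAY, KooiParams

__all__ = [
    "EnvironmentSample",
    "IdealizedProfileConfig",
    "IdealizedProvider",
    "sample_idealized",
    "GriddedFieldSet",
    "SyntheticWorldConfig",
    "generate_synthetic_ocean",
]

_TRACERS = ("temperature", "salinity", "phyto", "pp")
_VECTORS = ("u", "v", "w")
_VARIABLES = _TRACERS + _VECTORS


@dataclass
class EnvironmentSample:
    """Local ocean state at one or more points (fields broadcast together).

    ``u``/``v`` are eastward/northward velocity (m s⁻¹), ``w`` vertical
    velocity positive up (m s⁻¹), ``phyto`` phytoplankton nitrogen
    (mmol N m⁻³), ``pp`` primary productivity (mmol N m⁻³ d⁻¹).
    """

    temperature: np.ndarray
    salinity: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    phyto: np.ndarray
    pp: np.ndarray
    is_ocean: np.ndarray


# --------------------------------------------------------------------------
# Idealized depth profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IdealizedProfileConfig:
    """Analytic, horizontally uniform water-column profiles.

    Properties are constant down to the mixed-layer depth; below it the
    biological fields decay exponentially with ``decay_scale`` and
    temperature decreases linearly at ``temperature_lapse`` (floored at
    ``deep_temperature_floor``).  Advection is zero.
    """

    surface_temperature: float = 20.0  # degC
    temperature_lapse: float = 0.04  # degC per m below the mixed layer
    deep_temperature_floor: float = 2.0  # degC
    salinity: float = 35.0  # g/kg
    mld: float = 30.0  # m
    surface_phyto: float = 0.25  # mmol N m^-3
    surface_pp: float = 0.125  # mmol N m^-3 d^-1
    decay_scale: float = 50.0  # m, e-folding of phyto/pp below the MLD
    seafloor_depth: float = 4000.0  # m
    surface_depth: float = 0.6  # m

    @classmethod
    def from_ambient_conditions(
        cls,
        ambient_cells: float,
        growth_per_day: float,
        temperature: float,
        params: KooiParams | None = None,
        **kwargs,
    ) -> "IdealizedProfileConfig":
        """Build a column from ambient algal cells (m⁻³), specific growth
        (d⁻¹) and surface temperature (°C), inverting the nitrogen-to-cell
        conversion of ``params``."""
        params = params or KooiParams()
        phyto = ambient_cells / params.cells_per_mmol_n
        return cls(
            surface_temperature=temperature,
            surface_phyto=phyto,
            surface_pp=phyto * growth_per_day,
            **kwargs,
        )


def sample_idealized(config: IdealizedProfileConfig, depth, time=0.0) -> EnvironmentSample:
    """Evaluate the idealized profiles at ``depth`` (m, positive down)."""
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise DomainError("depth must be >= 0")
    below = np.maximum(depth - config.mld, 0.0)
    decay = np.exp(-below / config.decay_scale)
    temperature = np.maximum(
        config.surface_temperature - config.temperature_lapse * below,
        config.deep_temperature_floor,
    )
    zeros = np.zeros_like(depth)
    return EnvironmentSample(
        temperature=temperature,
        salinity=np.full_like(depth, config.salinity),
        u=zeros,
        v=zeros.copy(),
        w=zeros.copy(),
        phyto=config.surface_phyto * decay,
        pp=config.surface_pp * decay,
        is_ocean=np.ones_like(depth, dtype=bool),
    )


class IdealizedProvider:
    """Provider facade over :func:`sample_idealized` (uniform in lon/lat/time)."""

    def __init__(self, config: IdealizedProfileConfig | None = None):
        self.config = config or IdealizedProfileConfig()

    @property
    def surface_depth(self) -> float:
        return self.config.surface_depth

    def sample(self, lon, lat, depth, time) -> EnvironmentSample:
        return sample_idealized(self.config, depth, time)

    def is_ocean(self, lon, lat):
        return np.ones(np.broadcast(np.asarray(lon), np.asarray(lat)).shape, dtype=bool)

    def seafloor(self, lon, lat):
        shape = np.broadcast(np.asarray(lon), np.asarray(lat)).shape
        return np.full(shape, self.config.seafloor_depth)

    @property
    def lat_bounds(self):
        return (-90.0, 90.0)


# --------------------------------------------------------------------------
# Gridded fields
# --------------------------------------------------------------------------

def _interp_weights(axis, x, periodic_span=None, name="axis"):
    """Lower/upper indices and linear weight along a strictly ascending axis.

    With ``periodic_span`` the coordinate wraps with that period (longitude:
    360; climatological time: one year), interpolating across the seam.
    """
    x = np.asarray(x, dtype=float)
    n = axis.size
    if periodic_span is not None:
        x = axis[0] + np.mod(x - axis[0], periodic_span)
    else:
        if np.any(x < axis[0] - 1e-9) or np.any(x > axis[-1] + 1e-9):
            raise DomainError(
                f"{name} out of grid range [{axis[0]:g}, {axis[-1]:g}]"
            )
        x = np.clip(x, axis[0], axis[-1])
    i = np.searchsorted(axis, x, side="right") - 1
    i = np.clip(i, 0, n - 1)
    if periodic_span is None:
        i0 = np.minimum(i, n - 2)
        i1 = i0 + 1
        frac = (x - axis[i0]) / (axis[i1] - axis[i0])
    else:
        on_seam = i == n - 1
        i0 = i
        i1 = np.where(on_seam, 0, np.minimum(i + 1, n - 1))
        upper = np.where(on_seam, axis[0] + periodic_span, axis[i1])
        frac = (x - axis[i0]) / (upper - axis[i0])
    return i0.astype(np.intp), i1.astype(np.intp), np.clip(frac, 0.0, 1.0)


class GriddedFieldSet:
    """Regular lon/lat/depth/time environment fields with interpolation.

    Data arrays are shaped ``(time, depth, lat, lon)``; the land mask is
    ``(lat, lon)`` with True = ocean.  Longitude is periodic; time is
    periodic when ``time_period`` (seconds) is given.  Velocities are zero
    at land nodes; tracers must be defined (filled) everywhere so that
    land-adjacent interpolation draws on ocean-like values.
    """

    def __init__(self, lon, lat, depth, time, data, mask, time_period=None):
        self.lon = np.asarray(lon, dtype=float)
        self.lat = np.asarray(lat, dtype=float)
        self.depth = np.asarray(depth, dtype=float)
        self.time = np.asarray(time, dtype=float)
        for name, axis in (("lon", self.lon), ("lat", self.lat),
                           ("depth", self.depth), ("time", self.time)):
            if axis.ndim != 1 or axis.size < 2 or np.any(np.diff(axis) <= 0):
                raise ConfigError(f"{name} axis must be 1-D strictly ascending")
        shape = (self.time.size, self.depth.size, self.lat.size, self.lon.size)
        self.data = {}
        for name in _VARIABLES:
            arr = np.asarray(data[name])
            if arr.shape != shape:
                raise ConfigError(f"variable {name!r} has shape {arr.shape}, want {shape}")
            self.data[name] = arr
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != (self.lat.size, self.lon.size):
            raise ConfigError("mask must have shape (lat, lon)")
        self.time_period = time_period
        self._flat = {name: arr.reshape(-1) for name, arr in self.data.items()}

    # -- sampling ----------------------------------------------------------

    @property
    def surface_depth(self) -> float:
        return float(self.depth[0])

    @property
    def lat_bounds(self):
        return (float(self.lat[0]), float(self.lat[-1]))

    def seafloor(self, lon, lat):
        shape = np.broadcast(np.asarray(lon), np.asarray(lat)).shape
        return np.full(shape, self.depth[-1])

    def is_ocean(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ix0, ix1, fx = _interp_weights(self.lon, lon, periodic_span=360.0)
        iy0, iy1, fy = _interp_weights(self.lat, lat, name="latitude")
        ix = np.where(fx > 0.5, ix1, ix0)
        iy = np.where(fy > 0.5, iy1, iy0)
        return self.mask[iy, ix]

    def sample(self, lon, lat, depth, time) -> EnvironmentSample:
        """Trilinear-in-space, linear-in-time sample at the given points."""
        lon, lat, depth, time = np.broadcast_arrays(
            np.asarray(lon, dtype=float), np.asarray(lat, dtype=float),
            np.asarray(depth, dtype=float), np.asarray(time, dtype=float),
        )
        shape = lon.shape
        ix0, ix1, fx = _interp_weights(self.lon, lon.ravel(), periodic_span=360.0)
        iy0, iy1, fy = _interp_weights(self.lat, lat.ravel(), name="latitude")
        iz0, iz1, fz = _interp_weights(self.depth, depth.ravel(), name="depth")
        it0, it1, ft = _interp_weights(
            self.time, time.ravel(), periodic_span=self.time_period, name="time"
        )

        nz, ny, nx = self.depth.size, self.lat.size, self.lon.size
        acc = {name: 0.0 for name in _VARIABLES}
        for at, it, wt in ((0, it0, 1 - ft), (1, it1, ft)):
            if self.time.size == 1:
                it, wt = it0, (1.0 if at == 0 else 0.0)
            for az, iz, wz in ((0, iz0, 1 - fz), (1, iz1, fz)):
                for ay, iy, wy in ((0, iy0, 1 - fy), (1, iy1, fy)):
                    for ax, ix, wx in ((0, ix0, 1 - fx), (1, ix1, fx)):
                        wgt = wt * wz * wy * wx
                        flat = ((it * nz + iz) * ny + iy) * nx + ix
                        for name in _VARIABLES:
                            acc[name] = acc[name] + wgt * self._flat[name][flat]

        out = {name: np.asarray(acc[name], dtype=float).reshape(shape)
               for name in _VARIABLES}
        return EnvironmentSample(
            temperature=out["temperature"],
            salinity=out["salinity"],
            u=out["u"], v=out["v"], w=out["w"],
            phyto=np.maximum(out["phyto"], 0.0),
            pp=np.maximum(out["pp"], 0.0),
            is_ocean=self.is_ocean(lon, lat).reshape(shape),
        )

    # -- I/O ---------------------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        coords = {
            "lon": ("lon", self.lon, {"units": "degrees_east"}),
            "lat": ("lat", self.lat, {"units": "degrees_north"}),
            "depth": ("depth", self.depth, {"units": "m", "positive": "down"}),
            "time": ("time", self.time, {"units": "seconds"}),
        }
        data_vars = {
            name: (("time", "depth", "lat", "lon"), self.data[name])
            for name in _VARIABLES
        }
        data_vars["mask"] = (("lat", "lon"), self.mask.astype(np.int8))
        attrs = {}
        if self.time_period is not None:
            attrs["time_period_seconds"] = float(self.time_period)
        return xr.Dataset(data_vars, coords=coords, attrs=attrs)

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset, name_map=None) -> "GriddedFieldSet":
        """Build from a dataset; ``name_map`` maps canonical names
        (temperature, salinity, u, v, w, phyto, pp, mask, lon, lat, depth,
        time) to the file's variable names (e.g. MEDUSA conventions, with
        phytoplankton groups summed upstream)."""
        name_map = name_map or {}

        def get(name):
            return ds[name_map.get(name, name)]

        data = {}
        for name in _VARIABLES:
            da = get(name)
            arr = np.asarray(da, dtype=np.float32)
            if name in _TRACERS and np.isnan(arr).any():
                filled = (
                    da.ffill("lon").bfill("lon").ffill("lat").bfill("lat")
                )
                arr = np.asarray(filled.fillna(filled.mean()), dtype=np.float32)
            elif name in _VECTORS:
                arr = np.nan_to_num(arr)
            data[name] = arr
        if name_map.get("mask", "mask") in ds:
            mask = np.asarray(get("mask"), dtype=bool)
        else:
            mask = ~np.isnan(np.asarray(get("temperature")))[0, 0]
        return cls(
            lon=np.asarray(get("lon")),
            lat=np.asarray(get("lat")),
            depth=np.asarray(get("depth")),
            time=np.asarray(get("time"), dtype=float),
            data=data,
            mask=mask,
            time_period=ds.attrs.get("time_period_seconds"),
        )

    @classmethod
    def from_netcdf(cls, path, name_map=None) -> "GriddedFieldSet":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load(), name_map=name_map)


# --------------------------------------------------------------------------
# Synthetic global ocean
# --------------------------------------------------------------------------

def _wrap180(dlon):
    return (np.asarray(dlon) + 180.0) % 360.0 - 180.0


def _seasonal_gauss(doy, peak, width, year=365.0):
    """Gaussian pulse in day-of-year with circular distance."""
    d = np.abs((doy - peak + year / 2.0) % year - year / 2.0)
    return np.exp(-((d / width) ** 2))


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Structure of the synthetic global ocean.

    Ambient algal concentrations (cells m⁻³) blend, in log space, a
    mid-ocean background, suppressed subtropical gyres, an elevated
    equatorial band and hemispheric spring blooms peaking at the configured
    days of year.  Velocities are gyre-scale swirls plus zonal bands, with
    vertical velocity tapered to ~0 at the surface, upwelling along the
    equator and downwelling in gyre interiors at depth.
    """

    lon_step: float = 2.0
    lat_step: float = 2.0
    lat_min: float = -78.0
    lat_max: float = 80.0
    depth_levels: tuple = (
        0.6, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 65.0, 80.0,
        100.0, 125.0, 150.0, 200.0, 250.0, 300.0, 400.0, 500.0, 650.0, 800.0,
    )
    n_time: int = 73
    days_per_step: float = 5.0
    year_days: float = 365.0

    background_cells: float = 3.0e8
    gyre_cells: float = 5.0e7
    equator_cells: float = 5.0e9
    bloom_factor: float = 10.0
    min_cells: float = 2.0e7
    equator_band_width: float = 8.0  # deg latitude
    gyre_centers: tuple = (
        (30.0, -150.0), (28.0, -45.0), (-30.0, -120.0), (-30.0, -15.0), (-32.0, 80.0),
    )
    gyre_radius_lat: float = 12.0
    gyre_radius_lon: float = 25.0
    bloom_lat_center: float = 50.0
    bloom_lat_width: float = 12.0
    bloom_peak_doy_nh: float = 105.0  # mid-April (MAM)
    bloom_peak_doy_sh: float = 288.0  # mid-October (SON)
    bloom_doy_width: float = 30.0

    growth_background: float = 0.3  # d^-1
    growth_gyre: float = 0.2
    growth_equator: float = 1.0
    growth_bloom: float = 1.2
    growth_depth_scale: float = 60.0  # m

    mld_base: float = 30.0
    mld_winter_amplitude: float = 70.0
    mld_lat_center: float = 50.0
    mld_lat_width: float = 15.0
    winter_peak_doy_nh: float = 46.0
    winter_peak_doy_sh: float = 228.0
    winter_doy_width: float = 60.0

    sst_equator: float = 28.0
    sst_pole: float = -1.0
    sst_seasonal_amplitude: float = 3.0
    summer_peak_doy_nh: float = 212.0
    deep_temperature: float = 4.0
    thermocline_scale: float = 150.0
    salinity_mean: float = 35.0
    euphotic_scale: float = 50.0  # m, phyto decay below the MLD

    current_speed: float = 0.3  # m/s gyre swirl scale
    w0: float = 2.0e-5  # m/s deep vertical velocity scale
    w_taper_depth: float = 100.0  # m, surface taper of |w|
    velocity_depth_scale: float = 200.0

    noise_sigma: float = 0.05  # lognormal multiplicative noise on biology
    land_boxes: tuple = (
        ((-80.0, -60.0), (-55.0, 70.0)),
        ((0.0, 40.0), (-35.0, 70.0)),
        ((115.0, 150.0), (-35.0, -12.0)),
    )

    def validate(self) -> None:
        problems = []
        if self.lon_step <= 0 or 360.0 % self.lon_step > 1e-9:
            problems.append("lon_step")
        if self.lat_step <= 0 or self.lat_min >= self.lat_max:
            problems.append("lat_step/lat_min/lat_max")
        if len(self.depth_levels) < 2 or np.any(np.diff(self.depth_levels) <= 0):
            problems.append("depth_levels")
        if self.n_time < 2 or self.days_per_step <= 0:
            problems.append("n_time/days_per_step")
        for name in ("background_cells", "gyre_cells", "equator_cells",
                     "min_cells", "bloom_factor"):
            if getattr(self, name) <= 0:
                problems.append(name)
        if not self.gyre_centers:
            problems.append("gyre_centers")
        if problems:
            raise ConfigError("invalid synthetic world config fields: " + ", ".join(problems))

    def gyre_boxes(self, half_lat=5.0, half_lon=5.0):
        """Release boxes centred on the gyres (for diagnostics/tests)."""
        return [
            (lon - half_lon, lon + half_lon, lat - half_lat, lat + half_lat)
            for lat, lon in self.gyre_centers
        ]


def _gyre_gaussians(lon2d, lat2d, config):
    """Per-gyre gaussian footprints, list of (center_lat, footprint)."""
    out = []
    for clat, clon in config.gyre_centers:
        dx = _wrap180(lon2d - clon) * np.cos(np.deg2rad(clat))
        dy = lat2d - clat
        r2 = (dx / config.gyre_radius_lon) ** 2 + (dy / config.gyre_radius_lat) ** 2
        out.append((clat, np.exp(-r2)))
    return out


def generate_synthetic_ocean(
    config: SyntheticWorldConfig | None = None,
    seed: int = 0,
    params: KooiParams | None = None,
) -> GriddedFieldSet:
    """Generate the synthetic global ocean; deterministic for a fixed seed."""
    config = config or SyntheticWorldConfig()
    config.validate()
    params = params or KooiParams()

    lon = np.arange(0.0, 360.0, config.lon_step)
    lat = np.arange(config.lat_min, config.lat_max + 1e-9, config.lat_step)
    depth = np.asarray(config.depth_levels, dtype=float)
    time = (np.arange(config.n_time) + 0.5) * config.days_per_step * SECONDS_PER_DAY
    nt, nz, ny, nx = time.size, depth.size, lat.size, lon.size

    lon2d, lat2d = np.meshgrid(lon, lat)  # (ny, nx)
    rng = np.random.default_rng(seed)
    noise = np.exp(config.noise_sigma * rng.standard_normal((ny, nx)))

    # land mask (True = ocean)
    mask = np.ones((ny, nx), dtype=bool)
    for (lo0, lo1), (la0, la1) in config.land_boxes:
        in_lon = (_wrap180(lon2d - lo0) >= 0) & (_wrap180(lon2d - lo1) <= 0)
        mask &= ~(in_lon & (lat2d >= la0) & (lat2d <= la1))

    gyres = _gyre_gaussians(lon2d, lat2d, config)
    eq_band = np.exp(-((lat2d / config.equator_band_width) ** 2))
    bloom_nh = np.exp(-(((lat2d - config.bloom_lat_center) / config.bloom_lat_width) ** 2))
    bloom_sh = np.exp(-(((lat2d + config.bloom_lat_center) / config.bloom_lat_width) ** 2))
    mld_band_nh = np.exp(-(((lat2d - config.mld_lat_center) / config.mld_lat_width) ** 2))
    mld_band_sh = np.exp(-(((lat2d + config.mld_lat_center) / config.mld_lat_width) ** 2))

    # depth-independent horizontal current pattern
    u_pat = np.zeros((ny, nx))
    v_pat = np.zeros((ny, nx))
    w_pat = np.zeros((ny, nx))
    for (clat, clon), (_, g) in zip(config.gyre_centers, gyres):
        dx = _wrap180(lon2d - clon) * np.cos(np.deg2rad(clat)) / config.gyre_radius_lon
        dy = (lat2d - clat) / config.gyre_radius_lat
        spin = 1.0 if clat >= 0 else -1.0
        u_pat += spin * config.current_speed * dy * g
        v_pat += -spin * config.current_speed * dx * g
        w_pat -= config.w0 * g  # downwelling in gyre interiors
    u_pat += -0.2 * eq_band  # trades
    u_pat += 0.15 * (
        np.exp(-(((np.abs(lat2d) - 45.0) / 10.0) ** 2))
    )  # westerlies
    w_pat += config.w0 * eq_band  # equatorial upwelling

    z = depth[:, None, None]
    z_taper = np.tanh(z / config.w_taper_depth)
    vel_decay = np.exp(-z / config.velocity_depth_scale)

    data = {name: np.empty((nt, nz, ny, nx), dtype=np.float32) for name in _VARIABLES}
    log_bg = np.log10(config.background_cells)
    log_gyre_drop = log_bg - np.log10(config.gyre_cells)
    log_eq_gain = np.log10(config.equator_cells) - log_bg
    log_bloom = np.log10(config.bloom_factor)

    for it, t in enumerate(time):
        doy = (t / SECONDS_PER_DAY) % config.year_days
        s_nh = _seasonal_gauss(doy, config.bloom_peak_doy_nh, config.bloom_doy_width,
                               config.year_days)
        s_sh = _seasonal_gauss(doy, config.bloom_peak_doy_sh, config.bloom_doy_width,
                               config.year_days)
        bloom = bloom_nh * s_nh + bloom_sh * s_sh

        logc = log_bg + log_eq_gain * eq_band + log_bloom * bloom
        for _, g in gyres:
            logc -= log_gyre_drop * g
        cells = np.maximum(10.0 ** logc * noise, config.min_cells)
        phyto_s = cells / params.cells_per_mmol_n  # mmol N m^-3

        growth_s = (
            config.growth_background
            + (config.growth_equator - config.growth_background) * eq_band
            + (config.growth_bloom - config.growth_background) * bloom
        )
        for _, g in gyres:
            growth_s -= (config.growth_background - config.growth_gyre) * g
        growth_s = np.maximum(growth_s, 0.05)

        w_nh = _seasonal_gauss(doy, config.winter_peak_doy_nh, config.winter_doy_width,
                               config.year_days)
        w_sh = _seasonal_gauss(doy, config.winter_peak_doy_sh, config.winter_doy_width,
                               config.year_days)
        mld = config.mld_base + config.mld_winter_amplitude * (
            mld_band_nh * w_nh + mld_band_sh * w_sh
        )

        season_t = config.sst_seasonal_amplitude * np.cos(
            2.0 * np.pi * (doy - config.summer_peak_doy_nh) / config.year_days
        ) * np.tanh(lat2d / 20.0)
        sst = (
            config.sst_pole
            + (config.sst_equator - config.sst_pole)
            * np.cos(np.deg2rad(lat2d)) ** 2
            + season_t
        )
        sal = (
            config.salinity_mean
            + 0.8 * np.exp(-(((np.abs(lat2d) - 25.0) / 15.0) ** 2))
            - 0.3 * np.abs(lat2d) / 80.0
        )

        below = np.maximum(z - mld[None, :, :], 0.0)  # (nz, ny, nx)
        bio_shape = np.exp(-below / config.euphotic_scale)
        growth_shape = np.exp(-below / config.growth_depth_scale)
        t3d = np.maximum(
            config.deep_temperature
            + (sst[None, :, :] - config.deep_temperature)
            * np.exp(-below / config.thermocline_scale),
            -2.0,
        )

        data["temperature"][it] = t3d
        data["salinity"][it] = np.broadcast_to(sal, (nz, ny, nx))
        data["phyto"][it] = phyto_s[None, :, :] * bio_shape
        data["pp"][it] = phyto_s[None, :, :] * growth_s[None, :, :] * bio_shape * growth_shape
        data["u"][it] = u_pat[None, :, :] * vel_decay * mask
        data["v"][it] = v_pat[None, :, :] * vel_decay * mask
        data["w"][it] = w_pat[None, :, :] * z_taper * mask

    return GriddedFieldSet(
        lon=lon, lat=lat, depth=depth, time=time, data=data, mask=mask,
        time_period=config.year_days * SECONDS_PER_DAY,
    )
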