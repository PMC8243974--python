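"""Lagrangian integration: release grids, RK4 advection, surface clamp,
process toggles and convergence."""

import dataclasses
import math

import numpy as np
import pytest
import xarray as xr

from plastisink import (
    ConfigError,
    IdealizedProfileConfig,
    IdealizedProvider,
    NPSG,
    ReleaseSpec,
    SimulationConfig,
    apply_surface_clamp,
    build_release_grid,
    compute_diagnostics,
    run_simulation,
)
from plastisink.fields import EnvironmentSample
from plastisink.simulate import EARTH_RADIUS


class AnalyticProvider:
    """Test provider with a velocity field given as a callable."""

    def __init__(self, velocity, temperature=15.0, salinity=35.0,
                 phyto=0.0, pp=0.0, seafloor=4000.0):
        self.velocity = velocity
        self.temperature = temperature
        self.salinity = salinity
        self.phyto = phyto
        self.pp = pp
        self._seafloor = seafloor
        self.surface_depth = 0.6
        self.lat_bounds = (-90.0, 90.0)

    def sample(self, lon, lat, depth, time):
        lon, lat, depth = np.broadcast_arrays(
            np.asarray(lon, float), np.asarray(lat, float), np.asarray(depth, float)
        )
        u, v, w = self.velocity(lon, lat, depth, time)
        full = np.full_like
        return EnvironmentSample(
            temperature=full(lon, self.temperature),
            salinity=full(lon, self.salinity),
            u=np.broadcast_to(u, lon.shape).astype(float),
            v=np.broadcast_to(v, lon.shape).astype(float),
            w=np.broadcast_to(w, lon.shape).astype(float),
            phyto=full(lon, self.phyto),
            pp=full(lon, self.pp),
            is_ocean=np.ones(lon.shape, dtype=bool),
        )

    def is_ocean(self, lon, lat):
        return np.ones(np.broadcast(np.asarray(lon), np.asarray(lat)).shape, bool)

    def seafloor(self, lon, lat):
        shape = np.broadcast(np.asarray(lon), np.asarray(lat)).shape
        return np.full(shape, self._seafloor)


def _still(lon, lat, depth, time):
    z = np.zeros_like(np.asarray(lon, float))
    return z, z, z


class TestReleaseGrid:
    def test_npsg_box_has_25_points(self):
        lon, lat = build_release_grid(NPSG, IdealizedProvider())
        assert lon.size == 25
        assert lat.min() == 28.0 and lat.max() == 36.0

    def test_single_point(self):
        lon, lat = build_release_grid(ReleaseSpec(10, 10, 20, 20), IdealizedProvider())
        assert lon.size == 1 and lon[0] == 10.0 and lat[0] == 20.0

    def test_all_land_errors(self):
        class Land(IdealizedProvider):
            def is_ocean(self, lon, lat):
                return np.zeros(np.broadcast(np.asarray(lon), np.asarray(lat)).shape, bool)

        with pytest.raises(ConfigError):
            build_release_grid(NPSG, Land())


class TestSurfaceClamp:
    def test_buoyant_particle_held(self):
        depth, w, clamped = apply_surface_clamp(0.6, 0.05)
        assert depth == 0.6 and w == 0.0 and clamped

    def test_downward_velocity_releases(self):
        depth, w, clamped = apply_surface_clamp(0.6, -0.01)
        assert w == -0.01 and not clamped

    def test_submerged_particle_untouched_then_reclamped(self):
        # below the surface the clamp is inactive even when rising ...
        depth, w, clamped = apply_surface_clamp(50.0, 0.01)
        assert depth == 50.0 and w == 0.01 and not clamped
        # ... until the particle is back at the surface depth
        depth, w, clamped = apply_surface_clamp(0.6, 0.01)
        assert depth == 0.6 and w == 0.0 and clamped


def _one_particle_config(**kw):
    base = dict(
        radii=(1e-6,),
        densities=(920.0,),
        release=ReleaseSpec(0, 0, 0, 0),
        horizon_days=1.0,
        dt=600.0,
        output_interval=43200.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestIntegration:
    def test_zero_velocity_keeps_position(self):
        cfg = _one_particle_config(biofouling=False)
        traj = run_simulation(cfg, AnalyticProvider(_still))
        assert np.all(traj.lon.values == 0.0)
        assert np.all(traj.lat.values == 0.0)
        assert np.all(traj.z.values == 0.6)
        assert np.all(traj.clamped.values == 1)  # buoyant pristine particle
        assert np.all(traj.net_w.values == 0.0)

    def test_uniform_downwelling_is_exact(self):
        # neutral-ish particle: tiny radius makes settling negligible
        w_down = -1e-3  # m/s, positive-up convention

        def vel(lon, lat, depth, time):
            z = np.zeros_like(np.asarray(lon, float))
            return z, z, z + w_down

        cfg = _one_particle_config(radii=(1e-7,), densities=(1026.0,),
                                   biofouling=False, dt=600.0)
        traj = run_simulation(cfg, AnalyticProvider(vel))
        # depth grows by |w| dt per step; first snapshot after 43200 s
        expected = 0.6 + 1e-3 * 43200.0
        assert float(traj.z[0, 0]) == pytest.approx(expected, abs=1e-3)

    def test_solid_body_rotation_conserves_radius(self):
        """RK4 on a solid-body rotation about (0 E, 0 N): the metric radius
        is conserved to <0.1% over 100 steps."""
        omega = 2 * math.pi / (50 * 3600.0)  # one revolution per ~2 days

        def vel(lon, lat, depth, time):
            x = np.deg2rad(np.asarray(lon, float)) * EARTH_RADIUS
            y = np.deg2rad(np.asarray(lat, float)) * EARTH_RADIUS
            return -omega * y, omega * x, np.zeros_like(x)

        cfg = SimulationConfig(
            radii=(1e-6,), densities=(920.0,),
            release=ReleaseSpec(1.0, 1.0, 0.0, 0.0),  # 1 degree east of center
            horizon_days=100 * 600.0 / 86400.0, dt=600.0,
            output_interval=600.0, biofouling=False,
        )
        traj = run_simulation(cfg, AnalyticProvider(vel))
        r = np.hypot(
            np.deg2rad(traj.lon.values) * EARTH_RADIUS,
            np.deg2rad(traj.lat.values) * EARTH_RADIUS,
        )
        r0 = np.deg2rad(1.0) * EARTH_RADIUS
        assert np.max(np.abs(r - r0) / r0) < 1e-3

    def test_protocol_snapshot_count_and_times(self):
        cfg = _one_particle_config(horizon_days=3.0, dt=3600.0, biofouling=False)
        traj = run_simulation(cfg, AnalyticProvider(_still))
        assert traj.sizes["obs"] == 6  # 3 days / 12 h
        assert np.allclose(traj.time.values, 43200.0 * np.arange(1, 7))

    def test_determinism(self, params):
        cfg = _one_particle_config(
            radii=(1e-5,), horizon_days=2.0, dt=600.0
        )
        prov = IdealizedProvider(
            IdealizedProfileConfig.from_ambient_conditions(1e9, 0.8, 25.0, params)
        )
        a = run_simulation(cfg, prov, params)
        b = run_simulation(cfg, prov, params)
        assert a.identical(b)

    def test_biofouling_toggle_keeps_pristine(self, params):
        prov = IdealizedProvider(
            IdealizedProfileConfig.from_ambient_conditions(5e9, 1.0, 27.0, params)
        )
        cfg = _one_particle_config(biofouling=False, horizon_days=2.0)
        traj = run_simulation(cfg, prov, params)
        assert np.all(traj.attached_algae.values == 0.0)
        assert np.all(traj.clamped.values == 1)

    def test_advection_toggles_recombine_in_linear_field(self):
        def vel(lon, lat, depth, time):
            z = np.zeros_like(np.asarray(lon, float))
            return z + 0.2, z + 0.1, z - 1e-4

        base = dict(radii=(1e-7,), densities=(1026.0,), biofouling=False,
                    release=ReleaseSpec(0, 0, 0, 0), horizon_days=1.0,
                    dt=600.0, output_interval=43200.0)
        full = run_simulation(SimulationConfig(**base), AnalyticProvider(vel))
        hor = run_simulation(SimulationConfig(**base, horizontal_only=True),
                             AnalyticProvider(vel))
        ver = run_simulation(SimulationConfig(**base, vertical_only=True),
                             AnalyticProvider(vel))
        off = run_simulation(SimulationConfig(**base, advection=False),
                             AnalyticProvider(vel))
        # vertical_only keeps no horizontal motion; horizontal_only keeps depth
        assert np.all(ver.lon.values == 0.0) and np.all(ver.lat.values == 0.0)
        assert np.all(hor.z.values == pytest.approx(0.6, abs=1e-6))
        assert np.all(off.lon.values == 0.0) and np.all(
            off.z.values == pytest.approx(0.6, abs=1e-6)
        )
        # displacements recombine in a constant field
        assert float(full.lon[0, -1]) == pytest.approx(float(hor.lon[0, -1]), rel=1e-4)
        assert float(full.z[0, -1] - 0.6) == pytest.approx(
            float(ver.z[0, -1] - 0.6), rel=1e-3
        )

    def test_seafloor_freeze(self):
        def vel(lon, lat, depth, time):
            z = np.zeros_like(np.asarray(lon, float))
            return z, z, z - 0.05

        cfg = _one_particle_config(radii=(1e-7,), densities=(1026.0,),
                                   biofouling=False)
        traj = run_simulation(cfg, AnalyticProvider(vel, seafloor=100.0))
        assert float(traj.z[0, -1]) == pytest.approx(100.0)
        assert int(traj.frozen[0, -1]) == 1
        assert float(traj.net_w[0, -1]) == 0.0

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SimulationConfig(dt=0.0).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(dt=700.0, output_interval=43200.0).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(horizontal_only=True, vertical_only=True).validate()


class TestConvergence:
    def test_dt_halving_changes_zs_less_than_a_metre(self, params):
        """First sinking depth of a 0.1 mm particle in a smooth column is
        insensitive to halving the time step."""
        prov = IdealizedProvider(
            IdealizedProfileConfig.from_ambient_conditions(5e9, 1.0, 27.0, params)
        )

        def zs_at(dt):
            cfg = SimulationConfig(
                radii=(1e-4,), densities=(920.0,),
                release=ReleaseSpec(0, 0, 0, 0), horizon_days=15.0,
                dt=dt, advection=False,
            )
            d = compute_diagnostics(run_simulation(cfg, prov, params))
            return float(d.zs_m[0]), float(d.ts_days[0])

        zs_coarse, ts_coarse = zs_at(600.0)
        zs_fine, ts_fine = zs_at(300.0)
        assert abs(zs_coarse - zs_fine) < 1.0
        assert ts_coarse == ts_fine
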