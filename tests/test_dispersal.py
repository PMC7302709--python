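"""Advection--diffusion stepper: substep rule, random walk, season driver."""

import numpy as np
import pytest

from larvadrift.dispersal import (
    SECONDS_PER_DAY,
    ParticleEnsemble,
    SimulationConfig,
    Status,
    advance_particles,
    compute_substep,
    diffusion_displacement,
    run_season_simulation,
)
from larvadrift.ocean_field import CurrentField, METERS_PER_DEGREE, min_node_spacing_meters
from larvadrift.seeding import build_release_schedule
from larvadrift.synthetic import Island, SyntheticFieldSpec, make_field

from conftest import make_uniform_field, square_polyset
from reference import naive_advance


def single_particle_ensemble(lon, lat):
    return ParticleEnsemble(
        lon=np.array([lon]),
        lat=np.array([lat]),
        age=np.array([0]),
        release_day=np.array([0]),
        status=np.array([int(Status.ACTIVE)]),
    )


class TestSubstep:
    def test_hand_computed_value(self):
        # dx_min ~ 9276.67 m (near-equatorial 1/12 deg), u_max = 1 m/s, safety 0.5
        field = make_uniform_field(nx=4, ny=2, lat0=0.0)
        cfg = SimulationConfig()
        dt = compute_substep(field, cfg, u_max=1.0)
        assert dt == pytest.approx(0.5 * min_node_spacing_meters(field), rel=1e-12)
        assert dt == pytest.approx(4638.3, abs=0.5)

    def test_no_flow_returns_snapshot_interval(self):
        field = make_uniform_field(nx=4, ny=4)
        assert compute_substep(field, SimulationConfig(), 0.0) == SECONDS_PER_DAY

    def test_inverse_proportional_to_speed_until_floor(self):
        field = make_uniform_field(nx=4, ny=4)
        cfg = SimulationConfig()
        assert compute_substep(field, cfg, 2.0) == pytest.approx(
            0.5 * compute_substep(field, cfg, 1.0)
        )
        assert compute_substep(field, cfg, 1e6) == cfg.min_substep

    def test_advective_displacement_stays_below_cell(self):
        field = make_uniform_field(nx=8, ny=8, lat0=40.0)
        cfg = SimulationConfig()
        for u_max in (0.1, 0.5, 1.3, 4.0):
            dt = compute_substep(field, cfg, u_max)
            if dt > cfg.min_substep:
                assert u_max * dt <= min_node_spacing_meters(field)


class TestDiffusion:
    def test_zero_diffusivity_is_zero_displacement(self, rng):
        dx, dy = diffusion_displacement(0.0, 1000.0, rng, n=100)
        assert np.all(dx == 0.0) and np.all(dy == 0.0)

    def test_angular_symmetry_zero_mean(self):
        rng = np.random.default_rng(11)
        dx, dy = diffusion_displacement(5.0, 1000.0, rng, n=1_000_000)
        se = np.sqrt(2 * 5.0 * 1000.0) / 1000.0  # per-axis sd / sqrt(n)
        assert abs(dx.mean()) < 3 * se
        assert abs(dy.mean()) < 3 * se

    def test_mean_squared_radial_displacement(self):
        # E[rho^2] = 4*Eh*dt
        rng = np.random.default_rng(12)
        eh, dt = 5.0, 1000.0
        dx, dy = diffusion_displacement(eh, dt, rng, n=1_000_000)
        msd = (dx**2 + dy**2).mean()
        assert msd == pytest.approx(4 * eh * dt, rel=0.01)


class TestAdvance:
    def test_stationary_without_flow_or_diffusion(self):
        field = make_uniform_field(0.0, 0.0, nx=6, ny=6)
        ens = single_particle_ensemble(0.2, 0.0)
        cfg = SimulationConfig(eh=0.0)
        advance_particles(ens, field, cfg, 0.0, 3600.0, np.random.default_rng(0))
        assert ens.lon[0] == 0.2 and ens.lat[0] == 0.0

    def test_hand_converted_eastward_step(self):
        # u = 1 m/s for 1000 s at the equator -> dlon = 1000/111320 deg
        field = make_uniform_field(1.0, 0.0, nx=6, ny=6)
        ens = single_particle_ensemble(0.1, 0.0)
        cfg = SimulationConfig(eh=0.0)
        advance_particles(ens, field, cfg, 0.0, 1000.0, np.random.default_rng(0))
        assert ens.lon[0] - 0.1 == pytest.approx(0.0089831, abs=1e-7)
        assert ens.lat[0] == 0.0

    def test_boundary_crossing_exits_and_freezes(self):
        field = make_uniform_field(1.0, 0.0, nx=6, ny=6)
        lon0 = field.lon_max - 1e-4
        ens = single_particle_ensemble(lon0, 0.0)
        advance_particles(ens, field, SimulationConfig(eh=0.0), 0.0, 3600.0,
                         np.random.default_rng(0))
        assert ens.status[0] == Status.EXITED
        assert ens.lon[0] == lon0  # frozen at pre-step position

    def test_step_onto_land_is_cancelled(self):
        field = make_uniform_field(1.0, 0.0, nx=6, ny=6)
        u, v = field.u.copy(), field.v.copy()
        u[:, :, 4] = np.nan  # land column east of the particle
        v[:, :, 4] = np.nan
        field = CurrentField(field.lon_axis, field.lat_axis, field.time_axis, u, v)
        lon0 = field.lon_axis[3]
        ens = single_particle_ensemble(lon0, 0.0)
        advance_particles(ens, field, SimulationConfig(eh=0.0), 0.0, 7200.0,
                         np.random.default_rng(0))
        assert ens.status[0] == Status.ACTIVE
        assert ens.lon[0] == lon0  # held for this substep


class TestSeasonRun:
    def test_zero_flow_particles_stay_at_seed_positions(self):
        field = make_uniform_field(0.0, 0.0, nx=10, ny=10, n_days=61)
        polyset = square_polyset(0.2, -0.2, 0.3)
        sched = build_release_schedule(2, 50)
        cfg = SimulationConfig(eh=0.0, rng_seed=5)
        traj = run_season_simulation(field, polyset, sched, cfg)
        first_rel = traj.day_index(1)
        np.testing.assert_array_equal(traj.lon[-1], traj.lon[first_rel])
        np.testing.assert_array_equal(traj.lat[-1], traj.lat[first_rel])

    def test_age_equals_day_minus_release_day(self):
        field = make_uniform_field(0.0, 0.0, nx=10, ny=10, n_days=61)
        traj = run_season_simulation(
            field, square_polyset(0.2, -0.2, 0.3),
            build_release_schedule(10, 5), SimulationConfig(eh=0.0, rng_seed=1),
        )
        i60 = traj.day_index(60)
        released = traj.status[i60] != Status.UNRELEASED
        np.testing.assert_array_equal(
            traj.age[i60][released], 60 - traj.release_day[released]
        )

    def test_conservation_at_every_snapshot(self):
        spec = SyntheticFieldSpec(nx=30, ny=30, amplitude=0.2,
                                  islands=(Island(178.0, -18.0, 0.2),))
        field = make_field(spec)
        polyset = square_polyset(177.5, -18.6, 0.3)
        sched = build_release_schedule(5, 40)
        traj = run_season_simulation(field, polyset, sched,
                                     SimulationConfig(rng_seed=3, duration_days=20))
        for i, day in enumerate(traj.days):
            s = traj.status[i]
            n_unrel = int((s == Status.UNRELEASED).sum())
            n_act = int((s == Status.ACTIVE).sum())
            n_exit = int((s == Status.EXITED).sum())
            assert n_unrel + n_act + n_exit == sched.total
            # cohorts released on days <= snapshot day
            assert n_unrel == int((traj.release_day > day).sum())

    def test_identical_seed_identical_trajectories(self):
        field = make_uniform_field(0.05, 0.02, nx=40, ny=20, n_days=61)
        polyset = square_polyset(0.3, -0.3, 0.2)
        sched = build_release_schedule(3, 30)
        a = run_season_simulation(field, polyset, sched, SimulationConfig(rng_seed=9,
                                                                          duration_days=15))
        b = run_season_simulation(field, polyset, sched, SimulationConfig(rng_seed=9,
                                                                          duration_days=15))
        np.testing.assert_array_equal(a.lon, b.lon)
        np.testing.assert_array_equal(a.lat, b.lat)
        np.testing.assert_array_equal(a.status, b.status)

    def test_short_forcing_rejected_before_stepping(self):
        field = make_uniform_field(0.0, 0.0, nx=6, ny=6, n_days=10)
        with pytest.raises(ValueError, match="forcing"):
            run_season_simulation(field, square_polyset(0.1, -0.1, 0.1),
                                  build_release_schedule(1, 5),
                                  SimulationConfig(duration_days=60))


class TestAdvectionExactness:
    def test_constant_current_displacement_matches_u_times_t(self):
        # 60 days at u = 0.05 m/s along the equator: dlon = u*T/111320
        field = make_uniform_field(0.05, 0.0, nx=60, ny=20, n_days=61)
        polyset = square_polyset(0.4, -0.01, 0.02)
        traj = run_season_simulation(field, polyset, build_release_schedule(1, 20),
                                     SimulationConfig(eh=0.0, rng_seed=2))
        T = 60 * SECONDS_PER_DAY
        expected_dlon = 0.05 * T / (METERS_PER_DEGREE * np.cos(np.radians(traj.lat[0])))
        actual_dlon = traj.lon[-1] - traj.lon[0]
        np.testing.assert_allclose(actual_dlon, expected_dlon, rtol=1e-3)
        assert (traj.status[-1] == Status.ACTIVE).all()


class TestOracleEquivalence:
    def test_batched_matches_naive_stepper_bitwise(self):
        """Batched and one-particle-at-a-time steppers agree bit-for-bit
        on a 100-particle, 5-day double-gyre run with shared random streams."""
        spec = SyntheticFieldSpec(nx=30, ny=30, amplitude=0.25, n_days=6,
                                  islands=(Island(178.0, -18.0, 0.2),))
        field = make_field(spec)
        from larvadrift.seeding import sample_polygon_points

        pts = sample_polygon_points(square_polyset(177.8, -18.3, 0.4), 100,
                                    np.random.default_rng(77))
        cfg = SimulationConfig(eh=5.0)

        def fresh():
            return ParticleEnsemble(
                lon=pts[:, 0].copy(), lat=pts[:, 1].copy(),
                age=np.zeros(100, dtype=int), release_day=np.zeros(100, dtype=int),
                status=np.full(100, int(Status.ACTIVE)),
            )

        ens_a, ens_b = fresh(), fresh()
        rng_a = np.random.default_rng(123)
        rng_b = np.random.default_rng(123)
        dt = compute_substep(field, cfg, field.speed_max(0))
        n_sub = max(1, int(np.ceil(SECONDS_PER_DAY / dt)))
        dt_day = SECONDS_PER_DAY / n_sub
        for day in range(5):
            for k in range(n_sub):
                t = day + k * dt_day / SECONDS_PER_DAY
                advance_particles(ens_a, field, cfg, t, dt_day, rng_a)
                naive_advance(ens_b, field, cfg, t, dt_day, rng_b)
        np.testing.assert_array_equal(ens_a.lon, ens_b.lon)
        np.testing.assert_array_equal(ens_a.lat, ens_b.lat)
        np.testing.assert_array_equal(ens_a.status, ens_b.status)
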