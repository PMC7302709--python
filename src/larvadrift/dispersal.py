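"""Lagrangian advection--diffusion particle stepper and season driver.

Particle displacement over a substep dt is

    dx = u_p * dt + K

where u_p is the interpolated surface current at the particle position and K
is a random-walk parameterisation of sub-grid turbulent eddies: with R_NA,
R_NB uniform on (0, 1),

    rho = sqrt(-4 * Eh * dt * ln(1 - R_NA))
    K   = (rho * cos(2*pi*R_NB), rho * sin(2*pi*R_NB))

so E[rho^2] = 4*Eh*dt and per-axis positional variance grows as 2*Eh*t — the
standard isotropic 2-D random walk with horizontal eddy diffusivity Eh
(default 5 m^2 s^-1).  The substep is chosen so that the advective
displacement stays below one grid cell.  No mortality, competency or
swimming behaviour is simulated; particle age is tracked from release.

Random-draw order is documented and fixed so a naive one-particle-at-a-time
reference stepper can replay the same stream: within each substep, each
active particle (ascending particle id) consumes R_NA then R_NB.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ocean_field import (
    METERS_PER_DEGREE,
    CurrentField,
    min_node_spacing_meters,
    velocity_at,
)
from .seeding import ReleaseSchedule, SeedPolygonSet, sample_polygon_points

SECONDS_PER_DAY = 86_400.0


class Status(enum.IntEnum):
    """Particle lifecycle: unreleased -> active -> (possibly) exited."""

    UNRELEASED = 0
    ACTIVE = 1
    EXITED = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable parameters of a season run.

    eh : horizontal turbulent diffusion coefficient, m^2 s^-1 (default 5).
    duration_days : run length (default 60, covering the 26-30 day pelagic
        larval duration plus a settlement window).
    snapshot_interval : days between recorded position snapshots (default 1).
    substep_safety : fraction of a grid cell the advective displacement may
        cover per substep, in (0, 1] (default 0.5).
    min_substep : floor on the substep length, seconds (default 60).
    rng_seed : seed for the single simulation random stream.
    recruitment_window : (start_day, end_day] treated as the putative
        recruitment phase (default (30, 60)).
    """

    eh: float = 5.0
    duration_days: int = 60
    snapshot_interval: int = 1
    substep_safety: float = 0.5
    min_substep: float = 60.0
    rng_seed: int = 0
    recruitment_window: tuple[int, int] = (30, 60)

    def __post_init__(self) -> None:
        if self.eh < 0:
            raise ValueError("eh must be >= 0")
        if self.duration_days < self.snapshot_interval:
            raise ValueError("duration must cover at least one snapshot interval")
        if not 0.0 < self.substep_safety <= 1.0:
            raise ValueError("substep_safety must be in (0, 1]")


@dataclass
class ParticleEnsemble:
    """Per-particle state advanced by the stepper (struct-of-arrays)."""

    lon: np.ndarray
    lat: np.ndarray
    age: np.ndarray  # days since own release; -1 before release
    release_day: np.ndarray
    status: np.ndarray  # Status values

    @property
    def n(self) -> int:
        return self.lon.size

    def counts(self) -> dict[str, int]:
        s = self.status
        return {
            "unreleased": int((s == Status.UNRELEASED).sum()),
            "active": int((s == Status.ACTIVE).sum()),
            "exited": int((s == Status.EXITED).sum()),
        }


@dataclass
class TrajectoryRecord:
    """Daily snapshots of the full ensemble.

    Arrays are (n_snapshots, n_particles); particle ids are the column
    indices 0..n-1 throughout.  Exited particles keep their frozen position;
    unreleased particles hold NaN positions and age -1.
    """

    days: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    age: np.ndarray
    status: np.ndarray
    release_day: np.ndarray  # (n_particles,)

    @property
    def n_particles(self) -> int:
        return self.release_day.size

    def day_index(self, day: int) -> int:
        idx = np.flatnonzero(self.days == day)
        if idx.size == 0:
            raise KeyError(f"no snapshot recorded for day {day}")
        return int(idx[0])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (day, particle_id, lon, lat, age, status)."""
        n_snap, n = self.lon.shape
        return pd.DataFrame(
            {
                "day": np.repeat(self.days, n),
                "particle_id": np.tile(np.arange(n), n_snap),
                "lon": self.lon.ravel(),
                "lat": self.lat.ravel(),
                "age": self.age.ravel(),
                "status": self.status.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.8f")


def compute_substep(field: CurrentField, config: SimulationConfig, u_max: float) -> float:
    """Substep length in seconds keeping advective displacement under a cell.

    dt = clamp(safety * dx_min / u_max, min_substep, snapshot interval);
    with no flow (u_max = 0) the full snapshot interval is returned.
    """
    if u_max < 0:
        raise ValueError("u_max must be >= 0")
    dt_snap = config.snapshot_interval * SECONDS_PER_DAY
    if u_max == 0.0:
        return dt_snap
    dt = config.substep_safety * min_node_spacing_meters(field) / u_max
    return float(np.clip(dt, config.min_substep, dt_snap))


def diffusion_displacement(eh: float, dt: float, rng: np.random.Generator, n: int | None = None):
    """Random-walk displacement(s) in metres for one substep.

    Draws R_NA, R_NB per particle (R_NA first), radial magnitude
    rho = sqrt(-4*eh*dt*ln(1-R_NA)), direction 2*pi*R_NB.  With ``n`` given,
    returns two length-n arrays; otherwise a scalar pair.
    """
    if eh < 0:
        raise ValueError("eh must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    m = 1 if n is None else n
    draws = rng.random((m, 2))
    rho = np.sqrt(-4.0 * eh * dt * np.log1p(-draws[:, 0]))
    theta = 2.0 * np.pi * draws[:, 1]
    dx = rho * np.cos(theta)
    dy = rho * np.sin(theta)
    if n is None:
        return float(dx[0]), float(dy[0])
    return dx, dy


def advance_particles(
    ensemble: ParticleEnsemble,
    field: CurrentField,
    config: SimulationConfig,
    t: float,
    dt: float,
    rng: np.random.Generator,
) -> ParticleEnsemble:
    """Advance all active particles by one substep (in place).

    Advection uses the interpolated velocity at the pre-step position; the
    metre displacement converts to degrees with dlat = dy/111,320 and
    dlon = dx/(111,320*cos(lat)) at the pre-step latitude.  A displacement
    crossing the grid boundary exits the particle (frozen at its pre-step
    position); one landing on a land-masked cell is cancelled for this
    substep (the particle holds position and stays active).
    """
    act = np.flatnonzero(ensemble.status == Status.ACTIVE)
    if act.size == 0:
        return ensemble

    lon0 = ensemble.lon[act]
    lat0 = ensemble.lat[act]
    u, v = velocity_at(field, lon0, lat0, t)
    ddx, ddy = diffusion_displacement(config.eh, dt, rng, n=act.size)
    dx_m = u * dt + ddx
    dy_m = v * dt + ddy
    lat1 = lat0 + dy_m / METERS_PER_DEGREE
    lon1 = lon0 + dx_m / (METERS_PER_DEGREE * np.cos(np.radians(lat0)))
    if not (np.all(np.isfinite(lon1)) and np.all(np.isfinite(lat1))):
        raise RuntimeError("non-finite particle position after update")

    inside = field.contains(lon1, lat1)
    exited = act[~inside]
    ensemble.status[exited] = Status.EXITED  # frozen at pre-step position

    ok = np.flatnonzero(inside)
    on_land = field.is_land_at(lon1[ok], lat1[ok])
    moved = ok[~on_land]  # landing on land cancels the sub-displacement
    ensemble.lon[act[moved]] = lon1[moved]
    ensemble.lat[act[moved]] = lat1[moved]
    return ensemble


def run_season_simulation(
    field: CurrentField,
    polyset: SeedPolygonSet,
    schedule: ReleaseSchedule,
    config: SimulationConfig,
) -> TrajectoryRecord:
    """Run one spawning-season simulation and return daily snapshots.

    Cohorts are released at the start of each of the first ``seed_days``
    days (fresh uniform positions each day), substeps advance the ensemble
    within each day with the day's flow-limited dt, and ages increment at
    day end.  A snapshot is recorded every ``snapshot_interval`` days: the
    state at the start of that day after its release (so a cohort released
    on day d first appears in snapshot d at age 0), plus a final snapshot
    at the end of the run.
    """
    if field.t_max - field.t_min < config.duration_days:
        raise ValueError(
            f"forcing covers {field.t_max - field.t_min:.0f} days; "
            f"simulation needs {config.duration_days}"
        )
    if schedule.seed_days > config.duration_days:
        raise ValueError("seed_days exceeds simulation duration")

    rng = np.random.default_rng(config.rng_seed)
    n = schedule.total
    ppd = schedule.particles_per_day

    ens = ParticleEnsemble(
        lon=np.full(n, np.nan),
        lat=np.full(n, np.nan),
        age=np.full(n, -1, dtype=np.int64),
        release_day=np.repeat(np.arange(schedule.seed_days), ppd),
        status=np.full(n, Status.UNRELEASED, dtype=np.int64),
    )

    snap_days = list(range(0, config.duration_days + 1, config.snapshot_interval))
    rec = TrajectoryRecord(
        days=np.array(snap_days, dtype=np.int64),
        lon=np.empty((len(snap_days), n)),
        lat=np.empty((len(snap_days), n)),
        age=np.empty((len(snap_days), n), dtype=np.int64),
        status=np.empty((len(snap_days), n), dtype=np.int64),
        release_day=ens.release_day.copy(),
    )

    def record(day: int) -> None:
        if day in snap_days:
            i = snap_days.index(day)
            rec.lon[i] = ens.lon
            rec.lat[i] = ens.lat
            rec.age[i] = ens.age
            rec.status[i] = ens.status

    def release(day: int) -> None:
        if day < schedule.seed_days and ppd > 0:
            pts = sample_polygon_points(polyset, ppd, rng)
            sl = slice(day * ppd, (day + 1) * ppd)
            ens.lon[sl] = pts[:, 0]
            ens.lat[sl] = pts[:, 1]
            ens.age[sl] = 0
            ens.status[sl] = Status.ACTIVE

    t0 = field.t_min
    for day in range(config.duration_days):
        release(day)
        record(day)  # state at the start of the day, after that day's release
        u_max = field.speed_max(t0 + day)
        dt = compute_substep(field, config, u_max)
        n_sub = max(1, int(np.ceil(SECONDS_PER_DAY / dt)))
        dt_day = SECONDS_PER_DAY / n_sub
        for k in range(n_sub):
            t = t0 + day + k * dt_day / SECONDS_PER_DAY
            advance_particles(ens, field, config, t, dt_day, rng)
        released = ens.status != Status.UNRELEASED
        ens.age[released] += 1
    record(config.duration_days)
    return rec
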