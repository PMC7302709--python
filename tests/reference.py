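"""Deliberately naive reference implementations used as independent oracles.

Everything here is written one-particle-at-a-time / from the defining
formulas, never calling the code paths it checks.
"""

from itertools import combinations

import numpy as np

from larvadrift.dispersal import Status
from larvadrift.ocean_field import METERS_PER_DEGREE


def naive_velocity_at(field, lon, lat, t):
    """Scalar time-then-bilinear interpolation, node by node."""
    nt = field.time_axis.size
    it = int(np.clip(np.floor(t - field.t_min), 0, nt - 2))
    wt = (t - field.t_min) - it
    nx = field.lon_axis.size
    ny = field.lat_axis.size
    fx = (lon - field.lon_min) / field.dx_deg
    fy = (lat - field.lat_min) / field.dy_deg
    ix = int(np.clip(np.floor(fx), 0, nx - 2))
    iy = int(np.clip(np.floor(fy), 0, ny - 2))
    tx = fx - ix
    ty = fy - iy
    out = []
    for a in (field._u_fill, field._v_fill):
        n00 = (1.0 - wt) * a[it, iy, ix] + wt * a[it + 1, iy, ix]
        n01 = (1.0 - wt) * a[it, iy, ix + 1] + wt * a[it + 1, iy, ix + 1]
        n10 = (1.0 - wt) * a[it, iy + 1, ix] + wt * a[it + 1, iy + 1, ix]
        n11 = (1.0 - wt) * a[it, iy + 1, ix + 1] + wt * a[it + 1, iy + 1, ix + 1]
        out.append(
            n00 * (1.0 - tx) * (1.0 - ty)
            + n01 * tx * (1.0 - ty)
            + n10 * (1.0 - tx) * ty
            + n11 * tx * ty
        )
    return out[0], out[1]


def naive_advance(ensemble, field, config, t, dt, rng):
    """One-particle-at-a-time stepper consuming the same random stream as the
    batched implementation (per active particle, ascending id: R_NA, R_NB)."""
    for pid in np.flatnonzero(ensemble.status == Status.ACTIVE):
        lon0 = ensemble.lon[pid]
        lat0 = ensemble.lat[pid]
        u, v = naive_velocity_at(field, lon0, lat0, t)
        r = rng.random(2)
        rho = np.sqrt(-4.0 * config.eh * dt * np.log1p(-r[0]))
        theta = 2.0 * np.pi * r[1]
        dx_m = u * dt + rho * np.cos(theta)
        dy_m = v * dt + rho * np.sin(theta)
        lat1 = lat0 + dy_m / METERS_PER_DEGREE
        lon1 = lon0 + dx_m / (METERS_PER_DEGREE * np.cos(np.radians(lat0)))
        if not field.contains(lon1, lat1):
            ensemble.status[pid] = Status.EXITED
        elif not field.is_land_at(lon1, lat1):
            ensemble.lon[pid] = lon1
            ensemble.lat[pid] = lat1
    return ensemble


def pearson_from_definition(x, y):
    """Sums-of-products product-moment correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm = x - x.mean()
    ym = y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def exact_ranksum_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of labelings.

    Assumes a tie-free pooled sample; the null U distribution is then
    symmetric and the two-sided p is P(|U - mu| >= |U_obs - mu|).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    m, n = x.size, y.size
    mu = m * n / 2.0
    u_obs = ranks[:m].sum() - m * (m + 1) / 2.0
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(m + n), m):
        u = ranks[list(idx)].sum() - m * (m + 1) / 2.0
        if abs(u - mu) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def t_one_sample(values, mu0):
    """From-definition one-sample t statistic."""
    v = np.asarray(values, float)
    return float((v.mean() - mu0) / (v.std(ddof=1) / np.sqrt(v.size)))
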