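"""Statistics comparing simulated site visit counts with observed spat counts.

The observed data are single-harvest spat totals at collector deployment
sites (n = 28 in the motivating survey); the simulated quantity is the
cumulative particle-visit count of the grid cell containing each site.
Spat counts are arcsinh-transformed (a variance-stabilising transform valid
at zero) before correlation; particle counts enter untransformed by default.
Besides the per-season Pearson correlation, the module provides a
continuity-corrected Wilcoxon rank-sum comparison of pooled seasonal data,
per-site one-sample t-tests on z-standardised values, Shapiro-Wilk and
Levene diagnostics, and a pairwise site-corridor median density matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .visit_grid import VisitGrid, site_cell_count

#: Symmetric site x site table of median corridor particle counts.
PairwiseDensityMatrix = pd.DataFrame


# ---------------------------------------------------------------------------
# transforms and correlation


def arcsinh_transform(counts) -> np.ndarray:
    """Elementwise ln(x + sqrt(x^2 + 1)); strictly increasing, 0 -> 0."""
    x = np.asarray(counts, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to arcsinh transform")
    if np.any(x < 0):
        raise ValueError("negative counts are not valid for the arcsinh transform")
    return np.arcsinh(x)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its t-test: r, df = n-2, t, two-sided p, r^2."""

    r: float
    df: int
    t_stat: float
    p_two_sided: float
    r_squared: float
    n: int

    def __str__(self) -> str:
        return (
            f"r({self.df}) = {self.r:.3f}, p = {self.p_two_sided:.3g}, "
            f"R2 = {self.r_squared:.4f}"
        )


def pearson_with_df(x, y) -> CorrelationResult:
    """Product-moment correlation with t = r*sqrt(df/(1-r^2)), df = n-2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 for a correlation, got {n}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(r=r, df=df, t_stat=float(t), p_two_sided=float(p),
                             r_squared=r * r, n=n)


# ---------------------------------------------------------------------------
# location tests


@dataclass(frozen=True)
class RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) result.

    ``w`` is the U statistic of the first sample (its rank sum minus the
    minimum possible), so printed W values are comparable only up to this
    convention.  p is two-sided from the continuity-corrected normal
    approximation with tie-adjusted variance.
    """

    w: float
    p_two_sided: float
    n1: int
    n2: int


def rank_sum_test(simulated, observed) -> RankSumResult:
    """Two-sample rank-sum test of a location difference."""
    x = np.asarray(simulated, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical: rank-sum variance degenerate")
    res = stats.mannwhitneyu(
        x, y, use_continuity=True, alternative="two-sided", method="asymptotic"
    )
    return RankSumResult(
        w=float(res.statistic), p_two_sided=float(res.pvalue), n1=x.size, n2=y.size
    )


def per_site_t_tests(seasonal_counts: pd.DataFrame, spat: pd.Series) -> pd.DataFrame:
    """One-sample t-test per site of seasonal counts against the spat value.

    ``seasonal_counts`` is a site x season table of visit counts; ``spat``
    the per-site observed totals.  Counts and spat live on incomparable
    scales, so both are z-standardised across sites first (each season
    column, and the arcsinh-spat vector); each site's standardised seasonal
    values are then tested against its standardised spat value.  Sites with
    zero across-season variance are flagged and their p omitted.  Raw
    p-values are reported alongside Benjamini-Hochberg adjusted ones.
    """
    if (seasonal_counts.shape[1]) < 2:
        raise ValueError("need >= 2 seasonal values per site")
    spat = spat.loc[seasonal_counts.index]

    def zscore(a):
        a = np.asarray(a, dtype=float)
        s = a.std(ddof=1)
        if s == 0:
            raise ValueError("zero variance across sites")
        return (a - a.mean()) / s

    z_counts = np.column_stack([zscore(seasonal_counts[c]) for c in seasonal_counts])
    z_spat = zscore(arcsinh_transform(spat.values))

    rows = []
    for i, site in enumerate(seasonal_counts.index):
        vals = z_counts[i]
        raw = seasonal_counts.iloc[i].to_numpy(dtype=float)
        degenerate = np.std(raw, ddof=1) == 0.0 or np.std(vals, ddof=1) == 0.0
        if degenerate and np.allclose(vals, z_spat[i]):
            t, p = 0.0, 1.0
            degenerate = False
        elif degenerate:
            t, p = np.nan, np.nan
        else:
            res = stats.ttest_1samp(vals, popmean=z_spat[i])
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"site": site, "t": t, "df": vals.size - 1, "p": p, "degenerate": degenerate}
        )
    out = pd.DataFrame(rows).set_index("site")
    valid = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if valid.any():
        adj[valid.values] = stats.false_discovery_control(out.loc[valid, "p"].values)
    out["p_bh"] = adj
    return out


def normality_and_variance_checks(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Shapiro-Wilk per sample plus a pooled Levene (center=median) test.

    Returns one row per sample (W, p) and a final ``levene`` row with the
    across-group statistic and p.  Sample sizes must be in [3, 5000].
    """
    rows = []
    arrays = []
    for name, a in samples.items():
        a = np.asarray(a, dtype=float)
        if not 3 <= a.size <= 5000:
            raise ValueError(f"sample '{name}' size {a.size} outside [3, 5000]")
        arrays.append(a)
        w, p = stats.shapiro(a)
        rows.append({"sample": name, "test": "shapiro", "stat": float(w), "p": float(p)})
    if len(arrays) >= 2:
        lev, lp = stats.levene(*arrays, center="median")
        rows.append({"sample": "all", "test": "levene", "stat": float(lev), "p": float(lp)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise corridor density


def _supercover_cells(x0: float, y0: float, x1: float, y1: float) -> list[tuple[int, int]]:
    """All grid cells touched by the segment between two points.

    Coordinates are continuous cell coordinates (cell (i, j) spans
    [i, i+1) x [j, j+1)).  Amanatides-Woo traversal; on an exact corner
    crossing both axis neighbours are included (supercover).
    """
    ix, iy = int(np.floor(x0)), int(np.floor(y0))
    ix1, iy1 = int(np.floor(x1)), int(np.floor(y1))
    cells = [(ix, iy)]
    dx, dy = x1 - x0, y1 - y0
    step_x = 1 if dx > 0 else -1
    step_y = 1 if dy > 0 else -1

    def t_next(p, i, d, step):
        if d == 0:
            return np.inf
        edge = i + (1 if step > 0 else 0)
        return (edge - p) / d

    tx = t_next(x0, ix, dx, step_x)
    ty = t_next(y0, iy, dy, step_y)
    tdx = abs(1.0 / dx) if dx != 0 else np.inf
    tdy = abs(1.0 / dy) if dy != 0 else np.inf
    guard = 0
    while (ix, iy) != (ix1, iy1):
        guard += 1
        if guard > 10_000:  # pragma: no cover - malformed input guard
            raise RuntimeError("corridor traversal did not terminate")
        if np.isclose(tx, ty):  # corner: include both side cells
            cells.append((ix + step_x, iy))
            cells.append((ix, iy + step_y))
            ix += step_x
            iy += step_y
            tx += tdx
            ty += tdy
        elif tx < ty:
            ix += step_x
            tx += tdx
        else:
            iy += step_y
            ty += tdy
        cells.append((ix, iy))
    return cells


def corridor_cell_counts(grid: VisitGrid, a: tuple[float, float], b: tuple[float, float]) -> np.ndarray:
    """Counts of the cells crossed by the straight lon/lat segment a-b."""
    ox = grid.lon_centers[0] - 0.5 * grid.dx_deg
    oy = grid.lat_centers[0] - 0.5 * grid.dy_deg
    x0, y0 = (a[0] - ox) / grid.dx_deg, (a[1] - oy) / grid.dy_deg
    x1, y1 = (b[0] - ox) / grid.dx_deg, (b[1] - oy) / grid.dy_deg
    cells = _supercover_cells(x0, y0, x1, y1)
    nx, ny = grid.lon_centers.size, grid.lat_centers.size
    return np.array(
        [grid.counts[j, i] for i, j in cells if 0 <= i < nx and 0 <= j < ny],
        dtype=float,
    )


def pairwise_corridor_density(
    grids: list[VisitGrid], sites: pd.DataFrame
) -> pd.DataFrame:
    """Median corridor particle density between every pair of sites.

    For each site pair and each supplied grid (typically early and late
    recruitment windows of each season) the median count along the straight
    lon/lat corridor between the sites is taken; the matrix entry is the
    median of those per-grid medians.  The diagonal is the median of the
    site's own cell count across grids.  Symmetric, non-negative.
    """
    if len(sites) < 2:
        raise ValueError("need >= 2 sites for a pairwise matrix")
    names = list(sites["name"])
    coords = {r["name"]: (r["lon"], r["lat"]) for _, r in sites.iterrows()}
    m = pd.DataFrame(0.0, index=names, columns=names)
    for i, si in enumerate(names):
        for sj in names[i:]:
            if si == sj:
                vals = [site_cell_count(g, coords[si], name=si) for g in grids]
            else:
                vals = [np.median(corridor_cell_counts(g, coords[si], coords[sj])) for g in grids]
            med = float(np.median(vals))
            m.loc[si, sj] = med
            m.loc[sj, si] = med
    return m
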