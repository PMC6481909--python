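"""Time-difference-of-arrival localization of the expansion origin.

For a candidate origin o, each defined population pair contributes the
distance difference dd(i, j) = d(o, j) - d(o, i); psi(i, j) is regressed on
dd through the origin (a population is at distance difference 0 from
itself and has psi 0 by construction).  The candidate minimizing the
residual sum of squares over a padded geographic grid is the inferred
origin.  Significance against isolation by distance comes from permuting
the population -> coordinate assignment while keeping psi fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .directionality import PsiMatrix
from .genotypes import SampleInfo, population_coordinates
from .selection import ConfigurationError

logger = logging.getLogger("rangexp")

EARTH_RADIUS_KM = 6371.0088


def geodesic_distance(p, q) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    return float(_haversine(np.asarray(p[0]), np.asarray(p[1]),
                            np.asarray(q[0]), np.asarray(q[1])))


def _haversine(lat1, lon1, lat2, lon2):
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude out of [-90, 90]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class Grid:
    """Regular lat/lon search grid (row-major: lat outer, lon inner)."""

    lats: np.ndarray
    lons: np.ndarray
    bbox: tuple[float, float, float, float]  # lat_min, lat_max, lon_min, lon_max
    spacing_deg: float
    padding_fraction: float

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.lats), len(self.lons)

    @property
    def n_cells(self) -> int:
        return len(self.lats) * len(self.lons)

    def cell_coords(self) -> np.ndarray:
        """(n_cells, 2) array of (lat, lon), row-major."""
        glat, glon = np.meshgrid(self.lats, self.lons, indexing="ij")
        return np.column_stack([glat.ravel(), glon.ravel()])

    def is_boundary(self, flat_index: int) -> bool:
        r, c = divmod(flat_index, len(self.lons))
        return (r in (0, len(self.lats) - 1)) or (c in (0, len(self.lons) - 1))


def make_grid(info: list[SampleInfo], spacing_deg: float = 0.25,
              padding_fraction: float = 0.5) -> Grid:
    """Grid over the populations' bounding box padded on each side."""
    if spacing_deg <= 0:
        raise ConfigurationError("grid spacing must be > 0")
    coords = np.array(list(population_coordinates(info).values()))
    if len(np.unique(coords, axis=0)) < 2:
        raise ConfigurationError("degenerate extent: all populations at one coordinate")
    lat_min, lon_min = coords.min(axis=0)
    lat_max, lon_max = coords.max(axis=0)
    dlat = (lat_max - lat_min) * padding_fraction
    dlon = (lon_max - lon_min) * padding_fraction
    lat_lo = max(lat_min - dlat, -90.0)
    lat_hi = min(lat_max + dlat, 90.0)
    lon_lo = max(lon_min - dlon, -180.0)
    lon_hi = min(lon_max + dlon, 180.0)
    lats = np.arange(lat_lo, lat_hi + spacing_deg * 1e-9, spacing_deg)
    lons = np.arange(lon_lo, lon_hi + spacing_deg * 1e-9, spacing_deg)
    if lats.size == 0:
        lats = np.array([lat_lo])
    if lons.size == 0:
        lons = np.array([lon_lo])
    return Grid(lats, lons, (lat_lo, lat_hi, lon_lo, lon_hi), spacing_deg, padding_fraction)


@dataclass
class OriginSurface:
    grid: Grid
    rss: np.ndarray    # flat, row-major over grid cells
    r2: np.ndarray
    slopes: np.ndarray
    best_index: int
    best_cell: tuple[float, float]
    slope: float       # slope at best cell, psi per km
    pvalue: float | None
    boundary_flag: bool
    tie_flag: bool
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        cells = self.grid.cell_coords()
        return pd.DataFrame({
            "lat": cells[:, 0], "lon": cells[:, 1],
            "rss": self.rss, "r2": self.r2, "slope": self.slopes,
        })

    def summary(self) -> dict:
        return {
            "best_lat": self.best_cell[0], "best_lon": self.best_cell[1],
            "slope_per_km": self.slope,
            "r2": float(self.r2[self.best_index]),
            "rss": float(self.rss[self.best_index]),
            "pvalue": self.pvalue,
            "boundary_flag": self.boundary_flag,
            "tie_flag": self.tie_flag,
            "n_pairs": self.n_pairs,
            "bbox": list(self.grid.bbox),
            "padding_fraction": self.grid.padding_fraction,
            "spacing_deg": self.grid.spacing_deg,
        }


def _defined_pairs(psi: PsiMatrix):
    """Upper-triangle pairs with a defined psi; (i_idx, j_idx, psi_values)."""
    P = len(psi.populations)
    iu, ju = np.triu_indices(P, 1)
    vals = psi.psi[iu, ju]
    ok = np.isfinite(vals) & (psi.n_informative[iu, ju] > 0)
    return iu[ok], ju[ok], vals[ok]


def _pair_fit(dd: np.ndarray, pv: np.ndarray):
    """Least squares through the origin of psi on distance differences.

    dd: (n_cells, n_pairs).  Returns (slope, rss, r2) per cell.  Cells with
    all-zero dd get rss = inf (undefined, worst fit).
    """
    tss = float(pv @ pv)
    A = dd @ pv
    B = (dd * dd).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(B > 0, A / B, 0.0)
        expl = np.where(B > 0, A * A / B, 0.0)
    rss = tss - expl
    if tss > 0:
        r2 = expl / tss
    else:
        r2 = np.zeros_like(rss)
    rss = np.where(B > 0, rss, np.inf)
    if tss == 0.0:
        rss = np.where(B > 0, 0.0, np.inf)
    return slope, rss, r2


def tdoa_fit_at(origin, psi: PsiMatrix, info: list[SampleInfo]):
    """(slope, rss, r2) of the through-origin fit at one candidate origin."""
    iu, ju, pv = _defined_pairs(psi)
    if pv.size < 3:
        raise ConfigurationError("need >= 3 defined psi pairs for a TDOA fit")
    coords = population_coordinates(info)
    d = np.array([geodesic_distance(origin, coords[p]) for p in psi.populations])
    dd = (d[ju] - d[iu])[None, :]
    slope, rss, r2 = _pair_fit(dd, pv)
    return float(slope[0]), float(rss[0]), float(r2[0])


def _cell_pop_distances(grid_cells: np.ndarray, psi: PsiMatrix,
                        info: list[SampleInfo]) -> np.ndarray:
    coords = population_coordinates(info)
    missing = [p for p in psi.populations if p not in coords]
    if missing:
        raise KeyError(f"populations without coordinates: {missing}")
    plat = np.array([coords[p][0] for p in psi.populations])
    plon = np.array([coords[p][1] for p in psi.populations])
    return _haversine(grid_cells[:, [0]], grid_cells[:, [1]],
                      plat[None, :], plon[None, :])


def origin_scan(psi: PsiMatrix, info: list[SampleInfo], grid: Grid,
                require_positive_slope: bool = True) -> OriginSurface:
    """Evaluate the TDOA fit on every grid cell; best cell = argmin RSS.

    With ``require_positive_slope`` (default) the argmin is taken over cells
    whose fitted slope is positive — the expansion model predicts psi
    increasing with distance from the origin, and the unconstrained argmin
    can land on a mirror solution with inverted sign.  Falls back to the
    global argmin when no cell has a positive slope.
    """
    iu, ju, pv = _defined_pairs(psi)
    if pv.size == 0:
        raise ConfigurationError("no defined psi pairs; cannot scan for an origin")
    D = _cell_pop_distances(grid.cell_coords(), psi, info)
    dd = D[:, ju] - D[:, iu]
    slope, rss, r2 = _pair_fit(dd, pv)
    if require_positive_slope and np.any(slope > 0):
        best = int(np.argmin(np.where(slope > 0, rss, np.inf)))
    else:
        best = int(np.argmin(rss))  # row-major first on ties
    ties = np.flatnonzero(rss == rss[best])
    tie_flag = ties.size > 1
    if tie_flag:
        logger.warning("origin_scan: %d cells tie for best fit; keeping first "
                       "in row-major order", ties.size)
    boundary = grid.is_boundary(best)
    if boundary:
        logger.warning("origin_scan: best cell lies on the grid boundary; "
                       "origin accuracy is reduced")
    cells = grid.cell_coords()
    return OriginSurface(
        grid=grid, rss=rss, r2=r2, slopes=slope,
        best_index=best, best_cell=(float(cells[best, 0]), float(cells[best, 1])),
        slope=float(slope[best]), pvalue=None,
        boundary_flag=boundary, tie_flag=tie_flag, n_pairs=int(pv.size),
    )


def test_expansion_vs_ibd(psi: PsiMatrix, info: list[SampleInfo], grid: Grid,
                          n_perm: int = 999, seed: int = 0) -> float:
    """Permutation p-value of the expansion signal against an IBD null.

    Statistic: r-squared of the best-fitting grid cell.  Null: permute which
    population sits at which coordinate, keeping the psi matrix fixed.
    """
    if n_perm < 99:
        raise ConfigurationError("n_perm must be >= 99")
    # canonical population order so the p-value is invariant to input order
    order = sorted(range(len(psi.populations)), key=lambda i: psi.populations[i])
    psi = PsiMatrix(
        populations=[psi.populations[i] for i in order],
        psi=psi.psi[np.ix_(order, order)],
        se=psi.se[np.ix_(order, order)],
        n_informative=psi.n_informative[np.ix_(order, order)],
        m=psi.m, n_bootstrap=psi.n_bootstrap, seed=psi.seed,
    )
    iu, ju, pv = _defined_pairs(psi)
    if pv.size == 0:
        raise ConfigurationError("no defined psi pairs")
    P = len(psi.populations)
    if P < 4:
        logger.warning("test_expansion_vs_ibd: only %d populations; "
                       "the permutation test is underpowered", P)
    D = _cell_pop_distances(grid.cell_coords(), psi, info)

    def stat(perm: np.ndarray) -> float:
        Dp = D[:, perm]
        dd = Dp[:, ju] - Dp[:, iu]
        _, rss, r2 = _pair_fit(dd, pv)
        return float(r2[np.argmin(rss)])

    t_obs = stat(np.arange(P))
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        if stat(rng.permutation(P)) >= t_obs - 1e-12:
            n_ge += 1
    return (1.0 + n_ge) / (1.0 + n_perm)
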