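"""Kernel utilisation distributions on a 1-km colony-centred grid,
percent-volume contours and Bhattacharyya overlap.

The kernel is an isotropic bivariate Gaussian evaluated exactly at cell
centres (separable, so the grid surface is a single matrix product over
the points) and renormalized over the finite grid, which guarantees the
unit-mass invariant the overlap index needs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union


class ZeroVarianceError(ValueError):
    pass


class CoverageError(ValueError):
    pass


class GridMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Regular square grid in projected km; ``(x0, y0)`` is the outer
    corner of cell (0, 0) and cell centres sit at half-cell offsets."""

    x0: float
    y0: float
    nx: int
    ny: int
    cell_km: float = 1.0

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell_km

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cell_km

    @classmethod
    def around_points(cls, x, y, margin_km: float, cell_km: float = 1.0) -> "GridSpec":
        """Bounding box of the points padded by ``margin_km`` (use 3h)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        x0 = np.floor((x.min() - margin_km) / cell_km) * cell_km
        y0 = np.floor((y.min() - margin_km) / cell_km) * cell_km
        nx = int(np.ceil((x.max() + margin_km - x0) / cell_km))
        ny = int(np.ceil((y.max() + margin_km - y0) / cell_km))
        return cls(x0=x0, y0=y0, nx=nx, ny=ny, cell_km=cell_km)


@dataclass
class UDGrid:
    """Discretized utilisation distribution: cell masses summing to one."""

    grid: GridSpec
    masses: np.ndarray  # shape (ny, nx)
    bandwidth_km: float

    def __post_init__(self) -> None:
        if self.masses.shape != (self.grid.ny, self.grid.nx):
            raise GridMismatchError("mass array does not match grid shape")
        if np.any(self.masses < 0) or abs(float(self.masses.sum()) - 1.0) > 1e-9:
            raise ValueError("masses must be nonnegative and sum to 1")


@dataclass(frozen=True)
class ContourLevel:
    level: float
    mask: np.ndarray
    area_km2: float
    polygon: object  # shapely (Multi)Polygon outline


def href_bandwidth(x, y) -> float:
    """Ad hoc bivariate-normal reference bandwidth:
    h = sqrt((var(x) + var(y)) / 2) * n^(-1/6)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 2:
        raise ZeroVarianceError("need >= 2 points")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx + vy <= 0:
        raise ZeroVarianceError("all points identical: zero-variance bandwidth")
    return float(np.sqrt(0.5 * (vx + vy)) * n ** (-1.0 / 6.0))


def kernel_ud(x, y, h: float, grid: GridSpec) -> UDGrid:
    """Gaussian kernel UD on the grid, renormalized to total mass 1.

    Every point must lie inside the grid (the grid itself should extend a
    3h margin beyond the data; see :meth:`GridSpec.around_points`).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xmax = grid.x0 + grid.nx * grid.cell_km
    ymax = grid.y0 + grid.ny * grid.cell_km
    bad = (x < grid.x0) | (x > xmax) | (y < grid.y0) | (y > ymax)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise CoverageError(f"grid does not cover point ({x[i]:.1f}, {y[i]:.1f}) km")
    xc = grid.x_centers
    yc = grid.y_centers
    masses = np.zeros((grid.ny, grid.nx))
    chunk = 512
    inv2h2 = 1.0 / (2.0 * h * h)
    for i in range(0, len(x), chunk):
        gx = np.exp(-((xc[None, :] - x[i : i + chunk, None]) ** 2) * inv2h2)
        gy = np.exp(-((yc[None, :] - y[i : i + chunk, None]) ** 2) * inv2h2)
        masses += gy.T @ gx
    total = masses.sum()
    if total <= 0:
        raise ZeroVarianceError("degenerate kernel surface")
    return UDGrid(grid=grid, masses=masses / total, bandwidth_km=float(h))


def volume_contour(ud: UDGrid, level: float, build_polygon: bool = True) -> ContourLevel:
    """Smallest cell set holding ``level`` percent of the mass.

    Cells are accumulated in descending mass order until the cumulative
    mass reaches level/100; cells tied with the boundary mass are all
    included (deterministic, no tie-breaking randomness).
    """
    flat = ud.masses.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level / 100.0, side="left"))
    k = min(k, len(flat) - 1)
    boundary_mass = flat[order[k]]
    mask = (ud.masses >= boundary_mass) & (ud.masses > 0)
    area = float(mask.sum()) * ud.grid.cell_km**2
    poly = None
    if build_polygon:
        cells = np.argwhere(mask)
        g = ud.grid
        boxes = [
            box(
                g.x0 + j * g.cell_km,
                g.y0 + i * g.cell_km,
                g.x0 + (j + 1) * g.cell_km,
                g.y0 + (i + 1) * g.cell_km,
            )
            for i, j in cells
        ]
        poly = unary_union(boxes) if boxes else None
    return ContourLevel(level=float(level), mask=mask, area_km2=area, polygon=poly)


def volume_contours(ud: UDGrid, levels=(50, 75, 95), build_polygons: bool = False) -> dict:
    return {lv: volume_contour(ud, lv, build_polygon=build_polygons) for lv in levels}


def ba_overlap(ud1: UDGrid, ud2: UDGrid) -> float:
    """Bhattacharyya affinity sum_cells sqrt(p_i q_i); 0 disjoint, 1 identical."""
    if ud1.grid != ud2.grid:
        raise GridMismatchError("utilisation distributions are on different grids")
    return float(np.sqrt(ud1.masses * ud2.masses).sum())
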