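"""Kernel utilisation distributions and isopleth extraction.

The UD is a gridded probability surface from an isotropic bivariate
Gaussian kernel with standard deviation h (km) per axis.  h follows the
central-place-forager "mag" convention: the natural log of the median
per-trip maximum distance from the colony.  Isopleths at 50/75/95%
cumulative mass delineate core, intermediate and home-range areas; an
isopleth is the smallest set of grid cells holding the stated fraction of
UD mass, polygonised along cell boundaries so areas add exactly across the
population stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import box
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (0.50, 0.75, 0.95)
SUBSETS = ("all", "resting", "foraging", "transiting", "sample")


@dataclass
class UDGrid:
    """Gridded utilisation distribution (probability per km²).

    ``density[i, j]`` is the cell with x-centre ``x0 + (i + 0.5) * cell``
    and y-centre ``y0 + (j + 0.5) * cell``; Σ density · cell² = 1.
    """

    x0: float
    y0: float
    cell_size: float
    density: np.ndarray  # (nx, ny)

    @property
    def nx(self) -> int:
        return self.density.shape[0]

    @property
    def ny(self) -> int:
        return self.density.shape[1]

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def x_centres(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size

    def y_centres(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size

    def mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


@dataclass
class Isopleth:
    """Cells and dissolved polygon of one cumulative-mass level."""

    level: float
    cells: np.ndarray  # boolean (nx, ny) mask on the source grid
    grid: UDGrid
    area_km2: float
    polygon: object = field(default=None, repr=False)  # shapely geometry, lazy

    def geometry(self):
        """Dissolved cell-boundary polygon (built on first request)."""
        if self.polygon is None:
            self.polygon = _cells_to_polygon(self.grid, self.cells)
        return self.polygon


def bandwidth_mag(max_distances_km, h_min: float = 0.5) -> float:
    """Smoothing parameter h = ln(median per-trip max distance from colony).

    Floored at *h_min* (default 0.5 km) because the log is non-positive for
    ranges ≤ 1 km.
    """
    md = np.asarray(list(max_distances_km), dtype=float)
    if md.size == 0:
        raise ValueError("need at least one complete trip")
    h = float(np.log(np.median(md)))
    if h < h_min:
        logger.warning(
            "bandwidth_mag: ln(median range %.3f km) = %.3f below floor; using %.3f km",
            float(np.median(md)), h, h_min,
        )
        return h_min
    return h


def make_grid_spec(
    points: np.ndarray,
    h: float,
    cell_size: float | None = None,
    margin_frac: float = 0.20,
    max_cells: int = 2000,
) -> tuple[float, float, float, int, int]:
    """(x0, y0, cell, nx, ny) covering the points with a generous margin.

    The margin is max(20% of each span, 4h) per side: generous enough that
    the mass truncated outside the grid (< 0.02% of a kernel at 4h) does
    not bias high-level isopleth areas.  Default cell size is h/10,
    enlarged if the grid would exceed *max_cells* per axis.
    """
    pts = np.asarray(points, dtype=float)
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    mx = max(margin_frac * max(xmax - xmin, 1e-9), 4.0 * h)
    my = max(margin_frac * max(ymax - ymin, 1e-9), 4.0 * h)
    x0, x1 = xmin - mx, xmax + mx
    y0, y1 = ymin - my, ymax + my
    cell = h / 10.0 if cell_size is None else cell_size
    cell = max(cell, (x1 - x0) / max_cells, (y1 - y0) / max_cells)
    nx = int(np.ceil((x1 - x0) / cell))
    ny = int(np.ceil((y1 - y0) / cell))
    return x0, y0, cell, nx, ny


def compute_ud(
    points: np.ndarray,
    h: float,
    grid_spec: tuple[float, float, float, int, int] | None = None,
) -> UDGrid:
    """Gaussian-kernel UD of a point set on a regular grid.

    Each point contributes an isotropic bivariate Gaussian with standard
    deviation *h* per axis; the surface is renormalised so its mass over
    the grid is exactly 1.  Works for a single point (the UD is then one
    kernel).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid_spec is None:
        grid_spec = make_grid_spec(pts, h)
    x0, y0, cell, nx, ny = grid_spec
    xc = x0 + (np.arange(nx) + 0.5) * cell
    yc = y0 + (np.arange(ny) + 0.5) * cell
    # separable kernel: density = Gx^T Gy summed over points
    gx = np.exp(-0.5 * ((xc[None, :] - pts[:, 0:1]) / h) ** 2)
    gy = np.exp(-0.5 * ((yc[None, :] - pts[:, 1:2]) / h) ** 2)
    density = gx.T @ gy
    total = density.sum() * cell * cell
    if total <= 0:
        raise ValueError("all kernel mass fell outside the grid")
    density /= total
    return UDGrid(x0=x0, y0=y0, cell_size=cell, density=density)


def isopleth(ud: UDGrid, level: float) -> Isopleth:
    """Smallest cell set holding ≥ *level* of UD mass.

    Cells are taken in descending density order; all cells tied with the
    threshold density are included (deterministic and level-conservative).
    The area is the selected cell count × cell area.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    flat = ud.density.ravel()
    order = np.argsort(flat)[::-1]
    cmass = np.cumsum(flat[order]) * ud.cell_area
    k = int(np.searchsorted(cmass, level * ud.mass(), side="left")) + 1
    k = min(k, flat.size)
    thresh = flat[order[k - 1]]
    mask = (ud.density >= thresh) & (ud.density > 0)
    area = float(mask.sum() * ud.cell_area)
    return Isopleth(level=level, cells=mask, grid=ud, area_km2=area)


def _cells_to_polygon(grid: UDGrid, mask: np.ndarray):
    """Dissolve selected cells into a (multi)polygon along cell boundaries."""
    ii, jj = np.nonzero(mask)
    if len(ii) == 0:
        return shapely.geometry.Polygon()
    cs = grid.cell_size
    boxes = [
        box(grid.x0 + i * cs, grid.y0 + j * cs, grid.x0 + (i + 1) * cs, grid.y0 + (j + 1) * cs)
        for i, j in zip(ii, jj)
    ]
    return unary_union(boxes)


def subsample_control(
    all_indices: np.ndarray, decoded_states: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Random location subsample matching the rarest behaviour's fix count.

    Controls for sample-size effects: the subsample is drawn uniformly
    without replacement from ALL of the individual's fixes, with size equal
    to the smallest per-behaviour count.
    """
    counts = np.bincount(decoded_states, minlength=3)
    n = int(counts.min())
    if n == 0:
        raise ValueError("a behaviour has zero fixes; individual unusable for control")
    rng = np.random.default_rng(seed)
    return rng.choice(np.asarray(all_indices), size=n, replace=False)


def behaviour_ud_set(
    points: np.ndarray,
    decoded_states: np.ndarray,
    h: float,
    levels=DEFAULT_LEVELS,
    min_fixes: int = 10,
    seed: int = 0,
    individual_id: str = "",
) -> dict[str, dict[float, Isopleth]]:
    """UD isopleths per subset: all, resting, foraging, transiting, sample.

    All subsets share the same bandwidth and the same grid (spanning the
    full point set) so isopleth overlap is a like-for-like comparison.
    Subsets with fewer than *min_fixes* fixes are skipped with a log entry.
    """
    pts = np.asarray(points, dtype=float)
    states = np.asarray(decoded_states)
    if len(pts) != len(states):
        raise ValueError("points and decoded states must align")
    grid_spec = make_grid_spec(pts, h)
    subsets: dict[str, np.ndarray] = {"all": np.arange(len(pts))}
    for s, name in enumerate(("resting", "foraging", "transiting")):
        subsets[name] = np.flatnonzero(states == s)
    if all(len(subsets[n]) > 0 for n in ("resting", "foraging", "transiting")):
        subsets["sample"] = subsample_control(np.arange(len(pts)), states, seed=seed)
    out: dict[str, dict[float, Isopleth]] = {}
    for name, idx in subsets.items():
        if len(idx) < min_fixes:
            logger.info(
                "behaviour_ud_set(%s): skipping %s (%d < %d fixes)",
                individual_id, name, len(idx), min_fixes,
            )
            continue
        ud = compute_ud(pts[idx], h, grid_spec)
        out[name] = {lv: isopleth(ud, lv) for lv in levels}
    return out
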