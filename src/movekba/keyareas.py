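"""Population-level key areas scaled by tracking-sample representativeness.

Representativeness asks how much of the source population's space use the
tracked sample captures: for increasing sample sizes k, individuals are
repeatedly drawn, their pooled locations turned into a utilisation
distribution, and the inclusion rate of held-out individuals' locations in
the level-isopleth measured.  A saturating (Michaelis-Menten) curve fitted
to inclusion vs k gives the asymptote; representativeness is the fitted
inclusion at the full sample size as a percentage of that asymptote.
Colonies under the 70% threshold (or too small to assess) are excluded from
population-level estimates.

Key areas aggregate individual core-area isopleths on a common colony
grid: each cell's fraction of individuals is multiplied by proportional
representativeness to estimate the percentage of the source population
using the cell; cells at or above the population threshold (10%) are
dissolved into the key-area polygon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import curve_fit

from movekba.ud import Isopleth, compute_ud, isopleth

logger = logging.getLogger(__name__)

REPRESENTATIVENESS_THRESHOLD = 70.0  # percent, population-estimate gate


@dataclass
class RepresentativenessResult:
    colony_id: str
    subset: str
    representativeness: float  # percent, NaN when unusable
    n_individuals: int
    inclusion_curve: pd.DataFrame | None  # columns k, mean_inclusion
    curve_params: tuple[float, float] | None  # (a, b) of a·k/(b+k)
    usable: bool
    reason: str = ""


@dataclass
class KeyAreaEstimate:
    colony_id: str
    subset: str
    level: float
    area_km2: float
    polygon: object = field(repr=False)  # shapely geometry (possibly empty)
    population_pct: np.ndarray = field(repr=False)  # (nx, ny) % of source population
    grid_origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    representativeness: float = 100.0
    threshold_pct: float = 10.0


def _michaelis_menten(k, a, b):
    return a * k / (b + k)


def assess_representativeness(
    location_sets: dict[str, np.ndarray],
    h: float,
    level: float = 0.5,
    n_iterations: int = 50,
    seed: int = 0,
    colony_id: str = "",
    subset: str = "all",
) -> RepresentativenessResult:
    """Bootstrap inclusion-vs-sample-size curve and saturation estimate.

    *location_sets* maps individual_id → (n, 2) projected locations (km).
    Needs ≥ 3 individuals; below that the result is flagged unusable.
    """
    inds = sorted(location_sets)
    n = len(inds)
    if n < 3:
        return RepresentativenessResult(
            colony_id, subset, float("nan"), n, None, None, False,
            reason=f"sample size {n} too small to calculate representativeness",
        )
    rng = np.random.default_rng(seed)
    pts = {i: np.asarray(location_sets[i], dtype=float) for i in inds}

    ks = np.arange(1, n)
    mean_inclusion = np.empty(len(ks))
    for ki, k in enumerate(ks):
        incl = np.empty(n_iterations)
        for it in range(n_iterations):
            chosen = rng.choice(n, size=k, replace=False)
            pool = np.vstack([pts[inds[c]] for c in chosen])
            ud = compute_ud(pool, h)
            iso = isopleth(ud, level)
            held = np.vstack([pts[inds[c]] for c in range(n) if c not in set(chosen)])
            incl[it] = _inclusion_rate(iso, held)
        mean_inclusion[ki] = incl.mean()

    curve = pd.DataFrame({"k": ks, "mean_inclusion": mean_inclusion})
    try:
        (a, b), _ = curve_fit(
            _michaelis_menten, ks.astype(float), mean_inclusion,
            p0=[max(mean_inclusion.max(), 1e-3), 1.0],
            bounds=([1e-6, 1e-9], [1.0, 1e6]), maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return RepresentativenessResult(
            colony_id, subset, float("nan"), n, curve, None, False,
            reason=f"inclusion curve fit failed: {exc}",
        )
    rep = 100.0 * _michaelis_menten(float(n), a, b) / a  # = 100·n/(b+n)
    rep = float(min(rep, 100.0))
    return RepresentativenessResult(
        colony_id, subset, rep, n, curve, (float(a), float(b)),
        usable=rep >= REPRESENTATIVENESS_THRESHOLD,
        reason="" if rep >= REPRESENTATIVENESS_THRESHOLD
        else f"representativeness {rep:.2f}% below the {REPRESENTATIVENESS_THRESHOLD:.0f}% threshold",
    )


def _inclusion_rate(iso: Isopleth, points: np.ndarray) -> float:
    """Fraction of points whose grid cell belongs to the isopleth."""
    g = iso.grid
    i = np.floor((points[:, 0] - g.x0) / g.cell_size).astype(int)
    j = np.floor((points[:, 1] - g.y0) / g.cell_size).astype(int)
    ok = (i >= 0) & (i < g.nx) & (j >= 0) & (j < g.ny)
    inside = np.zeros(len(points), dtype=bool)
    inside[ok] = iso.cells[i[ok], j[ok]]
    return float(inside.mean())


def find_site(
    individual_isopleths: dict[str, Isopleth],
    representativeness: float,
    threshold_pct: float = 10.0,
    cell_size: float | None = None,
    colony_id: str = "",
    subset: str = "all",
    min_individuals: int = 8,
) -> KeyAreaEstimate:
    """Delineate the population-level key area from individual isopleths.

    On a common grid, each cell's value is
    (fraction of individuals whose isopleth covers the cell centre)
    × (representativeness / 100) × 100%, a scaled estimate of the
    percentage of the source population using the cell.  Cells at or above
    *threshold_pct* are dissolved into the key-area polygon; the area is
    their count × cell area.  An empty estimate (area 0) is a valid result.
    """
    inds = sorted(individual_isopleths)
    if len(inds) < min_individuals:
        raise ValueError(
            f"need >= {min_individuals} usable individuals, got {len(inds)}"
        )
    if not np.isfinite(representativeness):
        raise ValueError("representativeness unusable")
    geoms = {i: individual_isopleths[i].geometry() for i in inds}
    level = individual_isopleths[inds[0]].level
    if cell_size is None:
        cell_size = float(
            np.median([individual_isopleths[i].grid.cell_size for i in inds])
        )
    bounds = np.array([geoms[i].bounds for i in inds])
    x0, y0 = bounds[:, 0].min() - cell_size, bounds[:, 1].min() - cell_size
    x1, y1 = bounds[:, 2].max() + cell_size, bounds[:, 3].max() + cell_size
    nx = int(np.ceil((x1 - x0) / cell_size))
    ny = int(np.ceil((y1 - y0) / cell_size))
    xc = x0 + (np.arange(nx) + 0.5) * cell_size
    yc = y0 + (np.arange(ny) + 0.5) * cell_size
    xx, yy = np.meshgrid(xc, yc, indexing="ij")

    coverage = np.zeros((nx, ny))
    for i in inds:
        coverage += shapely.contains_xy(geoms[i], xx.ravel(), yy.ravel()).reshape(nx, ny)
    population_pct = coverage / len(inds) * (representativeness / 100.0) * 100.0

    mask = population_pct >= threshold_pct
    area = float(mask.sum() * cell_size**2)
    if not mask.any():
        logger.info(
            "find_site(%s/%s): no cell reached %.1f%% of the source population",
            colony_id, subset, threshold_pct,
        )
        poly = shapely.geometry.Polygon()
    else:
        from movekba.ud import _cells_to_polygon, UDGrid

        dummy = UDGrid(x0=x0, y0=y0, cell_size=cell_size, density=np.zeros((nx, ny)))
        poly = _cells_to_polygon(dummy, mask)
    return KeyAreaEstimate(
        colony_id=colony_id, subset=subset, level=level, area_km2=area,
        polygon=poly, population_pct=population_pct, grid_origin=(x0, y0),
        cell_size=cell_size, representativeness=representativeness,
        threshold_pct=threshold_pct,
    )


def compare_key_area_sizes(
    estimates: list[KeyAreaEstimate],
    exclusions: list[RepresentativenessResult] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (colony, subset, level, area, log10 area) table for modelling.

    Colonies excluded by the representativeness rules appear only in the
    second (exclusion-report) frame.
    """
    rows = [
        {
            "colony_id": e.colony_id,
            "subset": e.subset,
            "level": e.level,
            "area_km2": e.area_km2,
            "log10_area": np.log10(e.area_km2) if e.area_km2 > 0 else np.nan,
            "representativeness": e.representativeness,
        }
        for e in estimates
    ]
    excl_rows = [
        {
            "colony_id": r.colony_id,
            "subset": r.subset,
            "n_individuals": r.n_individuals,
            "representativeness": r.representativeness,
            "reason": r.reason,
        }
        for r in (exclusions or [])
        if not r.usable
    ]
    return pd.DataFrame(rows), pd.DataFrame(excl_rows)
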