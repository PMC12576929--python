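"""Capture of behaviour-specific core areas within the all-behaviour area.

For each individual and behaviour subset, the capture proportion x is the
fraction of the behaviour's isopleth that falls inside the individual's
all-behaviour isopleth at the same utilisation-distribution level.  Both
isopleths live on the same grid, so the intersection is an exact cell-set
operation.  Proportions are nudged off the boundary with
ẋ = (x(N−1) + 0.5)/N (N = number of records entering the regression) before
beta-regression modelling, which requires responses strictly inside (0, 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from movekba.ud import Isopleth

BEHAVIOUR_SUBSETS = ("resting", "foraging", "transiting", "sample")


def capture_proportion(
    behaviour_iso: Isopleth, all_iso: Isopleth, mode: str = "area"
) -> float:
    """Proportion of the behaviour isopleth captured by the all-behaviour one.

    mode="area" (default): area(behaviour ∩ all) / area(behaviour), exact on
    the shared cell grid.  mode="mass": the behaviour UD mass inside the
    all-behaviour isopleth divided by the mass inside its own isopleth —
    the alternative reading of "proportion of kernel density captured".
    """
    if behaviour_iso.level != all_iso.level:
        raise ValueError("isopleths must be at the same level")
    if behaviour_iso.cells.shape != all_iso.cells.shape:
        raise ValueError("isopleths must share a grid frame")
    b = behaviour_iso.cells
    if not b.any():
        raise ValueError("behaviour isopleth has zero area")
    if mode == "area":
        return float(np.logical_and(b, all_iso.cells).sum() / b.sum())
    if mode == "mass":
        dens = behaviour_iso.grid.density
        own = float(dens[b].sum())
        return float(dens[np.logical_and(b, all_iso.cells)].sum() / own)
    raise ValueError(f"unknown mode {mode!r}")


def transform_proportion(x, n: int):
    """Boundary-avoiding transform ẋ = (x(N−1) + 0.5)/N.

    Maps [0, 1] strictly into (0, 1); x = 0.5 is a fixed point for every N.
    """
    if n < 1:
        raise ValueError("sample size N must be >= 1")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = (x * (n - 1) + 0.5) / n
    return float(out) if out.ndim == 0 else out


def inverse_transform_proportion(x_dot, n: int):
    """Invert :func:`transform_proportion` (exact)."""
    x_dot = np.asarray(x_dot, dtype=float)
    out = (x_dot * n - 0.5) / (n - 1)
    return float(out) if out.ndim == 0 else out


def overlap_table(
    ud_sets: dict[str, dict[str, dict[float, Isopleth]]],
    colony_of: dict[str, str],
    level: float = 0.5,
    mode: str = "area",
) -> pd.DataFrame:
    """One capture record per individual × available behaviour subset.

    *ud_sets* maps individual_id → subset → level → Isopleth (the output of
    ``behaviour_ud_set`` per individual).  Adds the transformed proportion
    with dataset-level N = number of records.  Colony-weighted grand means
    (weights = individuals per colony) are available via
    :func:`grand_mean_capture`.
    """
    rows = []
    for ind, subsets in ud_sets.items():
        if "all" not in subsets or level not in subsets["all"]:
            continue
        all_iso = subsets["all"][level]
        for name in BEHAVIOUR_SUBSETS:
            if name not in subsets or level not in subsets[name]:
                continue
            x = capture_proportion(subsets[name][level], all_iso, mode=mode)
            rows.append(
                {
                    "individual_id": ind,
                    "colony_id": colony_of.get(ind, "all"),
                    "subset": name,
                    "level": level,
                    "capture": x,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["capture_transformed"] = transform_proportion(df["capture"].to_numpy(), len(df))
    return df


def grand_mean_capture(table: pd.DataFrame) -> pd.DataFrame:
    """Colony-weighted grand mean capture per subset.

    Colony means are weighted by the number of individuals contributing to
    that colony, mirroring colony-size-weighted reporting.
    """
    out = []
    for subset, sub in table.groupby("subset"):
        per_colony = sub.groupby("colony_id").agg(
            mean_capture=("capture", "mean"),
            n_individuals=("individual_id", "nunique"),
        )
        w = per_colony["n_individuals"].to_numpy(dtype=float)
        gm = float(np.average(per_colony["mean_capture"].to_numpy(), weights=w))
        out.append({"subset": subset, "grand_mean_capture": gm, "n_records": len(sub)})
    return pd.DataFrame(out)
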