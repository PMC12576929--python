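"""Shared fixtures: constructed geometries and simulated datasets.

Everything is generated programmatically with fixed seeds; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from movekba.ud import behaviour_ud_set


def corridor_individual(rng: np.random.Generator, angle: float):
    """One central-place individual with a clear spatial behaviour split.

    The colony sits at the origin; a foraging patch lies 25 km out along
    *angle*.  Foraging fixes cluster densely at the patch, resting fixes
    sit just beyond it, and transiting fixes are strung sparsely along the
    colony-patch corridor — the geometry that makes all-behaviour core
    areas under-represent transit corridors.
    """
    patch = 25.0 * np.array([np.cos(angle), np.sin(angle)])
    forage = patch + rng.normal(0, 1.5, (100, 2))
    rest = patch + np.array([2.0, 0.0]) + rng.normal(0, 1.0, (40, 2))
    ts = np.linspace(0.05, 0.95, 30)
    transit = np.concatenate(
        [np.outer(ts, patch), np.outer(ts[::-1], patch)]
    ) + rng.normal(0, 0.5, (60, 2))
    points = np.vstack([forage, rest, transit])
    states = np.concatenate([np.full(100, 1), np.full(40, 0), np.full(60, 2)])
    return points, states


@pytest.fixture(scope="session")
def corridor_colony():
    """Ten corridor individuals fanned over ±23°, with their UD sets.

    Returns (ud_sets, colony_of, locations, h): the inputs the overlap and
    key-area stages consume.
    """
    rng = np.random.default_rng(5)
    angles = np.linspace(-0.4, 0.4, 10)
    h = float(np.log(25.0))
    ud_sets, colony_of, locations = {}, {}, {}
    for i, a in enumerate(angles):
        pts, states = corridor_individual(rng, a)
        name = f"bird{i:02d}"
        ud_sets[name] = behaviour_ud_set(pts, states, h, seed=i, individual_id=name)
        colony_of[name] = "corridor_colony"
        locations[name] = pts
    return ud_sets, colony_of, locations, h
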