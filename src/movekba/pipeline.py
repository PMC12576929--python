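"""End-to-end orchestration: simulate → segment → classify → ud → overlap →
keyareas → stats, from a single config, with a reproducibility manifest.

Each stage writes tabular outputs into the run directory and records a
content hash in the manifest; a rerun with an identical config and seeds
produces byte-identical tables.  Stages whose outputs already exist with a
matching stage-config hash are reused rather than recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from movekba import hmm as hmm_mod
from movekba import synthetic, trips as trips_mod
from movekba.keyareas import (
    assess_representativeness,
    compare_key_area_sizes,
    find_site,
)
from movekba.overlap import grand_mean_capture, overlap_table
from movekba.stats import fit_beta_glmm, fit_lmm
from movekba.synthetic import STATE_NAMES
from movekba.tracks_io import ColonySite
from movekba.ud import DEFAULT_LEVELS, bandwidth_mag, behaviour_ud_set

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "classify", "ud", "overlap", "keyareas", "stats")
STAGE_DEPS = {
    "simulate": (),
    "segment": ("simulate",),
    "classify": ("segment",),
    "ud": ("classify",),
    "overlap": ("ud",),
    "keyareas": ("ud",),
    "stats": ("overlap", "keyareas"),
}


@dataclass
class RunConfig:
    output_dir: str = "run_output"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # generator
    n_colonies: int = 2
    n_individuals_per_colony: int = 10
    trips_per_individual: int = 2
    trip_length: int = 150
    # segmentation
    inner_buffer_km: float = 0.5
    return_buffer_km: float = 1.0
    min_return_min: float = 14.0
    min_trip_fixes: int = 5
    # behaviour classification
    hmm_restarts: int = 2
    hmm_maxiter: int = 500
    hmm_pooled: bool = False  # False: fit per colony (default)
    use_true_states: bool = False  # bypass fitting, decode with generating params
    # utilisation distributions
    levels: tuple[float, ...] = DEFAULT_LEVELS
    min_fixes_per_subset: int = 10
    # overlap
    overlap_level: float = 0.5
    overlap_mode: str = "area"
    # key areas
    threshold_pct: float = 10.0
    rep_iterations: int = 20
    keyarea_min_individuals: int = 8

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_config(config: RunConfig) -> list[str]:
    """All invariants checked; a non-empty issue list blocks run_pipeline."""
    issues = []
    for s in config.stages:
        if s not in STAGES:
            issues.append(f"unknown stage {s!r}")
    enabled = set(config.stages)
    for s in config.stages:
        for dep in STAGE_DEPS.get(s, ()):
            if dep not in enabled:
                issues.append(f"stage {s!r} requires stage {dep!r} to be enabled")
    for lv in config.levels:
        if not 0.0 < lv < 1.0:
            issues.append(f"utilisation level {lv} outside (0, 1)")
    if not 0.0 < config.overlap_level < 1.0:
        issues.append(f"overlap level {config.overlap_level} outside (0, 1)")
    if config.seed is None:
        issues.append("a seed is required (stochastic stages)")
    if config.inner_buffer_km <= 0 or config.return_buffer_km < config.inner_buffer_km:
        issues.append("need 0 < inner_buffer_km <= return_buffer_km")
    if config.threshold_pct <= 0 or config.threshold_pct > 100:
        issues.append("threshold_pct must be in (0, 100]")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_hash(config: RunConfig, stage: str) -> str:
    payload = json.dumps({"stage": stage, "config": config.to_dict()}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _colony_sites(config: RunConfig) -> tuple[ColonySite, ...]:
    return tuple(
        ColonySite(f"colony_{chr(65 + i)}", lon=-1.0 - 2.0 * i, lat=54.0)
        for i in range(config.n_colonies)
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; returns the manifest."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    old_manifest = {}
    if manifest_path.exists():
        old_manifest = json.loads(manifest_path.read_text())

    manifest = {"config": config.to_dict(), "stages": {}}
    state: dict = {}
    enabled = [s for s in STAGES if s in config.stages]
    try:
        for stage in enabled:
            t0 = time.time()
            shash = _stage_hash(config, stage)
            entry = {"stage_hash": shash}
            runner = globals()[f"_stage_{stage}"]
            cached = old_manifest.get("stages", {}).get(stage)
            outputs = runner(config, outdir, state,
                             reuse=bool(cached and cached.get("stage_hash") == shash))
            entry["outputs"] = {
                name: _sha256(outdir / name) for name in outputs
            }
            entry["wall_s"] = round(time.time() - t0, 3)
            manifest["stages"][stage] = entry
    except Exception as exc:  # record the failure point, skip downstream
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# --- stages ----------------------------------------------------------------


def _stage_simulate(config, outdir, state, reuse=False):
    cfg = synthetic.default_config(
        colony_sites=_colony_sites(config),
        n_individuals_per_colony=config.n_individuals_per_colony,
        trips_per_individual=config.trips_per_individual,
        trip_length=config.trip_length,
        seed=config.seed,
    )
    state["generator_config"] = cfg
    path = outdir / "simulated_tracks.csv"
    if reuse and path.exists():
        df = pd.read_csv(path, parse_dates=["timestamp"])
    else:
        df = synthetic.simulate_colony_trips(cfg)
        out = df.copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        out.to_csv(path, index=False, float_format="%.10g")
        df = pd.read_csv(path, parse_dates=["timestamp"])
    state["tracks"] = df
    return ["simulated_tracks.csv"]


def _stage_segment(config, outdir, state, reuse=False):
    tracks = state["tracks"]
    sites = {c.colony_id: c for c in _colony_sites(config)}
    all_trips = []
    for (ind, colony_id), grp in tracks.groupby(["individual_id", "colony_id"], sort=True):
        all_trips.extend(
            trips_mod.split_trips(
                grp.reset_index(drop=True), sites[colony_id],
                inner_buffer_km=config.inner_buffer_km,
                return_buffer_km=config.return_buffer_km,
                min_return_min=config.min_return_min,
                min_trip_fixes=config.min_trip_fixes,
            )
        )
    complete = trips_mod.filter_complete(all_trips)
    state["trips"] = complete
    tm = trips_mod.trips_to_frame(all_trips)
    tm.to_csv(outdir / "trip_metrics.csv", index=False, float_format="%.10g")
    return ["trip_metrics.csv"]


def _stage_classify(config, outdir, state, reuse=False):
    trips = state["trips"]
    series = {t.trip_id: hmm_mod.steps_and_turns(t.fixes, trip_id=t.trip_id)
              for t in trips if t.n_fixes >= 3}
    gen_params = hmm_mod.HMMParams.from_config(state["generator_config"])
    colony_of_trip = {t.trip_id: t.colony_id for t in trips}
    fitted: dict[str, hmm_mod.HMMParams] = {}
    params_out = {}
    if config.use_true_states:
        for colony in sorted({t.colony_id for t in trips}):
            fitted[colony] = gen_params
        params_out["mode"] = "generating parameters"
    else:
        groups = (
            {"pooled": list(series)} if config.hmm_pooled
            else {
                c: [tid for tid in series if colony_of_trip[tid] == c]
                for c in sorted({t.colony_id for t in trips})
            }
        )
        for gname, tids in groups.items():
            fit = hmm_mod.fit_hmm(
                [series[tid] for tid in tids], gen_params,
                n_restarts=config.hmm_restarts, seed=config.seed,
                maxiter=config.hmm_maxiter,
            )
            params_out[gname] = {
                "step_mean": fit.params.step_mean.tolist(),
                "step_sd": fit.params.step_sd.tolist(),
                "turn_mu": fit.params.turn_mu.tolist(),
                "turn_kappa": fit.params.turn_kappa.tolist(),
                "gamma": fit.params.gamma.tolist(),
                "delta": fit.params.delta.tolist(),
                "loglik": fit.loglik,
                "converged": fit.converged,
                "seed": config.seed,
            }
            for c in (sorted({t.colony_id for t in trips}) if config.hmm_pooled else [gname]):
                fitted[c] = fit.params
    decoded = {}
    rows = []
    for t in trips:
        if t.trip_id not in series:
            continue
        d = hmm_mod.viterbi_decode(fitted[t.colony_id], series[t.trip_id])
        decoded[t.trip_id] = d
        fx = t.fixes.iloc[: len(d.states)]
        for (_, r), s in zip(fx.iterrows(), d.states):
            rows.append(
                {
                    "trip_id": t.trip_id,
                    "individual_id": t.individual_id,
                    "colony_id": t.colony_id,
                    "x": r["x"],
                    "y": r["y"],
                    "state": int(s),
                    "state_name": STATE_NAMES[s],
                }
            )
    state["decoded"] = decoded
    state["classified"] = pd.DataFrame(rows)
    state["classified"].to_csv(outdir / "fixes_classified.csv", index=False,
                               float_format="%.10g")
    (outdir / "hmm_params.json").write_text(json.dumps(params_out, indent=2, sort_keys=True))
    return ["fixes_classified.csv", "hmm_params.json"]


def _stage_ud(config, outdir, state, reuse=False):
    classified = state["classified"]
    trips = state["trips"]
    # per-colony bandwidth from complete-trip foraging ranges
    h_colony = {}
    for colony, grp in trips_mod.trips_to_frame(trips).groupby("colony_id"):
        h_colony[colony] = bandwidth_mag(grp["max_distance_km"].to_numpy())
    ud_sets = {}
    colony_of = {}
    rows = []
    for (ind, colony), grp in classified.groupby(["individual_id", "colony_id"], sort=True):
        pts = grp[["x", "y"]].to_numpy()
        states = grp["state"].to_numpy()
        sets = behaviour_ud_set(
            pts, states, h_colony[colony], levels=config.levels,
            min_fixes=config.min_fixes_per_subset,
            seed=config.seed + (zlib.crc32(ind.encode()) % 100000), individual_id=ind,
        )
        if "all" not in sets:
            continue
        ud_sets[ind] = sets
        colony_of[ind] = colony
        for subset, by_level in sets.items():
            for lv, iso in by_level.items():
                rows.append(
                    {
                        "individual_id": ind,
                        "colony_id": colony,
                        "subset": subset,
                        "level": lv,
                        "area_km2": iso.area_km2,
                        "h_km": h_colony[colony],
                    }
                )
    state["ud_sets"] = ud_sets
    state["colony_of"] = colony_of
    pd.DataFrame(rows).to_csv(outdir / "ud_isopleths.csv", index=False,
                              float_format="%.10g")
    return ["ud_isopleths.csv"]


def _stage_overlap(config, outdir, state, reuse=False):
    table = overlap_table(
        state["ud_sets"], state["colony_of"],
        level=config.overlap_level, mode=config.overlap_mode,
    )
    state["overlap"] = table
    table.to_csv(outdir / "overlap_records.csv", index=False, float_format="%.10g")
    gm = grand_mean_capture(table) if len(table) else pd.DataFrame()
    gm.to_csv(outdir / "overlap_grand_means.csv", index=False, float_format="%.10g")
    return ["overlap_records.csv", "overlap_grand_means.csv"]


def _stage_keyareas(config, outdir, state, reuse=False):
    ud_sets = state["ud_sets"]
    colony_of = state["colony_of"]
    classified = state["classified"]
    estimates, reps = [], []
    level = config.overlap_level
    for colony in sorted(set(colony_of.values())):
        inds = [i for i, c in colony_of.items() if c == colony]
        for subset in ("all", "sample", "resting", "foraging", "transiting"):
            isos = {
                i: ud_sets[i][subset][level]
                for i in inds
                if subset in ud_sets[i] and level in ud_sets[i][subset]
            }
            if not isos:
                continue
            loc_sets = {}
            for i in inds:
                grp = classified[classified["individual_id"] == i]
                if subset == "all":
                    sel = grp
                elif subset == "sample":
                    sel = grp  # control inclusion uses all locations
                else:
                    sel = grp[grp["state_name"] == subset]
                if len(sel) >= 3:
                    loc_sets[i] = sel[["x", "y"]].to_numpy()
            h = ud_sets[inds[0]]["all"][level].grid.cell_size * 10.0
            rep = assess_representativeness(
                loc_sets, h, level=level, n_iterations=config.rep_iterations,
                seed=config.seed, colony_id=colony, subset=subset,
            )
            reps.append(rep)
            if not rep.usable or len(isos) < config.keyarea_min_individuals:
                continue
            estimates.append(
                find_site(
                    isos, rep.representativeness,
                    threshold_pct=config.threshold_pct,
                    colony_id=colony, subset=subset,
                    min_individuals=config.keyarea_min_individuals,
                )
            )
    table, excl = compare_key_area_sizes(estimates, reps)
    state["keyareas"] = table
    table.to_csv(outdir / "key_areas.csv", index=False, float_format="%.10g")
    excl.to_csv(outdir / "key_area_exclusions.csv", index=False, float_format="%.10g")
    return ["key_areas.csv", "key_area_exclusions.csv"]


def _stage_stats(config, outdir, state, reuse=False):
    results = {}
    overlap = state.get("overlap")
    if overlap is not None and len(overlap) and overlap["colony_id"].nunique() >= 2:
        fit = fit_beta_glmm(overlap)
        results["capture_beta_glmm"] = {
            "subsets": fit.subsets,
            "beta_logit": fit.beta.tolist(),
            "phi": fit.phi,
            "random_sd": fit.random_sd,
            "means": fit.means.to_dict(orient="records"),
            "loglik": fit.loglik,
            "converged": fit.converged,
        }
    areas = state.get("keyareas")
    if areas is not None and len(areas) and areas["colony_id"].nunique() >= 2:
        lmm = fit_lmm(areas)
        results["area_lmm"] = {
            "terms": lmm.terms,
            "beta": lmm.beta.tolist(),
            "conf_int": lmm.conf_int.tolist(),
            "random_var": lmm.random_var,
            "resid_var": lmm.resid_var,
            "r2_marginal": lmm.r2_marginal,
            "r2_conditional": lmm.r2_conditional,
        }
    (outdir / "stats_fits.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    return ["stats_fits.json"]
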