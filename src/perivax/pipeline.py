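"""Scenario orchestration: configuration, staged execution and manifests.

A scenario bundles a geometry, one or more cohorts (each possibly replicated
over simulated animals) and a set of analysis toggles. ``run_scenario``
executes simulate → render → detect/link → metrics → direction → flow →
density as enabled, writes every product as CSV/TIFF under the output
directory, and records a manifest. Reruns with the same config and seed are
numerically identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agents import simulate_cohort
from .density import RoiSpec, count_in_roi, density_change
from .detect import detect_stack, link_tracks
from .direction import classify_table, fraction_toward
from .flow import analyze_stack
from .geometry import build_geometry
from .motility import cohort_summary, track_metrics
from .render import render_stack, write_fixture
from .scenarios import preset_cohort

log = logging.getLogger("perivax")

DEFAULT_ANALYSES = {"metrics": True, "direction": True, "flow": False,
                    "density": False, "detect_link": False, "render": False}


def load_config(path) -> dict:
    with open(path) as f:
        text = f.read()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        return yaml.safe_load(text)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def run_scenario(config: dict, out_dir, seed: int = None) -> dict:
    """Execute one scenario; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    analyses = {**DEFAULT_ANALYSES, **config.get("analyses", {})}
    manifest = {"config": config, "config_hash": _config_hash(config),
                "version": __version__, "seed": seed, "stages": {}, "outputs": {}}

    def stage(name, fn):
        t0 = time.time()
        try:
            fn()
            manifest["stages"][name] = {"status": "ok",
                                        "seconds": round(time.time() - t0, 3)}
            return True
        except Exception as exc:  # record and stop downstream stages
            log.exception("stage %s failed", name)
            manifest["stages"][name] = {"status": "failed", "error": str(exc),
                                        "seconds": round(time.time() - t0, 3)}
            return False

    state = {}

    def do_simulate():
        geo_cfg = dict(config.get("geometry", {}))
        geo_cfg.setdefault("seed", seed)
        geometry = build_geometry(**geo_cfg)
        tables = []
        id_offset = 0
        for ci, cspec in enumerate(config.get("cohorts", [])):
            cspec = dict(cspec)
            n_animals = int(cspec.pop("animals", 1))
            name = cspec.pop("cohort", cspec.get("preset", f"cohort{ci}"))
            for a in range(n_animals):
                cfg = preset_cohort(
                    cspec.get("preset", "control"),
                    n_track_guided=int(cspec.get("n_track_guided", 60)),
                    seed=seed * 7919 + ci * 101 + a,
                    n_frames=int(cspec.get("n_frames", 40)),
                    frame_interval=float(cspec.get("frame_interval", 20.0)),
                    cohort=name,
                    lateral_sigma=float(cspec.get("lateral_sigma", 2.0)),
                    bias_q=float(cspec.get("bias_q", 0.95)),
                )
                tab = simulate_cohort(geometry, cfg)
                tab["animal"] = f"{name}-m{a + 1}"
                tab["cell_id"] = tab["cell_id"] + id_offset  # unique per movie
                id_offset += 1_000_000
                tables.append(tab)
        tracks = pd.concat(tables, ignore_index=True)
        p = out / "tracks.csv"
        tracks.to_csv(p, index=False)
        manifest["outputs"]["tracks"] = str(p)
        state["geometry"] = geometry
        state["tracks"] = tracks

    if not stage("simulate", do_simulate):
        _write_manifest(manifest, out)
        return manifest

    if analyses["render"] or analyses["detect_link"] or analyses["flow"]:
        def do_render():
            render_cfg = config.get("render", {})
            state["stacks"] = {}
            for (cohort, animal), g in state["tracks"].groupby(["cohort", "animal"]):
                stk = render_stack(g, state["geometry"], seed=seed,
                                   **render_cfg)
                state["stacks"][(cohort, animal)] = stk
            # persist one fixture per scenario for inspection
            (c0, a0), stk0 = next(iter(state["stacks"].items()))
            paths = write_fixture(state["geometry"],
                                  state["tracks"], stk0, out / "fixture",
                                  config=config)
            manifest["outputs"]["fixture"] = paths
        if not stage("render", do_render):
            _write_manifest(manifest, out)
            return manifest

    if analyses["detect_link"]:
        def do_detect_link():
            linked = []
            for (cohort, animal), stk in state["stacks"].items():
                det = detect_stack(stk)
                lt = link_tracks(det, stk.frame_interval, cohort=cohort)
                lt["animal"] = animal
                linked.append(lt)
            state["linked"] = pd.concat(linked, ignore_index=True)
            p = out / "linked_tracks.csv"
            state["linked"].to_csv(p, index=False)
            manifest["outputs"]["linked_tracks"] = str(p)
        if not stage("detect_link", do_detect_link):
            _write_manifest(manifest, out)
            return manifest

    if analyses["metrics"]:
        def do_metrics():
            src = state.get("linked", state["tracks"])
            rec = track_metrics(src)
            rec.to_csv(out / "track_metrics.csv", index=False)
            summ = cohort_summary(rec, group_by="animal")
            per_animal = summ.attrs["per_group"].reset_index()
            per_animal.to_csv(out / "per_animal_metrics.csv", index=False)
            summ.to_csv(out / "metrics_summary.csv", index=False)
            manifest["outputs"]["track_metrics"] = str(out / "track_metrics.csv")
            manifest["outputs"]["per_animal_metrics"] = str(out / "per_animal_metrics.csv")
            manifest["outputs"]["metrics_summary"] = str(out / "metrics_summary.csv")
        stage("metrics", do_metrics)

    if analyses["direction"]:
        def do_direction():
            res = classify_table(state["tracks"], state["geometry"])
            res.to_csv(out / "directionality.csv", index=False)
            frac = fraction_toward(res, group_by="animal")
            frac.to_csv(out / "fraction_toward.csv", index=False)
            manifest["outputs"]["directionality"] = str(out / "directionality.csv")
            manifest["outputs"]["fraction_toward"] = str(out / "fraction_toward.csv")
            manifest["summary_fraction_toward"] = frac.attrs["mean"]
        stage("direction", do_direction)

    if analyses["flow"]:
        def do_flow():
            rows = []
            for (cohort, animal), stk in state["stacks"].items():
                stat = analyze_stack(stk, state["geometry"].vessel_masks,
                                     state["geometry"].t_zone_center)
                rows.append({"cohort": cohort, "animal": animal,
                             "n_in_vessel": stat.n_in_vessel,
                             "n_positive": stat.n_positive,
                             "fraction": stat.fraction})
            pd.DataFrame(rows).to_csv(out / "flow_statistic.csv", index=False)
            manifest["outputs"]["flow_statistic"] = str(out / "flow_statistic.csv")
        stage("flow", do_flow)

    if analyses["density"]:
        def do_density():
            geometry = state["geometry"]
            tracks = state["tracks"]
            slab = float(config.get("slab_depth", 60.0))
            frames = sorted(tracks["frame"].unique())
            f0, f1 = frames[0], frames[-1]
            recs0, recs1 = [], []
            for i in range(len(geometry.tracks)):
                roi = RoiSpec(geometry.track_polygon(i), slab_depth=slab, roi_id=i)
                p0 = tracks[tracks["frame"] == f0][["x_um", "y_um"]].to_numpy()
                p1 = tracks[tracks["frame"] == f1][["x_um", "y_um"]].to_numpy()
                recs0.append(count_in_roi(p0, roi, timepoint=f0))
                recs1.append(count_in_roi(p1, roi, timepoint=f1))
            change = density_change(recs0, recs1)
            change.to_csv(out / "density_change.csv", index=False)
            manifest["outputs"]["density_change"] = str(out / "density_change.csv")
        stage("density", do_density)

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)


def compare_scenarios(manifest_a: dict, manifest_b: dict,
                      metric: str = "mean_velocity") -> pd.DataFrame:
    """Cohort-level comparison of one metric between two runs.

    Reads the per-animal metric tables of both manifests and reports the
    per-animal values, cohort means, difference, ratio and percent change
    (b relative to a).
    """
    def load(man):
        path = man["outputs"].get("per_animal_metrics")
        if path is None:
            raise KeyError("manifest lacks per-animal metrics")
        df = pd.read_csv(path)
        if metric not in df.columns:
            raise KeyError(f"metric {metric!r} not present")
        return df

    a, b = load(manifest_a), load(manifest_b)
    mean_a, mean_b = a[metric].mean(), b[metric].mean()
    sd_a = a[metric].std(ddof=1) if len(a) > 1 else 0.0
    sd_b = b[metric].std(ddof=1) if len(b) > 1 else 0.0
    return pd.DataFrame([{
        "metric": metric,
        "mean_a": mean_a, "sd_a": sd_a, "n_a": len(a),
        "mean_b": mean_b, "sd_b": sd_b, "n_b": len(b),
        "difference": mean_b - mean_a,
        "ratio": mean_b / mean_a if mean_a else np.nan,
        "percent_change": 100.0 * (mean_b - mean_a) / mean_a if mean_a else np.nan,
    }])
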