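"""Binary toward/away T-zone classification of tracks with branch-point and
dead-band exclusions, and per-animal fractions.

A track counts as moving toward the T zone when its end point is closer to
the T-zone centre than its start point by more than a dead band ε, and away
when it is farther by more than ε. Tracks that mostly sit near a junction of
two perivascular tracks, or that are too short, are excluded from the
denominator — junction regions are crowded and cell behaviour there is not
reliably classifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Geometry


@dataclass
class DirectionalityResult:
    cell_id: object
    d_start: float
    d_end: float
    klass: str              # 'toward' | 'away' | 'excluded'
    exclusion_reason: str   # 'none' | 'dead_band' | 'branch_point' | 'short_track'


def classify_track(t_s: np.ndarray, xy: np.ndarray, geometry: Geometry,
                   cell_id=0, epsilon: float = 5.0, branch_radius: float = 20.0,
                   min_duration: float = 10.0) -> DirectionalityResult:
    """Classify one track from its start/end distances to the T-zone centre."""
    if geometry.t_zone_center is None:
        raise ValueError("geometry lacks a T-zone centre")
    order = np.argsort(t_s)
    xy = np.asarray(xy, dtype=float)[order]
    t_s = np.asarray(t_s, dtype=float)[order]
    d = geometry.distance_to_tzone_center(xy)
    d_start, d_end = float(d[0]), float(d[-1])

    duration_min = (t_s[-1] - t_s[0]) / 60.0
    if duration_min < min_duration:
        return DirectionalityResult(cell_id, d_start, d_end, "excluded", "short_track")

    junctions = geometry.branch_junctions
    if len(junctions):
        near = np.zeros(len(xy), dtype=bool)
        for j in junctions:
            near |= np.linalg.norm(xy - j, axis=1) <= branch_radius
        if near.mean() > 0.5:
            return DirectionalityResult(cell_id, d_start, d_end, "excluded", "branch_point")

    if d_end < d_start - epsilon:
        return DirectionalityResult(cell_id, d_start, d_end, "toward", "none")
    if d_end > d_start + epsilon:
        return DirectionalityResult(cell_id, d_start, d_end, "away", "none")
    return DirectionalityResult(cell_id, d_start, d_end, "excluded", "dead_band")


def classify_table(table: pd.DataFrame, geometry: Geometry, epsilon: float = 5.0,
                   branch_radius: float = 20.0, min_duration: float = 10.0) -> pd.DataFrame:
    """Classify every track in a table; carries cohort/animal labels through."""
    rows = []
    for cid, g in table.groupby("cell_id", sort=True):
        r = classify_track(g["t_s"].to_numpy(), g[["x_um", "y_um"]].to_numpy(),
                           geometry, cell_id=cid, epsilon=epsilon,
                           branch_radius=branch_radius, min_duration=min_duration)
        row = {"cell_id": cid, "d_start": r.d_start, "d_end": r.d_end,
               "class": r.klass, "exclusion_reason": r.exclusion_reason}
        for extra in ("cohort", "animal"):
            if extra in g.columns:
                row[extra] = g[extra].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def fraction_toward(results: pd.DataFrame, group_by: str = "animal") -> pd.DataFrame:
    """Per-animal fraction toward = toward / (toward + away); excluded tracks
    leave the denominator. Animals with no classified track are omitted with
    a warning. The across-animal mean and SD are stored in ``attrs``."""
    per = []
    group_col = group_by if group_by in results.columns else None
    groups = results.groupby(group_col) if group_col else [("all", results)]
    for gid, g in groups:
        n_toward = int((g["class"] == "toward").sum())
        n_away = int((g["class"] == "away").sum())
        n = n_toward + n_away
        if n == 0:
            warnings.warn(f"group {gid!r}: no classified tracks, omitted")
            continue
        per.append({group_by: gid, "n_toward": n_toward, "n_away": n_away,
                    "fraction_toward": n_toward / n})
    out = pd.DataFrame(per, columns=[group_by, "n_toward", "n_away", "fraction_toward"])
    vals = out["fraction_toward"].to_numpy()
    out.attrs["mean"] = float(np.mean(vals)) if len(vals) else float("nan")
    out.attrs["sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return out
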