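"""Per-track motility metrics: mean velocity (path length / duration),
straightness (net displacement / path length), displacement-vs-√time curves
and per-animal summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

METRIC_COLUMNS = ["cell_id", "mean_velocity", "straightness", "duration",
                  "path_length", "net_displacement", "excluded"]


def metrics_from_arrays(t_s: np.ndarray, xy: np.ndarray) -> dict:
    """Metrics of a single track given times (s) and positions (µm)."""
    order = np.argsort(t_s)
    t_s = np.asarray(t_s, dtype=float)[order]
    xy = np.asarray(xy, dtype=float)[order]
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    path = float(steps.sum())
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    duration_min = (t_s[-1] - t_s[0]) / 60.0
    velocity = path / duration_min if duration_min > 0 else 0.0
    straightness = net / path if path > 0 else 0.0
    return {
        "mean_velocity": velocity,
        "straightness": min(straightness, 1.0),
        "duration": duration_min,
        "path_length": path,
        "net_displacement": net,
    }


def track_metrics(table: pd.DataFrame, min_duration: float = 10.0) -> pd.DataFrame:
    """Compute per-cell motility metrics from a long-format track table.

    Tracks shorter than ``min_duration`` (minutes) are kept in the output but
    flagged ``excluded=True`` rather than raising.
    """
    records = []
    for cid, g in table.groupby("cell_id", sort=True):
        m = metrics_from_arrays(g["t_s"].to_numpy(), g[["x_um", "y_um"]].to_numpy())
        m["cell_id"] = cid
        m["excluded"] = m["duration"] < min_duration
        records.append(m)
    out = pd.DataFrame(records, columns=METRIC_COLUMNS)
    for extra in ("cohort", "animal"):
        if extra in table.columns:
            out = out.merge(table.groupby("cell_id", sort=True)[extra].first(),
                            on="cell_id")
    return out


@dataclass
class DisplacementCurve:
    sqrt_t: np.ndarray              # min^0.5, starts at 0
    mean_displacement: np.ndarray   # µm, starts at 0
    motility_coefficient: float     # µm / min^0.5, through-origin LS slope


def displacement_curve(table: pd.DataFrame, horizon: float = 10.0) -> DisplacementCurve:
    """Mean displacement |x(t+τ) − x(t)| versus √τ up to ``horizon`` minutes.

    Averages over all tracks and all start offsets (overlapping windows).
    The motility coefficient is the least-squares slope of the line through
    the origin, the standard diffusive summary for lymphocyte motility.
    Raises ValueError when no track spans the horizon.
    """
    groups = []
    dt = None
    for _, g in table.groupby("cell_id"):
        g = g.sort_values("frame")
        t = g["t_s"].to_numpy()
        if len(t) < 2:
            continue
        step = np.diff(t).mean() / 60.0
        dt = step if dt is None else dt
        if (t[-1] - t[0]) / 60.0 >= horizon:
            groups.append(g[["x_um", "y_um"]].to_numpy())
    if not groups:
        raise ValueError(f"no track spans the {horizon} min horizon")

    n_lags = int(round(horizon / dt))
    lags = np.arange(1, n_lags + 1)
    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=int)
    for xy in groups:
        T = len(xy)
        for i, lag in enumerate(lags):
            if lag >= T:
                break
            d = np.linalg.norm(xy[lag:] - xy[:-lag], axis=1)
            sums[i] += d.sum()
            counts[i] += len(d)
    valid = counts > 0
    tau = lags[valid] * dt
    mean_disp = sums[valid] / counts[valid]
    sqrt_t = np.concatenate([[0.0], np.sqrt(tau)])
    disp = np.concatenate([[0.0], mean_disp])
    slope = float(np.sum(sqrt_t * disp) / np.sum(sqrt_t**2))
    return DisplacementCurve(sqrt_t=sqrt_t, mean_displacement=disp,
                             motility_coefficient=slope)


def cohort_summary(records: pd.DataFrame, group_by: str = "animal",
                   metrics=("mean_velocity", "straightness")) -> pd.DataFrame:
    """Per-group (typically per-animal) unweighted means, then across-group
    mean, SD and SEM for each metric. Empty groups are dropped."""
    usable = records[~records.get("excluded", False)] if "excluded" in records else records
    per_group = usable.groupby(group_by)[list(metrics)].mean()
    per_group = per_group.dropna(how="all")
    rows = []
    for m in metrics:
        vals = per_group[m].dropna().to_numpy()
        n = len(vals)
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        rows.append({"metric": m, "n_groups": n,
                     "mean": float(np.mean(vals)) if n else np.nan,
                     "sd": sd, "sem": sd / np.sqrt(n) if n else np.nan})
    summary = pd.DataFrame(rows)
    summary.attrs["per_group"] = per_group
    return summary
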