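"""Ready-made study scenarios: geometries and cohorts that mirror the
experimental designs the analysis pipeline is meant to quantify."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agents import AgentParams, CohortConfig, default_params, simulate_cohort
from .geometry import Geometry


def straight_track_geometry(field_size=(1000.0, 1000.0), track_length: float = 700.0,
                            t_zone_radius: float = 150.0, track_half_width: float = 15.0,
                            pixel_size: float = 2.0, t_zone_center=None) -> Geometry:
    """One horizontal track running leftward into a T zone.

    The track ends on the disc perimeter; its distal end sits toward the
    right edge of the field. Useful for controlled directionality tests.
    Pass ``t_zone_center`` left of centre to fit a longer corridor.
    """
    w, h = field_size
    center = (np.array([w / 2.0, h / 2.0]) if t_zone_center is None
              else np.asarray(t_zone_center, dtype=float))
    x_end = center[0] + t_zone_radius           # T-zone end (on the perimeter)
    x_start = min(x_end + track_length, w - 2 * track_half_width)
    xs = np.linspace(x_start, x_end, 8)
    verts = np.stack([xs, np.full_like(xs, center[1])], axis=1)
    return Geometry(t_zone_center=center, t_zone_radius=t_zone_radius,
                    tracks=[verts], track_half_width=track_half_width,
                    field_size=tuple(map(float, field_size)), pixel_size=pixel_size)


def simulate_isotropic_in_vessel(geometry: Geometry, n_cells: int = 150,
                                 speed_mean: float = 10.0, speed_sd: float = 2.0,
                                 persistence: float = 0.0, n_frames: int = 30,
                                 frame_interval: float = 20.0, seed: int = 0,
                                 cohort: str = "isotropic") -> pd.DataFrame:
    """Cells walking inside the (straight, axis-aligned) vessel corridor of
    ``geometry`` with uniformly random directions — the directional null.

    By default every step takes a fresh uniform heading (fully isotropic
    motion, so per-movie net flux stays small); ``persistence`` > 0 instead
    gives a persistent walk. The corridor walls reflect, keeping along-axis
    motion symmetric by construction. Requires the single straight track
    produced by :func:`straight_track_geometry`.
    """
    verts = geometry.tracks[0]
    y0 = verts[0, 1]
    x_lo, x_hi = sorted((verts[0, 0], verts[-1, 0]))
    hw = geometry.track_half_width * 0.9   # keep blobs inside the mask
    dt_min = frame_interval / 60.0

    rows = []
    t = np.arange(n_frames)
    for cid in range(n_cells):
        rng = np.random.default_rng([int(seed), cid])
        pos = np.empty((n_frames, 2))
        pos[0] = (rng.uniform(x_lo, x_hi), rng.uniform(y0 - hw, y0 + hw))
        speed = max(0.0, rng.normal(speed_mean, speed_sd))
        th = rng.uniform(0, 2 * np.pi)
        h = np.array([np.cos(th), np.sin(th)])
        noise = rng.uniform(0, 2 * np.pi, n_frames - 1)
        for k in range(n_frames - 1):
            u = np.array([np.cos(noise[k]), np.sin(noise[k])])
            h = persistence * h + (1.0 - persistence) * u
            h /= max(np.linalg.norm(h), 1e-12)
            p = pos[k] + speed * dt_min * h
            # mirror-reflect at the corridor walls
            if p[0] < x_lo or p[0] > x_hi:
                p[0] = np.clip(2 * (x_lo if p[0] < x_lo else x_hi) - p[0], x_lo, x_hi)
                h[0] = -h[0]
            if p[1] < y0 - hw or p[1] > y0 + hw:
                wall = y0 - hw if p[1] < y0 - hw else y0 + hw
                p[1] = np.clip(2 * wall - p[1], y0 - hw, y0 + hw)
                h[1] = -h[1]
            pos[k + 1] = p
        rows.append(pd.DataFrame({
            "cell_id": cid, "frame": t, "t_s": t * frame_interval,
            "x_um": pos[:, 0], "y_um": pos[:, 1], "cohort": cohort,
            "behavior": "isotropic", "compartment": "track",
        }))
    return pd.concat(rows, ignore_index=True)


def preset_cohort(preset: str, n_track_guided: int = 60, seed: int = 0,
                  n_frames: int = 40, frame_interval: float = 20.0,
                  cohort: str = None, lateral_sigma: float = 2.0,
                  bias_q: float = 0.95, **param_overrides) -> CohortConfig:
    """Cohort config for one simulated animal under a perturbation preset."""
    params = default_params()
    tg = params["track_guided"]
    tg.lateral_sigma = lateral_sigma
    tg.bias_q = bias_q
    for k, v in param_overrides.items():
        setattr(tg, k, v)
    return CohortConfig(
        n_cells={"track_guided": n_track_guided},
        params=params, preset=preset, n_frames=n_frames,
        frame_interval=frame_interval, seed=seed,
        cohort=cohort or preset,
    )


def simulate_animals(geometry: Geometry, preset: str, n_animals: int = 5,
                     n_track_guided: int = 60, seed: int = 0,
                     **cohort_kwargs) -> pd.DataFrame:
    """Simulate ``n_animals`` independent cohorts and tag each with an animal id."""
    tables = []
    for a in range(n_animals):
        cfg = preset_cohort(preset, n_track_guided=n_track_guided,
                            seed=int(seed) * 1009 + a, **cohort_kwargs)
        tab = simulate_cohort(geometry, cfg)
        tab["animal"] = f"m{a + 1}"
        tab["cell_id"] = tab["cell_id"] + a * 1_000_000  # unique across animals
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)
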