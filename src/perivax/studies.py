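"""End-to-end study definitions: the fixed scenarios whose summary numbers
the pipeline is designed to reproduce.

Each function simulates its inputs from scratch, runs the relevant pipeline
stages, and returns the summary statistic. All randomness derives from the
single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .agents import simulate_cohort
from .density import RoiSpec, count_in_roi, density_change
from .detect import detect_stack, link_tracks
from .direction import classify_table, fraction_toward
from .flow import analyze_stack
from .geometry import build_geometry
from .motility import track_metrics
from .render import render_stack
from .scenarios import (preset_cohort, simulate_animals,
                        simulate_isotropic_in_vessel, straight_track_geometry)


def flow_geometry():
    """Single straight corridor at 1 µm/px on a 1000 µm field.

    The T zone sits near the left edge so a 650 µm corridor fits with its
    distal cap well away from the image border (flow estimates degrade
    there); half-width 25 µm yields ~300 in-vessel superpixels at the
    default ~10,000-superpixel grid.
    """
    return straight_track_geometry(pixel_size=1.0, t_zone_center=(120.0, 500.0),
                                   track_half_width=25.0, track_length=650.0)


def spread_geometry(seed: int = 2):
    """Large field with many tracks so 200 rendered cells stay resolvable."""
    return build_geometry(field_size=(2000, 2000), n_tracks=14,
                          track_length=(400, 650), seed=seed)


def null_flow_study(seed: int, n_seeds: int = 20, n_cells: int = 150,
                    n_frames: int = 30):
    """Isotropic in-vessel motion rendered and measured by the superpixel
    projection statistic, one fraction per seed.

    Returns (per-seed fractions, total in-vessel superpixels).
    """
    geo = flow_geometry()
    fractions = []
    total_n = 0
    for k in range(n_seeds):
        s = (int(seed) * 1009 + k) % (2**31 - 1)
        tab = simulate_isotropic_in_vessel(geo, n_cells=n_cells,
                                           n_frames=n_frames, seed=s)
        stk = render_stack(tab, geo, seed=s + 1, texture_sd=10.0)
        stat = analyze_stack(stk, geo.vessel_masks, geo.t_zone_center)
        fractions.append(stat.fraction)
        total_n += stat.n_in_vessel
    return np.array(fractions), total_n


def strong_bias_direction_study(seed: int, n_animals: int = 5,
                                n_cells: int = 60, n_frames: int = 40):
    """Default strong-bias preset classified by the start/end rule.

    Returns (mean per-animal fraction toward in percent, n classified tracks).
    """
    geo = build_geometry(seed=int(seed) % (2**31 - 1))
    tab = simulate_animals(geo, "control", n_animals=n_animals,
                           n_track_guided=n_cells, seed=seed, n_frames=n_frames)
    res = classify_table(tab, geo, epsilon=5.0, min_duration=10.0)
    frac = fraction_toward(res, group_by="animal")
    n_classified = int((res["class"] != "excluded").sum())
    return 100.0 * frac.attrs["mean"], n_classified


def integrin_block_study(seed: int, n_cells: int = 200, n_frames: int = 40):
    """Percent reduction in mean track velocity of the integrin-blockade
    cohort relative to control, measured end-to-end through rendering,
    detection, greedy linking and track metrics.

    Returns (percent reduction, cells per cohort).
    """
    geo = spread_geometry(seed=int(seed) % (2**31 - 1))
    velocity = {}
    for preset in ("control", "integrin_block"):
        cfg = preset_cohort(preset, n_track_guided=n_cells,
                            seed=int(seed) * 101 + 17, n_frames=n_frames)
        tab = simulate_cohort(geo, cfg)
        stk = render_stack(tab, geo, seed=int(seed) * 101 + 29)
        linked = link_tracks(detect_stack(stk), stk.frame_interval)
        rec = track_metrics(linked)
        velocity[preset] = rec[~rec.excluded].mean_velocity.mean()
    reduction = 100.0 * (1.0 - velocity["integrin_block"] / velocity["control"])
    return reduction, n_cells


def lps_density_study(seed: int, n_rois: int = 20, cells_per_roi: int = 60,
                      n_frames: int = 40):
    """LPS detachment measured by the fixed-ROI density-change operation.

    Each replicate is one straight-track corridor ROI holding
    ``cells_per_roi`` track-associated cells; the LPS preset detaches each
    with the preset probability after the t0 snapshot. Returns
    (mean percent loss across ROIs, total cells at t0).
    """
    geo = straight_track_geometry()
    roi = RoiSpec(geo.track_polygon(0), roi_id=0)
    recs0, recs1 = [], []
    for r in range(n_rois):
        cfg = preset_cohort("lps", n_track_guided=cells_per_roi,
                            seed=int(seed) * 503 + r, n_frames=n_frames)
        tab = simulate_cohort(geo, cfg)
        f1 = int(tab.frame.max())
        p0 = tab[tab.frame == 0][["x_um", "y_um"]].to_numpy()
        p1 = tab[tab.frame == f1][["x_um", "y_um"]].to_numpy()
        rec0 = count_in_roi(p0, roi, timepoint=0)
        rec1 = count_in_roi(p1, roi, timepoint=f1)
        rec0.roi_id = rec1.roi_id = r
        recs0.append(rec0)
        recs1.append(rec1)
    change = density_change(recs0, recs1)
    n0 = sum(r.count for r in recs0)
    return float(change.percent_loss.mean()), n0
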