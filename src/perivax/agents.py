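"""Agent-based simulation of compartmentalised T cell migration.

Four behavioural phenotypes are modelled, matching what intravital imaging
of the spleen shows:

``track_guided``
    Cells latched onto a perivascular track polyline. Each frame they step
    an arc length of speed × Δt along the track, toward the T zone with
    probability ``bias_q`` and away with 1 − ``bias_q``, plus a lateral
    Gaussian offset clipped at the corridor half-width. At the T-zone end
    they detach into the disc and continue as persistent walkers (control),
    or are reflected if T-zone entry is forbidden (CCR7 knockout).
``tzone_walker``
    Persistent random walk confined to the T-zone disc.
``redpulp_arrested``
    Essentially stationary cells in the red pulp, with rare single-frame
    linear displacements that mimic passive transport by blood flow.
``flow_flyer``
    Very fast objects crossing the field in straight lines (intravascular
    cells swept by flow).

Randomness: one seed per cohort; every cell draws from its own substream
keyed by (cohort seed, cell id), so enlarging a cohort never perturbs the
trajectories of existing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .geometry import Geometry, polyline_arclengths, polyline_point, polyline_tangent

BEHAVIORS = ("track_guided", "tzone_walker", "redpulp_arrested", "flow_flyer")
PRESETS = ("control", "ccr7_ko", "ptx", "integrin_block", "lps")

TRACK_COLUMNS = ["cell_id", "frame", "t_s", "x_um", "y_um", "cohort", "behavior", "compartment"]


class ConfigError(ValueError):
    pass


@dataclass
class AgentParams:
    """Parameters of one behavioural phenotype.

    speed_mean, speed_sd : µm/min, per-cell speed drawn once per cell
    bias_q : per-step probability of stepping toward the T zone (track_guided)
    lateral_sigma : µm, stationary sd of the lateral offset off the polyline
    lateral_corr_length : µm of arc travel over which the lateral offset
        decorrelates; excursions are generated by locomotion, so a slower
        cell also wobbles less per unit time
    persistence : [0, 1] directional correlation per step (tzone_walker)
    flow_event_rate : events/min for passive-flow jumps (redpulp_arrested)
    flow_speed : µm/min displacement rate during a flow event / flyer speed
    detach_prob : probability of permanent track detachment at preset onset
    """

    behavior: str
    speed_mean: float = 10.0
    speed_sd: float = 2.0
    bias_q: float = 0.95
    lateral_sigma: float = 2.0
    lateral_corr_length: float = 20.0
    persistence: float = 0.7
    flow_event_rate: float = 0.01
    flow_speed: float = 300.0
    detach_prob: float = 0.5

    def __post_init__(self):
        if self.behavior not in BEHAVIORS:
            raise ConfigError(f"unknown behavior {self.behavior!r}")
        if not 0.0 <= self.bias_q <= 1.0:
            raise ConfigError("bias_q must be in [0, 1]")
        if not 0.0 <= self.persistence <= 1.0:
            raise ConfigError("persistence must be in [0, 1]")
        if self.speed_mean < 0 or self.speed_sd < 0 or self.flow_speed < 0:
            raise ConfigError("speeds must be >= 0")


def default_params() -> Dict[str, AgentParams]:
    return {
        "track_guided": AgentParams("track_guided", speed_mean=10.0, speed_sd=2.0,
                                    bias_q=0.95, lateral_sigma=2.0),
        "tzone_walker": AgentParams("tzone_walker", speed_mean=10.0, speed_sd=2.0,
                                    persistence=0.7),
        "redpulp_arrested": AgentParams("redpulp_arrested", speed_mean=0.5, speed_sd=0.2,
                                        flow_event_rate=0.01, flow_speed=300.0),
        "flow_flyer": AgentParams("flow_flyer", speed_mean=300.0, speed_sd=50.0),
    }


@dataclass
class CohortConfig:
    """One simulated animal/movie worth of cells."""

    n_cells: Dict[str, int]
    params: Dict[str, AgentParams] = field(default_factory=default_params)
    preset: str = "control"
    n_frames: int = 40
    frame_interval: float = 20.0  # seconds
    seed: int = 0
    cohort: str = "control"

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")
        for b in self.n_cells:
            if b not in BEHAVIORS:
                raise ConfigError(f"unknown behavior {b!r} in n_cells")


def apply_preset(config: CohortConfig) -> CohortConfig:
    """Return a config with the perturbation preset folded into the parameters.

    control: unchanged. ccr7_ko: unbiased track steps, no T-zone entry.
    ptx: all cells arrested in the red pulp. integrin_block: all speeds
    halved. lps: unbiased track steps; detachment is applied per cell during
    simulation (after frame 0) with probability ``detach_prob``.
    """
    params = {b: replace(p) for b, p in config.params.items()}
    n_cells = dict(config.n_cells)
    if config.preset == "control":
        pass
    elif config.preset == "ccr7_ko":
        if "track_guided" in params:
            params["track_guided"].bias_q = 0.5
    elif config.preset == "ptx":
        total = sum(n_cells.values())
        n_cells = {"redpulp_arrested": total}
        params.setdefault("redpulp_arrested", default_params()["redpulp_arrested"])
    elif config.preset == "integrin_block":
        for p in params.values():
            p.speed_mean = 0.5 * p.speed_mean
    elif config.preset == "lps":
        if "track_guided" in params:
            params["track_guided"].bias_q = 0.5
    return replace(config, params=params, n_cells=n_cells)


# -- per-cell helpers -------------------------------------------------------


def _cell_rng(seed: int, cell_id: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(cell_id)])


def _random_unit(rng, n) -> np.ndarray:
    th = rng.uniform(0, 2 * np.pi, n)
    return np.stack([np.cos(th), np.sin(th)], axis=-1)


def _sample_redpulp_point(rng, geometry: Geometry) -> np.ndarray:
    w, h = geometry.field_size
    m = 2 * geometry.track_half_width
    for _ in range(200):
        p = rng.uniform([m, m], [w - m, h - m])
        if geometry.compartment_of(p[None, :])[0] == "redpulp":
            return p
    return p  # pathological geometry: accept last draw


def _walker_path(rng, geometry, start, speed_um_s, persistence, n_steps, heading=None):
    """Persistent random walk inside the T-zone disc, mirror-reflected at the rim."""
    c = geometry.t_zone_center
    R = geometry.t_zone_radius
    pos = np.empty((n_steps + 1, 2))
    pos[0] = start
    if heading is None:
        heading = _random_unit(rng, 1)[0]
    noise = _random_unit(rng, n_steps)
    step = speed_um_s
    p = pos[0].copy()
    h = heading.copy()
    for t in range(n_steps):
        h = persistence * h + (1.0 - persistence) * noise[t]
        nrm = np.linalg.norm(h)
        if nrm < 1e-12:
            h = noise[t].copy()
            nrm = 1.0
        h = h / nrm
        p = p + step * h
        d = np.linalg.norm(p - c)
        if d > R:
            # mirror across the rim, flip the radial heading component
            radial = (p - c) / d
            p = c + radial * (2 * R - d)
            h = h - 2 * np.dot(h, radial) * radial
        pos[t + 1] = p
    return pos


def _ou_lateral(rng, sigma, corr_length, step, n, half_width):
    """Stationary Ornstein-Uhlenbeck lateral offset sampled per frame.

    The process lives in arc length: each frame the cell travels ``step`` µm,
    decorrelating the offset by exp(-step/corr_length). Stationary sd is
    ``sigma``; values are clipped at the corridor half-width.
    """
    if sigma <= 0:
        return np.zeros(n)
    rho = np.exp(-step / max(corr_length, 1e-9))
    innov = rng.normal(0.0, sigma, n)
    o = np.empty(n)
    o[0] = innov[0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        o[t] = rho * o[t - 1] + scale * innov[t]
    return np.clip(o, -half_width, half_width)


_GOLDEN = 0.6180339887498949


def _start_arclength(rng, L: float, slot: int) -> float:
    """Staggered starting arc position in [0.15 L, 0.85 L].

    Slots follow the golden-ratio (Kronecker) sequence, which keeps any
    prefix of cells well spread along the track (so rendered blobs stay
    separated) without depending on the total cell count, plus a small
    per-cell jitter.
    """
    frac = (slot * _GOLDEN) % 1.0
    return L * (0.15 + 0.7 * frac) + rng.uniform(-0.02, 0.02) * L


def _track_guided_path(rng, geometry, params: AgentParams, track_index, n_steps,
                       dt_s, preset, walker_params: Optional[AgentParams],
                       slot: int = 0):
    """Biased arc-length walk along one track polyline.

    Returns (positions (n_steps+1, 2), behavior labels per frame).
    """
    verts = geometry.tracks[track_index]
    arclens = polyline_arclengths(verts)
    L = arclens[-1]
    dt_min = dt_s / 60.0
    speed = max(0.0, rng.normal(params.speed_mean, params.speed_sd))
    step = speed * dt_min
    s0 = float(np.clip(_start_arclength(rng, L, slot), 0.12 * L, 0.88 * L))
    toward = rng.random(n_steps) < params.bias_q
    incr = np.where(toward, step, -step)  # arc length increases toward the T zone
    lateral = _ou_lateral(rng, params.lateral_sigma, params.lateral_corr_length,
                          step, n_steps + 1, geometry.track_half_width)
    free = s0 + np.concatenate([[0.0], np.cumsum(incr)])

    behavior = np.full(n_steps + 1, "track_guided", dtype=object)
    if preset == "ccr7_ko":
        # reflect at both ends: triangle fold into [0, L]
        s = L - np.abs(np.mod(free, 2 * L) - L)
        positions = _on_track_positions(verts, arclens, s, lateral)
        return positions, behavior

    # distal end reflects (mirror map), T-zone end absorbs
    s = np.abs(free)
    hit = np.nonzero(s >= L)[0]
    if len(hit) == 0:
        positions = _on_track_positions(verts, arclens, s, lateral)
        return positions, behavior

    k = int(hit[0])
    s = s[:k]
    positions = np.empty((n_steps + 1, 2))
    if k > 0:
        positions[:k] = _on_track_positions(verts, arclens, s, lateral[:k])
    # continue inside the T zone as a persistent walker
    wp = walker_params or AgentParams("tzone_walker", speed_mean=speed, speed_sd=0.0)
    entry = verts[-1]
    tangent = polyline_tangent(verts, arclens, np.array([L - 1e-6]))[0]
    wspeed = max(0.0, rng.normal(wp.speed_mean, wp.speed_sd))
    walk = _walker_path(rng, geometry, entry, wspeed * dt_min, wp.persistence,
                        n_steps - k + 1, heading=tangent)
    positions[k:] = walk[: n_steps + 1 - k]
    behavior[k:] = "tzone_walker"
    return positions, behavior


def _on_track_positions(verts, arclens, s, lateral):
    pts = polyline_point(verts, arclens, s)
    tan = polyline_tangent(verts, arclens, s)
    normal = np.stack([-tan[..., 1], tan[..., 0]], axis=-1)
    return pts + np.asarray(lateral)[..., None] * normal


def _arrested_path(rng, geometry, params: AgentParams, n_steps, dt_s, start=None):
    dt_min = dt_s / 60.0
    anchor = start if start is not None else _sample_redpulp_point(rng, geometry)
    jitter = rng.normal(0.0, 0.3, (n_steps + 1, 2))
    events = rng.random(n_steps) < params.flow_event_rate * dt_min
    dirs = _random_unit(rng, n_steps)
    jumps = np.zeros((n_steps + 1, 2))
    jumps[1:] = np.cumsum(events[:, None] * params.flow_speed * dt_min * dirs, axis=0)
    w, h = geometry.field_size
    pos = anchor + jumps + jitter
    return np.clip(pos, 1.0, [w - 1.0, h - 1.0])


def _flyer_path(rng, geometry, params: AgentParams, n_steps, dt_s):
    dt_min = dt_s / 60.0
    w, h = geometry.field_size
    speed = max(1.0, rng.normal(params.speed_mean, params.speed_sd))
    start = rng.uniform([1.0, 1.0], [w - 1.0, h - 1.0])
    direction = _random_unit(rng, 1)[0]
    t = np.arange(n_steps + 1)[:, None]
    free = start + t * speed * dt_min * direction
    # fold back into the field so positions stay renderable
    out = np.empty_like(free)
    for ax, size in enumerate((w, h)):
        span = size - 2.0
        out[:, ax] = 1.0 + span - np.abs(np.mod(free[:, ax] - 1.0, 2 * span) - span)
    return out


# -- cohort simulation ------------------------------------------------------


def simulate_cohort(geometry: Geometry, config: CohortConfig) -> pd.DataFrame:
    """Simulate every cell in ``config`` and return a long-format track table.

    Columns: cell_id, frame, t_s, x_um, y_um, cohort, behavior, compartment.
    Deterministic for a fixed (seed, config, geometry).
    """
    cfg = apply_preset(config)
    n_steps = cfg.n_frames - 1
    dt = cfg.frame_interval
    times = np.arange(cfg.n_frames) * dt

    rows_pos = []
    rows_meta = []
    cell_id = 0
    walker_params = cfg.params.get("tzone_walker")

    for behavior in BEHAVIORS:
        n = cfg.n_cells.get(behavior, 0)
        if n == 0:
            continue
        params = cfg.params.get(behavior) or default_params()[behavior]
        for i in range(n):
            rng = _cell_rng(cfg.seed, cell_id)
            labels = np.full(cfg.n_frames, behavior, dtype=object)
            if behavior == "track_guided":
                track_index = i % len(geometry.tracks)
                slot = i // len(geometry.tracks)
                detached = (config.preset == "lps" and
                            rng.random() < params.detach_prob)
                if detached:
                    # frame 0 on the track, then permanently arrested off-track
                    verts = geometry.tracks[track_index]
                    arclens = polyline_arclengths(verts)
                    s0 = float(np.clip(_start_arclength(rng, arclens[-1], slot),
                                       0.12 * arclens[-1], 0.88 * arclens[-1]))
                    p0 = _on_track_positions(
                        verts, arclens, np.array([s0]),
                        np.clip(rng.normal(0, params.lateral_sigma, 1),
                                -geometry.track_half_width, geometry.track_half_width))[0]
                    arrested = _arrested_path(rng, geometry,
                                              cfg.params.get("redpulp_arrested")
                                              or default_params()["redpulp_arrested"],
                                              n_steps - 1 if n_steps > 1 else 0, dt)
                    pos = np.vstack([p0[None, :], arrested[: cfg.n_frames - 1]])
                    labels[1:] = "redpulp_arrested"
                else:
                    pos, labels = _track_guided_path(
                        rng, geometry, params, track_index, n_steps, dt,
                        config.preset, walker_params, slot=slot)
            elif behavior == "tzone_walker":
                c, R = geometry.t_zone_center, geometry.t_zone_radius
                r = R * np.sqrt(rng.random())
                th = rng.uniform(0, 2 * np.pi)
                start = c + r * np.array([np.cos(th), np.sin(th)])
                dt_min = dt / 60.0
                speed = max(0.0, rng.normal(params.speed_mean, params.speed_sd))
                pos = _walker_path(rng, geometry, start, speed * dt_min,
                                   params.persistence, n_steps)
            elif behavior == "redpulp_arrested":
                pos = _arrested_path(rng, geometry, params, n_steps, dt)
            else:  # flow_flyer
                pos = _flyer_path(rng, geometry, params, n_steps, dt)
            rows_pos.append(pos)
            rows_meta.append((cell_id, labels))
            cell_id += 1

    if not rows_pos:
        return pd.DataFrame(columns=TRACK_COLUMNS)

    all_pos = np.concatenate(rows_pos, axis=0)
    compartments = geometry.compartment_of(all_pos)
    frames = np.tile(np.arange(cfg.n_frames), len(rows_meta))
    cell_ids = np.repeat([m[0] for m in rows_meta], cfg.n_frames)
    behaviors = np.concatenate([m[1] for m in rows_meta])
    table = pd.DataFrame({
        "cell_id": cell_ids,
        "frame": frames,
        "t_s": np.tile(times, len(rows_meta)),
        "x_um": all_pos[:, 0],
        "y_um": all_pos[:, 1],
        "cohort": cfg.cohort,
        "behavior": behaviors,
        "compartment": compartments,
    })
    return table
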