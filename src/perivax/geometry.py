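"""Spleen-like imaging-field geometry: T-zone disc, perivascular track
polylines, vessel masks and compartment labelling.

The field is a 2-D rectangle in physical units (µm). A central disc models
the T zone of the white pulp; oriented polylines radiating outward from its
perimeter model perivascular tracks (PT-tracks) that connect the red pulp to
the T zone. Each polyline is ordered distal end → T-zone end, so increasing
arc length means progress toward the T zone. Everything outside the disc and
off the tracks is red pulp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point


class SizingError(ValueError):
    """Field too small to hold the T-zone disc plus tracks."""


def polyline_arclengths(vertices: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex of a polyline, starting at 0."""
    seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def polyline_point(vertices: np.ndarray, arclens: np.ndarray, s) -> np.ndarray:
    """Point(s) at arc-length position(s) ``s`` along the polyline.

    Returns an array of shape (..., 2). ``s`` is clipped to [0, L].
    """
    s = np.clip(np.asarray(s, dtype=float), 0.0, arclens[-1])
    idx = np.clip(np.searchsorted(arclens, s, side="right") - 1, 0, len(arclens) - 2)
    seg_len = arclens[idx + 1] - arclens[idx]
    frac = (s - arclens[idx]) / seg_len
    p0 = vertices[idx]
    p1 = vertices[idx + 1]
    return p0 + frac[..., None] * (p1 - p0)


def polyline_tangent(vertices: np.ndarray, arclens: np.ndarray, s) -> np.ndarray:
    """Unit tangent(s) of the segment containing arc-length position(s) ``s``."""
    s = np.clip(np.asarray(s, dtype=float), 0.0, arclens[-1])
    idx = np.clip(np.searchsorted(arclens, s, side="right") - 1, 0, len(arclens) - 2)
    d = vertices[idx + 1] - vertices[idx]
    return d / np.linalg.norm(d, axis=-1, keepdims=True)


@dataclass
class Geometry:
    """Static geometry of one simulated imaging field.

    Attributes
    ----------
    t_zone_center : (2,) array, µm
    t_zone_radius : float, µm
    tracks : list of (N, 2) arrays, µm; vertex order distal end → T-zone end
    track_half_width : float, µm; lateral half-width of the vessel sheath
    field_size : (width, height) in µm
    pixel_size : µm per pixel used to rasterise masks
    branch_junctions : (M, 2) array of polyline-polyline crossing points, µm
    """

    t_zone_center: np.ndarray
    t_zone_radius: float
    tracks: list
    track_half_width: float
    field_size: tuple
    pixel_size: float
    branch_junctions: np.ndarray = field(default=None)

    _vessel_masks: list = field(default=None, repr=False)
    _vessel_distance: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.t_zone_center = np.asarray(self.t_zone_center, dtype=float)
        self.tracks = [np.asarray(t, dtype=float) for t in self.tracks]
        if self.branch_junctions is None:
            self.branch_junctions = _find_junctions(self.tracks)
        else:
            self.branch_junctions = np.asarray(self.branch_junctions, dtype=float).reshape(-1, 2)
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for i, t in enumerate(self.tracks):
            if t.ndim != 2 or t.shape[1] != 2 or len(t) < 2:
                raise ValueError(f"track {i}: need >= 2 vertices of dim 2")
            seg = np.linalg.norm(np.diff(t, axis=0), axis=1)
            if np.any(seg <= 0):
                raise ValueError(f"track {i}: zero-length segment")
            d_end = np.linalg.norm(t[-1] - self.t_zone_center)
            if d_end > self.t_zone_radius + self.track_half_width + 1e-6:
                raise ValueError(
                    f"track {i}: T-zone end is {d_end:.1f} µm from the centre, "
                    f"beyond radius + half-width"
                )

    # -- raster shape -----------------------------------------------------

    @property
    def raster_shape(self) -> tuple:
        w, h = self.field_size
        return (int(round(h / self.pixel_size)), int(round(w / self.pixel_size)))

    def um_to_px(self, xy: np.ndarray) -> np.ndarray:
        """Physical (x, y) µm → fractional (row, col) pixel coordinates."""
        xy = np.asarray(xy, dtype=float)
        return np.stack([xy[..., 1] / self.pixel_size, xy[..., 0] / self.pixel_size], axis=-1)

    # -- masks ------------------------------------------------------------

    @property
    def vessel_masks(self) -> list:
        """One binary raster per track: pixels within half-width of the polyline."""
        if self._vessel_masks is None:
            self._vessel_masks = [
                _rasterize_corridor(t, self.track_half_width, self.raster_shape, self.pixel_size)
                for t in self.tracks
            ]
        return self._vessel_masks

    def t_zone_mask(self) -> np.ndarray:
        H, W = self.raster_shape
        yy, xx = np.mgrid[0:H, 0:W]
        cx, cy = self.t_zone_center
        r2 = ((xx + 0.5) * self.pixel_size - cx) ** 2 + ((yy + 0.5) * self.pixel_size - cy) ** 2
        return r2 <= self.t_zone_radius**2

    @property
    def vessel_distance_map(self) -> np.ndarray:
        """Distance (µm) from each pixel centre to the nearest track polyline."""
        if self._vessel_distance is None:
            H, W = self.raster_shape
            skel = np.zeros((H, W), bool)
            for t in self.tracks:
                _draw_polyline(skel, t, self.pixel_size)
            self._vessel_distance = ndimage.distance_transform_edt(
                ~skel, sampling=self.pixel_size
            )
        return self._vessel_distance

    # -- queries ----------------------------------------------------------

    def distance_to_tzone_center(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return np.linalg.norm(xy - self.t_zone_center, axis=-1)

    def compartment_of(self, xy: np.ndarray) -> np.ndarray:
        """Label positions as 'tzone', 'track' or 'redpulp'.

        T-zone membership wins over track membership where the corridor
        overlaps the disc rim.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        labels = np.full(len(xy), "redpulp", dtype=object)
        rc = self.um_to_px(xy)
        H, W = self.raster_shape
        r = np.clip(rc[:, 0].astype(int), 0, H - 1)
        c = np.clip(rc[:, 1].astype(int), 0, W - 1)
        on_track = self.vessel_distance_map[r, c] <= self.track_half_width
        labels[on_track] = "track"
        in_tz = self.distance_to_tzone_center(xy) <= self.t_zone_radius
        labels[in_tz] = "tzone"
        return labels

    def track_polygon(self, index: int):
        """Shapely polygon of one vessel corridor (polyline buffered by half-width)."""
        return LineString(self.tracks[index]).buffer(self.track_half_width)

    def to_dict(self) -> dict:
        return {
            "t_zone_center": self.t_zone_center.tolist(),
            "t_zone_radius": float(self.t_zone_radius),
            "tracks": [t.tolist() for t in self.tracks],
            "track_half_width": float(self.track_half_width),
            "field_size": [float(v) for v in self.field_size],
            "pixel_size": float(self.pixel_size),
            "branch_junctions": self.branch_junctions.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Geometry":
        return cls(
            t_zone_center=np.array(d["t_zone_center"]),
            t_zone_radius=d["t_zone_radius"],
            tracks=[np.array(t) for t in d["tracks"]],
            track_half_width=d["track_half_width"],
            field_size=tuple(d["field_size"]),
            pixel_size=d["pixel_size"],
            branch_junctions=np.array(d["branch_junctions"]).reshape(-1, 2),
        )


# -- construction ---------------------------------------------------------


def _find_junctions(tracks: Sequence[np.ndarray]) -> np.ndarray:
    pts = []
    lines = [LineString(t) for t in tracks]
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            inter = lines[i].intersection(lines[j])
            if inter.is_empty:
                continue
            geoms = getattr(inter, "geoms", [inter])
            for g in geoms:
                if isinstance(g, Point):
                    pts.append([g.x, g.y])
                else:  # overlapping collinear stretch: take its midpoint
                    c = g.centroid
                    pts.append([c.x, c.y])
    return np.array(pts, dtype=float).reshape(-1, 2)


def _draw_polyline(canvas: np.ndarray, vertices: np.ndarray, pixel_size: float) -> None:
    from skimage.draw import line

    H, W = canvas.shape
    px = vertices / pixel_size
    for a, b in zip(px[:-1], px[1:]):
        rr, cc = line(int(round(a[1])), int(round(a[0])), int(round(b[1])), int(round(b[0])))
        keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        canvas[rr[keep], cc[keep]] = True


def _rasterize_corridor(vertices, half_width, shape, pixel_size) -> np.ndarray:
    skel = np.zeros(shape, bool)
    _draw_polyline(skel, vertices, pixel_size)
    dist = ndimage.distance_transform_edt(~skel, sampling=pixel_size)
    return dist <= half_width


def build_geometry(
    field_size=(1000.0, 1000.0),
    n_tracks: int = 4,
    t_zone_radius: float = 150.0,
    track_half_width: float = 15.0,
    track_length: tuple = (250.0, 400.0),
    pixel_size: float = 2.0,
    waypoint_spacing: float = 60.0,
    wiggle_sd: float = 0.12,
    seed: int = 0,
) -> Geometry:
    """Place a centred T-zone disc and ``n_tracks`` polylines radiating outward.

    Tracks start on the disc perimeter and extend into the red pulp with a
    small random angular wiggle per waypoint (radians, sd ``wiggle_sd``).
    Vertex order in the result is distal end → T-zone end. Raises
    :class:`SizingError` if the requested lengths cannot fit in the field.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = np.random.default_rng(seed)
    w, h = field_size
    center = np.array([w / 2.0, h / 2.0])
    margin = 2 * track_half_width
    max_reach = min(w, h) / 2.0 - margin
    if t_zone_radius + track_length[0] > max_reach:
        raise SizingError(
            f"field {field_size} cannot hold T-zone radius {t_zone_radius} "
            f"plus tracks of length >= {track_length[0]}"
        )

    base_angles = np.linspace(0, 2 * np.pi, n_tracks, endpoint=False)
    base_angles = base_angles + rng.uniform(0, 2 * np.pi / max(n_tracks, 1))
    tracks = []
    for ang in base_angles:
        length = rng.uniform(*track_length)
        length = min(length, max_reach - t_zone_radius)
        n_seg = max(2, int(np.ceil(length / waypoint_spacing)))
        step = length / n_seg
        p = center + t_zone_radius * np.array([np.cos(ang), np.sin(ang)])
        verts = [p]
        heading = ang  # outward radial
        for _ in range(n_seg):
            heading = heading + rng.normal(0.0, wiggle_sd)
            q = verts[-1] + step * np.array([np.cos(heading), np.sin(heading)])
            q = np.clip(q, margin, [w - margin, h - margin])
            if np.linalg.norm(q - verts[-1]) < 1e-9:
                break
            verts.append(q)
        verts = np.array(verts[::-1])  # distal → T-zone end
        tracks.append(verts)

    return Geometry(
        t_zone_center=center,
        t_zone_radius=t_zone_radius,
        tracks=tracks,
        track_half_width=track_half_width,
        field_size=tuple(float(v) for v in field_size),
        pixel_size=pixel_size,
    )
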