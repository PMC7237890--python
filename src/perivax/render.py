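"""Rendering of simulated cells into calibrated grayscale time-lapse stacks,
plus fixture I/O (TIFF stacks, CSV track tables, JSON sidecars)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .agents import TRACK_COLUMNS
from .geometry import Geometry


class CalibrationError(ValueError):
    pass


@dataclass
class ImageStack:
    """T×H×W grayscale time-lapse with physical calibration."""

    data: np.ndarray          # (T, H, W) float32, >= 0
    pixel_size: float         # µm / px
    frame_interval: float     # s / frame
    channel: str = "cells"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("stack must be T x H x W")
        if self.pixel_size <= 0:
            raise CalibrationError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise CalibrationError("frame_interval must be > 0")
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise ValueError("intensities must be finite and >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape


def render_stack(
    tracks: pd.DataFrame,
    geometry: Geometry,
    blob_sigma_px: float = 2.0,
    peak_intensity: float = 150.0,
    background: float = 20.0,
    noise_sd: float = 5.0,
    texture_sd: float = 0.0,
    texture_scale_px: float = 3.0,
    pixel_size: float = None,
    frame_interval: float = None,
    seed: int = 0,
    channel: str = "cells",
) -> ImageStack:
    """Draw each cell as an isotropic Gaussian blob at its per-frame position.

    ``texture_sd`` > 0 adds a static smoothed random texture (correlation
    length ``texture_scale_px``) shared by all frames — the stand-in for
    tissue autofluorescence in the endogenous/tissue channel, which anchors
    optical flow in cell-free regions. Leave it at 0 for a clean
    transferred-cell channel meant for detection and tracking. Additive
    per-frame Gaussian read noise is then applied and the result clipped at
    0. Deterministic for a fixed seed. ``pixel_size`` defaults to the
    geometry's.
    """
    px = geometry.pixel_size if pixel_size is None else float(pixel_size)
    if px <= 0:
        raise CalibrationError("pixel_size must be > 0")
    w_um, h_um = geometry.field_size
    H = int(round(h_um / px))
    W = int(round(w_um / px))
    if frame_interval is None:
        t_s = np.sort(tracks["t_s"].unique()) if len(tracks) else np.array([0.0, 1.0])
        frame_interval = float(np.diff(t_s).mean()) if len(t_s) > 1 else 1.0

    frames = np.sort(tracks["frame"].unique()) if len(tracks) else np.array([], dtype=int)
    n_frames = int(frames.max()) + 1 if len(frames) else 1
    rng = np.random.default_rng(seed)
    base = np.full((H, W), background, dtype=np.float32)
    if texture_sd > 0:
        from scipy.ndimage import gaussian_filter
        tex = gaussian_filter(rng.normal(0.0, 1.0, (H, W)), texture_scale_px)
        sd = tex.std()
        if sd > 0:
            base += (texture_sd / sd * tex).astype(np.float32)
    stack = np.tile(base, (n_frames, 1, 1))

    half = int(np.ceil(4 * blob_sigma_px))
    ax = np.arange(-half, half + 1)

    if len(tracks):
        x = tracks["x_um"].to_numpy() / px
        y = tracks["y_um"].to_numpy() / px
        fr = tracks["frame"].to_numpy().astype(int)
        if np.any((x < 0) | (x > W) | (y < 0) | (y > H)):
            raise ValueError("cell positions outside the field cannot be rendered")
        for xi, yi, fi in zip(x, y, fr):
            r0 = int(round(yi))
            c0 = int(round(xi))
            rr = ax + r0
            cc = ax + c0
            rm = (rr >= 0) & (rr < H)
            cm = (cc >= 0) & (cc < W)
            if not rm.any() or not cm.any():
                continue
            gy = np.exp(-((rr[rm] - yi) ** 2) / (2 * blob_sigma_px**2))
            gx = np.exp(-((cc[cm] - xi) ** 2) / (2 * blob_sigma_px**2))
            stack[fi, np.ix_(rr[rm], cc[cm])[0], np.ix_(rr[rm], cc[cm])[1]] += (
                peak_intensity * gy[:, None] * gx[None, :]
            )

    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, stack.shape).astype(np.float32)
    np.clip(stack, 0.0, None, out=stack)
    return ImageStack(stack, pixel_size=px, frame_interval=float(frame_interval),
                      channel=channel)


# -- fixture I/O ------------------------------------------------------------


def write_fixture(geometry: Geometry, tracks: pd.DataFrame, stack: ImageStack,
                  out_dir, config: dict = None) -> dict:
    """Write stack, track table, masks, and a regeneration sidecar.

    Returns a manifest mapping logical names to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["stack"] = str(out / "stack.tif")
    tifffile.imwrite(paths["stack"], stack.data,
                     metadata={"pixel_size_um": stack.pixel_size,
                               "frame_interval_s": stack.frame_interval,
                               "channel": stack.channel})

    paths["tracks"] = str(out / "tracks.csv")
    tracks.to_csv(paths["tracks"], index=False)

    paths["tzone_mask"] = str(out / "tzone_mask.tif")
    tifffile.imwrite(paths["tzone_mask"], geometry.t_zone_mask().astype(np.uint8))
    paths["vessel_masks"] = []
    for i, m in enumerate(geometry.vessel_masks):
        p = str(out / f"vessel_mask_{i:02d}.tif")
        tifffile.imwrite(p, m.astype(np.uint8))
        paths["vessel_masks"].append(p)

    sidecar = {
        "geometry": geometry.to_dict(),
        "stack": {"pixel_size": stack.pixel_size,
                  "frame_interval": stack.frame_interval,
                  "channel": stack.channel},
    }
    if config is not None:
        sidecar["config"] = config
    paths["sidecar"] = str(out / "config.json")
    with open(paths["sidecar"], "w") as f:
        json.dump(sidecar, f, indent=2)
    return paths


def read_stack(path) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return ImageStack(
        np.asarray(data, dtype=np.float32),
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        frame_interval=float(meta.get("frame_interval_s", 1.0)),
        channel=str(meta.get("channel", "cells")),
    )


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    return df


def read_geometry(path) -> Geometry:
    with open(path) as f:
        sidecar = json.load(f)
    return Geometry.from_dict(sidecar["geometry"] if "geometry" in sidecar else sidecar)
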