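"""Calibrated image-stack I/O and kymograph construction.

A kymograph is built by sampling each frame along a user-drawn polyline at
unit spacing (bilinear interpolation) and averaging across a perpendicular
band of odd width (default 5 px, mean projection, offsets −2..+2).
Out-of-bounds samples are dropped from the mean rather than zero-padded.
One kymograph row per frame; time runs down the rows.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .datatypes import Kymograph, LineRoi

__all__ = ["ImageStack", "read_stack", "build_kymograph", "extract_intensity_timecourse"]


@dataclass
class ImageStack:
    """Frames in acquisition order with physical calibration attached."""

    frames: np.ndarray  # (n_frames, height, width)
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("stack must be 3-D (frames, y, x)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def read_stack(
    path,
    pixel_size: float,
    frame_interval: float,
    channel: int | None = None,
    n_channels: int = 1,
) -> ImageStack:
    """Read a multi-page TIFF as an image stack.

    Interleaved multi-channel stacks are de-interleaved with ``channel`` /
    ``n_channels`` (channel 0 = pages 0, n, 2n, ...).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image stack not found: {p}")
    try:
        data = tifffile.imread(p)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise ValueError(f"could not read TIFF stack {p}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{p}: expected a stack of 2-D pages, got shape {data.shape}")
    if channel is not None:
        if not 0 <= channel < n_channels:
            raise ValueError("channel must be in [0, n_channels)")
        data = data[channel::n_channels]
        frame_interval = frame_interval * n_channels
    return ImageStack(data.astype(float), pixel_size, frame_interval)


def _polyline_samples(roi: LineRoi) -> tuple[np.ndarray, np.ndarray]:
    """Unit-spaced sample points and unit normals along the polyline.

    Returns (points (n, 2) as (x, y), normals (n, 2)). Sample count is
    round(arc length) + 1.
    """
    v = roi.vertices
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.all(seg_len == 0):
        raise ValueError("line ROI has zero length")
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arc[-1]
    n = int(round(total)) + 1
    s = np.linspace(0.0, total, n)
    x = np.interp(s, arc, v[:, 0])
    y = np.interp(s, arc, v[:, 1])
    pts = np.column_stack([x, y])
    # local tangent from central differences; normal is the tangent rotated 90°
    tx = np.gradient(x)
    ty = np.gradient(y)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    normals = np.column_stack([-ty / norm, tx / norm])
    return pts, normals


def build_kymograph(stack: ImageStack, roi: LineRoi, channel: str = "") -> Kymograph:
    """Average intensity along a polyline, across its width, for every frame.

    For each of the ``width`` perpendicular offsets the line is sampled at
    unit spacing with bilinear interpolation; the kymograph value is the mean
    over the offsets whose sample falls inside the image.
    """
    pts, normals = _polyline_samples(roi)
    h, w = stack.frames.shape[1:]
    half = roi.width // 2
    offsets = np.arange(-half, half + 1)
    # coordinates for all (offset, sample) pairs
    xs = pts[:, 0][None, :] + offsets[:, None] * normals[:, 0][None, :]
    ys = pts[:, 1][None, :] + offsets[:, None] * normals[:, 1][None, :]
    valid = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    if not valid[half].all():
        raise ValueError("line ROI extends outside the image bounds")
    coords = np.stack([ys.ravel(), xs.ravel()])  # map_coordinates wants (row, col)

    n_valid = valid.sum(axis=0).astype(float)
    rows = np.empty((stack.n_frames, pts.shape[0]))
    for f in range(stack.n_frames):
        samples = ndimage.map_coordinates(stack.frames[f], coords, order=1, mode="nearest")
        samples = samples.reshape(xs.shape)
        samples[~valid] = 0.0
        rows[f] = samples.sum(axis=0) / n_valid
    return Kymograph(
        rows,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        source_line=roi.vertices.copy(),
        channel=channel,
    )


def extract_intensity_timecourse(
    kymo: Kymograph, line: LineRoi, background_line: LineRoi
) -> "pd.DataFrame":
    """Per-frame mean intensity along a line drawn on the kymograph.

    The lines are drawn along the time axis (vertical); for each frame (row)
    the intensity is averaged over the line's column band of the given width.
    Returns a DataFrame with columns t_s, intensity, background.
    """
    import pandas as pd

    def per_frame_mean(roi: LineRoi) -> np.ndarray:
        v = roi.vertices
        if np.allclose(v[:, 1].min(), v[:, 1].max()):
            raise ValueError("timecourse line must span more than one frame (row)")
        y0, y1 = v[:, 1].min(), v[:, 1].max()
        r0 = max(int(math.ceil(y0)), 0)
        r1 = min(int(math.floor(y1)), kymo.n_frames - 1)
        if r1 < r0:
            raise ValueError("line ROI covers no kymograph rows")
        rows_idx = np.arange(r0, r1 + 1)
        # x position of the polyline at each covered row
        order = np.argsort(v[:, 1])
        xc = np.interp(rows_idx, v[order, 1], v[order, 0])
        half = roi.width // 2
        out = np.full(kymo.n_frames, np.nan)
        for r, x in zip(rows_idx, xc):
            c0 = max(int(round(x)) - half, 0)
            c1 = min(int(round(x)) + half, kymo.n_positions - 1)
            if c1 < c0:
                raise ValueError("line ROI lies outside the kymograph columns")
            out[r] = kymo.data[r, c0 : c1 + 1].mean()
        return out

    inten = per_frame_mean(line)
    bg = per_frame_mean(background_line)
    t = np.arange(kymo.n_frames) * kymo.frame_interval
    df = pd.DataFrame({"t_s": t, "intensity": inten, "background": bg})
    return df.dropna().reset_index(drop=True)
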