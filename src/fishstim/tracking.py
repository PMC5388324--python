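"""Midline tracks: containers, two-view merging, and moving-average smoothing.

A swimming fish is tracked as six points placed at equal distances along the
trunk, head to tail.  Recordings come from two synchronised cameras — one
viewing the tank from the side, one from above — so each camera sees a 2-D
projection of the 3-D midline.  This module merges the two projections into a
3-D track and applies the centred 3-point moving average used to de-noise raw
tracker output.

Coordinate convention (mm):

* ``x`` — the horizontal axis shared by both camera views,
* ``y`` — the horizontal depth axis (seen only by the top camera),
* ``z`` — the vertical axis (seen only by the side camera).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MidlineTrack",
    "ViewTrack2D",
    "merge_views",
    "project_to_views",
    "smooth_moving_average",
]


@dataclass
class MidlineTrack:
    """Per-frame 3-D positions of ordered trunk points (head first).

    Parameters
    ----------
    points
        Array of shape ``(n_frames, n_points, 3)`` in mm.
    fps
        Frame rate in frames per second.
    """

    points: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError("points must have shape (n_frames, n_points, 3)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("track contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def chord_lengths(self) -> np.ndarray:
        """Distances between consecutive points, shape (n_frames, n_points-1)."""
        diffs = np.diff(self.points, axis=1)
        return np.linalg.norm(diffs, axis=2)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        """Write as long-format CSV: frame, point_index, x_mm, y_mm, z_mm."""
        f, p, _ = self.points.shape
        frames = np.repeat(np.arange(f), p)
        idx = np.tile(np.arange(p), f)
        flat = self.points.reshape(-1, 3)
        df = pd.DataFrame(
            {
                "frame": frames,
                "point_index": idx,
                "x_mm": flat[:, 0],
                "y_mm": flat[:, 1],
                "z_mm": flat[:, 2],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fps: float, strict: bool = True) -> "MidlineTrack":
        """Read the long-format CSV written by :meth:`to_csv`.

        ``strict`` rejects NaN coordinates and missing (frame, point) cells.
        """
        df = pd.read_csv(path)
        required = {"frame", "point_index", "x_mm", "y_mm", "z_mm"}
        if not required.issubset(df.columns):
            raise ValueError(f"CSV must have columns {sorted(required)}")
        if strict and df[["x_mm", "y_mm", "z_mm"]].isna().any().any():
            raise ValueError("strict parse: NaN coordinates present")
        n_frames = int(df["frame"].max()) + 1
        n_points = int(df["point_index"].max()) + 1
        if len(df) != n_frames * n_points:
            raise ValueError("strict parse: missing (frame, point) rows")
        df = df.sort_values(["frame", "point_index"])
        pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy().reshape(n_frames, n_points, 3)
        return cls(points=pts, fps=fps)


@dataclass
class ViewTrack2D:
    """One camera's 2-D pixel track of the six trunk points.

    ``coords`` has shape ``(n_frames, n_points, 2)``; the first pixel axis is
    the horizontal axis shared by both cameras, the second is the
    view-specific axis (vertical for the side camera, depth for the top
    camera).  ``px_to_mm`` converts pixels to mm.
    """

    camera: str  # "side" or "top"
    coords: np.ndarray
    fps: float
    px_to_mm: float

    def __post_init__(self) -> None:
        if self.camera not in ("side", "top"):
            raise ValueError("camera must be 'side' or 'top'")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n_frames, n_points, 2)")
        if self.px_to_mm <= 0:
            raise ValueError("px_to_mm must be positive")


def merge_views(
    side: ViewTrack2D, top: ViewTrack2D, shared_axis_tol_mm: float = 2.0
) -> MidlineTrack:
    """Combine side- and top-camera 2-D tracks into one 3-D midline track.

    The shared horizontal axis ``x`` is taken as the average of the two
    views' estimates after converting each to mm; ``y`` comes from the top
    view and ``z`` from the side view.  If the two x estimates diverge by
    more than ``shared_axis_tol_mm`` anywhere, a warning carrying the
    worst-frame residual is emitted (cameras probably desynchronised or
    mis-scaled).
    """
    if side.camera != "side" or top.camera != "top":
        raise ValueError("arguments must be (side view, top view)")
    if side.coords.shape != top.coords.shape:
        raise ValueError(
            f"frame/point count mismatch: side {side.coords.shape[:2]} "
            f"vs top {top.coords.shape[:2]}"
        )
    if side.fps != top.fps:
        raise ValueError("views have different frame rates")

    side_mm = side.coords * side.px_to_mm
    top_mm = top.coords * top.px_to_mm
    x_side = side_mm[..., 0]
    x_top = top_mm[..., 0]
    residual = np.abs(x_side - x_top)
    if residual.max() > shared_axis_tol_mm:
        worst = int(residual.max(axis=1).argmax())
        warnings.warn(
            "shared-axis estimates disagree: max |x_side - x_top| = "
            f"{residual.max():.3f} mm (tolerance {shared_axis_tol_mm} mm), "
            f"worst at frame {worst}",
            stacklevel=2,
        )
    pts = np.stack([(x_side + x_top) / 2.0, top_mm[..., 1], side_mm[..., 1]], axis=2)
    return MidlineTrack(points=pts, fps=side.fps)


def project_to_views(
    track: MidlineTrack, px_to_mm_side: float = 1.0, px_to_mm_top: float = 1.0
) -> tuple[ViewTrack2D, ViewTrack2D]:
    """Orthographic projection of a 3-D track back onto the two camera planes.

    Inverse of :func:`merge_views` for consistent inputs; used for round-trip
    verification.
    """
    side = ViewTrack2D(
        camera="side",
        coords=track.points[..., [0, 2]] / px_to_mm_side,
        fps=track.fps,
        px_to_mm=px_to_mm_side,
    )
    top = ViewTrack2D(
        camera="top",
        coords=track.points[..., [0, 1]] / px_to_mm_top,
        fps=track.fps,
        px_to_mm=px_to_mm_top,
    )
    return side, top


def smooth_moving_average(track: MidlineTrack, window: int = 3) -> MidlineTrack:
    """Centred moving average over frames, applied per coordinate series.

    Endpoints use the shrinking-window mean of the neighbours that exist, so
    the frame count is preserved (the downstream skeletal conversion needs
    every frame).  ``window`` must be odd so the window is symmetric.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > track.n_frames:
        raise ValueError(
            f"window {window} exceeds track length {track.n_frames}"
        )
    f, p, _ = track.points.shape
    series = pd.DataFrame(track.points.reshape(f, p * 3))
    smoothed = series.rolling(window, center=True, min_periods=1).mean()
    return MidlineTrack(points=smoothed.to_numpy().reshape(f, p, 3), fps=track.fps)
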