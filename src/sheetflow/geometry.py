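"""Sheet geometry: circle fits, radial coordinate system, pixel/physical transforms.

The expanding cell sheet is approximately circular.  The leading edges seen in
the two imaged regions of interest (ROIs) are fit to a circle per frame; the
fitted center defines a polar coordinate system whose outward radial unit
vector is the local "direction of expansion".  Physical coordinates are in
micrometres with y increasing upward; image rows increase downward, so
``y = stage_y - row * pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SheetGeometry",
    "fit_circle",
    "fit_sheet_geometry",
    "pixel_to_physical",
]


class CircleFitError(ValueError):
    """No unique circle through the supplied points."""


def pixel_to_physical(
    points_rc: np.ndarray, pixel_size: float, stage_position: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Map (row, col) pixel coordinates to physical (x, y) in µm.

    ``stage_position`` is the physical location of the image origin (pixel
    (0, 0)).  y increases upward, rows increase downward.
    """
    pts = np.asarray(points_rc, dtype=float)
    sx, sy = stage_position
    x = sx + pts[..., 1] * pixel_size
    y = sy - pts[..., 0] * pixel_size
    return np.stack([x, y], axis=-1)


def fit_circle(points_xy: np.ndarray) -> tuple[float, float, float]:
    """Least-squares (Kåsa) circle fit; returns (cx, cy, radius).

    Exact for points lying exactly on a circle.  Raises :class:`CircleFitError`
    for collinear or degenerate inputs.
    """
    pts = np.asarray(points_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise CircleFitError("need at least 3 points for a circle fit")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise CircleFitError("points are collinear: no unique circle")
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        raise CircleFitError("degenerate circle fit (non-positive radius)")
    return float(cx), float(cy), float(np.sqrt(r2))


@dataclass
class SheetGeometry:
    """Fitted sheet center (µm) and radius per frame (µm).

    ``radial_unit(p)`` returns the outward unit vector at physical point(s) p.
    """

    center: tuple[float, float]
    radius: np.ndarray  # R(t), µm, one entry per frame
    frame_interval: float = 3.0  # minutes

    def __post_init__(self) -> None:
        self.radius = np.atleast_1d(np.asarray(self.radius, dtype=float))
        if np.any(self.radius <= 0):
            raise ValueError("sheet radius must be positive")

    def radius_at(self, frame: int) -> float:
        return float(self.radius[frame])

    def radial_unit(self, points_xy: np.ndarray) -> np.ndarray:
        p = np.asarray(points_xy, dtype=float)
        d = p - np.asarray(self.center)
        n = np.linalg.norm(d, axis=-1, keepdims=True)
        if np.any(n == 0):
            raise ValueError("point coincides with the sheet center")
        return d / n

    def r_over_R(self, points_xy: np.ndarray, frame: int) -> np.ndarray:
        """Normalized radial coordinate r/R at a frame (1 = leading edge)."""
        p = np.asarray(points_xy, dtype=float)
        r = np.linalg.norm(p - np.asarray(self.center), axis=-1)
        return r / self.radius_at(frame)


def fit_sheet_geometry(
    edges_per_frame: Sequence[np.ndarray],
    frame_interval: float = 3.0,
) -> SheetGeometry:
    """Fit the sheet circle from pooled physical edge points per frame.

    ``edges_per_frame[t]`` holds the (N, 2) physical (x, y) points of the
    leading edge(s) at frame t — typically the two opposing ROIs mapped through
    :func:`pixel_to_physical` with their stage positions and concatenated.

    A circle is fit per frame; the center is then fixed as the temporal median
    of the per-frame centers and R(t) is the mean distance of each frame's
    points to that fixed center (identical to the per-frame radius for exact
    circles, more stable for short noisy arcs).
    """
    if len(edges_per_frame) == 0:
        raise ValueError("no edges supplied")
    centers = np.array([fit_circle(pts)[:2] for pts in edges_per_frame])
    center = (float(np.median(centers[:, 0])), float(np.median(centers[:, 1])))
    radius = np.array(
        [np.mean(np.linalg.norm(np.asarray(pts, float) - center, axis=1)) for pts in edges_per_frame]
    )
    return SheetGeometry(center=center, radius=radius, frame_interval=frame_interval)
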