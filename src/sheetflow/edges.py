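"""Leading-edge segmentation and geometry metrics.

The textured cell sheet is separated from the smooth background by
thresholding a smoothed Sobel texture-energy image, the leading edge is
traced as the minimum-cost 8-connected path along the mask boundary between
the two lateral image borders (Dijkstra), and edge length, complexity,
variability, signed Menger curvature and sheet displacement follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from skimage import filters, morphology

from .geometry import SheetGeometry

__all__ = [
    "EdgeCurve",
    "SegmentationConfig",
    "segment_sheet",
    "trace_leading_edge",
    "edge_length",
    "edge_statistics",
    "menger_curvature",
    "sheet_displacement",
]


class SegmentationError(RuntimeError):
    pass


class EdgeTracingError(RuntimeError):
    pass


@dataclass
class EdgeCurve:
    """Ordered leading-edge pixel path, left border to right border."""

    points: np.ndarray  # (N, 2) (row, col); traced paths are 8-connected
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (N, 2) (row, col)")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SegmentationConfig:
    """Tunable segmentation parameters (the operator families are fixed)."""

    energy_sigma: float = 1.5       # px, smoothing of the Sobel magnitude
    median_size: int = 5            # px, median filter footprint
    morph_radius: int = 3           # px, closing/opening disk radius
    edge_offset: int = 2            # px, erosion compensating the gradient response width
    class_ratio: float = 2.0        # min FG/BG texture-energy ratio for a real boundary
    texture_floor: float = 0.05     # median(E)/mean(img) above which a frame counts as textured


def segment_sheet(frame: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Binary mask of the textured (cell-covered) region of one frame.

    Sobel gradient magnitude → Gaussian-smoothed texture energy → Otsu
    threshold → median filter → morphological closing/opening → largest
    connected component → hole filling → small erosion re-centering the
    boundary on the intensity step.  If Otsu finds no real boundary
    (foreground/background energy ratio below ``class_ratio``) the frame is
    classified whole: fully textured frames return an all-true mask, blank
    frames raise :class:`SegmentationError`.
    """
    cfg = config or SegmentationConfig()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise SegmentationError("frame must be a non-empty 2-D image")
    if img.std() == 0:
        raise SegmentationError("constant image: nothing to segment")

    energy = ndimage.gaussian_filter(filters.sobel(img), cfg.energy_sigma)
    thr = filters.threshold_otsu(energy)
    bw = energy > thr
    fg, bg = energy[bw], energy[~bw]
    if fg.size == 0 or bg.size == 0 or fg.mean() < cfg.class_ratio * bg.mean():
        # no boundary in the frame: decide all-sheet vs no-sheet by texture level
        if np.median(energy) > cfg.texture_floor * abs(img.mean()):
            return np.ones_like(img, dtype=bool)
        raise SegmentationError("no textured region found in frame")

    bw = ndimage.median_filter(bw, size=cfg.median_size)
    selem = morphology.disk(cfg.morph_radius)
    bw = morphology.closing(bw, selem)
    bw = morphology.opening(bw, selem)
    labels, n = ndimage.label(bw)
    if n == 0:
        raise SegmentationError("no textured region found in frame")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    bw = labels == (1 + int(np.argmax(sizes)))
    bw = ndimage.binary_fill_holes(bw)
    if cfg.edge_offset:
        # the gradient response extends ~(Sobel support + energy_sigma) beyond
        # the true step; erode to re-center the boundary on it
        bw = morphology.erosion(bw, morphology.disk(cfg.edge_offset))
    return bw


_STEPS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def trace_leading_edge(mask: np.ndarray, frame_index: int = 0) -> EdgeCurve:
    """Minimum-cost boundary path between the lateral image borders.

    Nodes are boundary pixels of the mask (mask pixels 8-adjacent to
    background); edges connect 8-neighbors with weight 1 (axial) or √2
    (diagonal).  Endpoints are boundary pixels on the first and last columns;
    the overall cheapest pair is chosen.
    """
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    free = ~mask
    boundary = mask & ndimage.binary_dilation(free, structure=np.ones((3, 3), bool))
    ridx = np.flatnonzero(boundary.ravel())
    if ridx.size == 0:
        raise EdgeTracingError("mask has no boundary")
    pos = np.column_stack(np.unravel_index(ridx, mask.shape))
    node_of = -np.ones(mask.size, dtype=np.int64)
    node_of[ridx] = np.arange(ridx.size)

    left = np.flatnonzero(pos[:, 1] == 0)
    right = np.flatnonzero(pos[:, 1] == W - 1)
    if left.size == 0 or right.size == 0:
        raise EdgeTracingError("edge does not reach both lateral borders")

    rows_i, cols_j, weights = [], [], []
    for dr, dc in _STEPS:
        r2 = pos[:, 0] + dr
        c2 = pos[:, 1] + dc
        ok = (r2 >= 0) & (r2 < H) & (c2 >= 0) & (c2 < W)
        nb = node_of[r2[ok] * W + c2[ok]]
        src = np.flatnonzero(ok)[nb >= 0]
        dst = nb[nb >= 0]
        rows_i.append(src)
        cols_j.append(dst)
        weights.append(np.full(dst.size, np.sqrt(2.0) if dr and dc else 1.0))
    n = ridx.size
    graph = sparse.csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows_i), np.concatenate(cols_j))), shape=(n, n)
    )
    dist, pred = dijkstra(graph, directed=False, indices=left, return_predecessors=True)
    d_right = dist[:, right]
    if not np.isfinite(d_right).any():
        raise EdgeTracingError("no admissible path between lateral borders")
    i_src, i_dst = np.unravel_index(np.argmin(d_right), d_right.shape)
    path = [right[i_dst]]
    while pred[i_src, path[-1]] >= 0:
        path.append(pred[i_src, path[-1]])
    pts = pos[path[::-1]]
    if pts[0, 1] > pts[-1, 1]:
        pts = pts[::-1]
    return EdgeCurve(points=pts.astype(float), frame_index=frame_index)


def edge_length(edge: EdgeCurve, pixel_size: float = 1.0) -> float:
    """Summed distance between consecutive boundary points, µm."""
    pts = edge.points
    if len(pts) < 2:
        raise ValueError("edge needs at least two points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)) * pixel_size)


def edge_statistics(lengths: Sequence[float]) -> tuple[float, float]:
    """(complexity, variability): temporal mean and sample SD of edge length."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size < 2:
        raise ValueError("need edge lengths from at least two frames")
    return float(arr.mean()), float(arr.std(ddof=1))


def menger_curvature(
    edge: EdgeCurve, half_window: int = 40, pixel_size: float = 1.0
) -> np.ndarray:
    """Signed Menger curvature (1/µm) at interior edge points.

    For each point p with flanking points p± ``half_window`` indices away,
    the curvature magnitude is the reciprocal circumradius of the triangle
    (p₋, p, p₊); the sign is the orientation of the cross product in physical
    coordinates (x = col, y = −row), so with the edge ordered left-to-right
    and free space above, positive curvature bulges outward into free space.
    Points without a full window are excluded; collinear triples give 0.
    """
    pts = edge.points
    if len(pts) <= 2 * half_window:
        raise ValueError("edge shorter than the curvature window")
    xy = np.column_stack([pts[:, 1], -pts[:, 0]]) * pixel_size
    p_m = xy[: -2 * half_window]
    p_0 = xy[half_window:-half_window]
    p_p = xy[2 * half_window :]
    a = p_0 - p_m
    b = p_p - p_0
    c = p_p - p_m
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    la, lb, lc = (np.linalg.norm(v, axis=1) for v in (a, b, c))
    denom = la * lb * lc
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(denom > 0, 2.0 * cross / denom, 0.0)
    k[np.abs(cross) < 1e-12 * np.maximum(denom, 1e-300)] = 0.0
    return k


def sheet_displacement(geometry: SheetGeometry) -> float:
    """R(t_end) − R(t₀), µm; negative values indicate a shrinking sheet."""
    disp = float(geometry.radius[-1] - geometry.radius[0])
    if disp < 0:
        import logging

        logging.getLogger(__name__).info("sheet shrank by %.1f µm over the movie", -disp)
    return disp
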