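"""Nuclei counting and cell-density metrics from DAPI-style images.

Nuclei are localized Crocker–Grier style: a spatial bandpass suppresses
pixel noise below ~4 px and background structure above ~30 px, local maxima
of the bandpassed intensity above a fixed threshold are taken as candidate
nuclei, and each centroid is refined by an intensity-weighted mean in a
local window.  The bandpassed image keeps the raw intensity units, so the
peak threshold (default 6) is expressed on the camera's grey-level scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .geometry import SheetGeometry

__all__ = ["NucleiDetection", "detect_nuclei", "density_metrics"]


class DetectionError(RuntimeError):
    pass


@dataclass
class NucleiDetection:
    centroids: np.ndarray  # (n, 2) sub-pixel (row, col)
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        H, W = self.image_shape
        if self.centroids.size and (
            (self.centroids[:, 0] < 0).any() or (self.centroids[:, 0] > H - 1).any()
            or (self.centroids[:, 1] < 0).any() or (self.centroids[:, 1] > W - 1).any()
        ):
            raise ValueError("centroids outside image bounds")

    @property
    def count(self) -> int:
        return len(self.centroids)


def _bandpass(img: np.ndarray, low: float, high: float) -> np.ndarray:
    """Difference-of-Gaussians bandpass in raw intensity units, clipped ≥ 0."""
    g_small = ndimage.gaussian_filter(img, low / 2.0)
    g_large = ndimage.gaussian_filter(img, high / 2.0)
    return np.clip(g_small - g_large, 0, None)


def detect_nuclei(
    image: np.ndarray,
    low_pass: float = 4.0,
    high_pass: float = 30.0,
    peak_threshold: float = 6.0,
    min_separation: Optional[int] = None,
    refine_radius: int = 4,
) -> NucleiDetection:
    """Locate nuclear centroids by bandpass filtering and peak finding.

    ``low_pass`` / ``high_pass`` are the feature-size limits in px (features
    smaller than the former or larger than the latter are suppressed);
    ``peak_threshold`` applies to the bandpassed intensity.  Minimum peak
    separation defaults to twice the low-pass size.  Centroids are refined to
    sub-pixel precision by an intensity-weighted mean within
    ``refine_radius`` px.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[0]
    if img.size == 0:
        raise DetectionError("empty image")
    if img.std() == 0:
        raise DetectionError("constant or saturated image")
    sep = min_separation if min_separation is not None else int(2 * low_pass)
    bp = _bandpass(img, low_pass, high_pass)
    # circular exclusion zone: a square min_distance footprint would also
    # suppress diagonal neighbors out to sep·√2
    from skimage.morphology import disk

    peaks = peak_local_max(bp, footprint=disk(sep), threshold_abs=peak_threshold, exclude_border=False)
    if len(peaks) == 0:
        return NucleiDetection(centroids=np.empty((0, 2)), image_shape=img.shape)

    H, W = img.shape
    refined = np.empty((len(peaks), 2))
    for k, (r, c) in enumerate(peaks):
        r_lo, r_hi = max(0, r - refine_radius), min(H, r + refine_radius + 1)
        c_lo, c_hi = max(0, c - refine_radius), min(W, c + refine_radius + 1)
        win = bp[r_lo:r_hi, c_lo:c_hi]
        tot = win.sum()
        if tot <= 0:
            refined[k] = (r, c)
            continue
        rr = np.arange(r_lo, r_hi)[:, None]
        cc = np.arange(c_lo, c_hi)[None, :]
        refined[k] = ((win * rr).sum() / tot, (win * cc).sum() / tot)
    # merge duplicates from intensity plateaus: keep the brighter of any two
    # refined centroids closer than half the separation limit
    order = np.argsort(-bp[peaks[:, 0], peaks[:, 1]])
    kept: list[int] = []
    for k in order:
        if all(np.hypot(*(refined[k] - refined[j])) >= sep / 2 for j in kept):
            kept.append(k)
    refined = refined[sorted(kept)]
    return NucleiDetection(centroids=refined, image_shape=img.shape)


def density_metrics(
    det_t0: NucleiDetection,
    det_t15: NucleiDetection,
    geometry: SheetGeometry,
    pixel_size: float,
    sheet_mask: Optional[np.ndarray] = None,
    bin_width: float = 0.05,
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """(fold_change, average_density, radial density profile).

    Fold change is the t = 15 h count over the t = 0 h count; average density
    is the t = 0 h count divided by the sheet area (the mask area if a mask
    is given, else the fitted circle's area), in cells/µm².  The radial
    profile divides per-annulus counts (r/R bins of ``bin_width``, using the
    t = 0 h detection) by annulus area.
    """
    if det_t0.count == 0:
        raise ValueError("zero nuclei at t = 0: fold change undefined")
    fold = det_t15.count / det_t0.count

    R = geometry.radius_at(0)
    if sheet_mask is not None:
        area = float(sheet_mask.sum()) * pixel_size**2
    else:
        area = np.pi * R**2
    avg_density = det_t0.count / area

    # physical radii of centroids about the sheet center
    cx, cy = geometry.center
    x = det_t0.centroids[:, 1] * pixel_size
    y = -det_t0.centroids[:, 0] * pixel_size
    rr = np.hypot(x - cx, y - cy) / R
    n_bins = int(np.ceil(1.0 / bin_width))
    counts = np.zeros(n_bins)
    inside = rr < 1.0
    b = np.minimum((rr[inside] / bin_width).astype(int), n_bins - 1)
    np.add.at(counts, b, 1)
    edges_ = np.arange(n_bins + 1) * bin_width
    annulus_area = np.pi * R**2 * (edges_[1:] ** 2 - edges_[:-1] ** 2)
    profile = counts / annulus_area
    centers = (edges_[:-1] + edges_[1:]) / 2
    return float(fold), float(avg_density), (centers, profile)
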