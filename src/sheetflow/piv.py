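"""Multipass FFT cross-correlation particle image velocimetry.

Velocity fields are estimated from image pairs by windowed cross-correlation
of texture, in the style of the MatPIV toolbox's basic multipass mode: two
passes with 64 px windows followed by two with 32 px windows, 50 % overlap,
each pass offsetting the search windows by the previous pass's (integer)
displacement estimate.  No window deformation is applied.

Conventions
-----------
* Window of size ``w`` number ``k`` along an axis covers pixels
  ``[k*w/2, k*w/2 + w)`` and its center is at ``k*w/2 + w/2`` (so for
  w = 32 the centers are 16, 32, 48, ...).  Windows extending past the image
  are discarded, not padded.
* ``u`` is velocity along +columns, ``v`` along physical +y (i.e. *up* the
  image, −rows), in µm/min.
* Sub-pixel peak location by a three-point Gaussian fit.
* SNR is the ratio of the highest correlation peak to the second-highest
  peak outside a 3 px exclusion zone around the first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import RegularGridInterpolator

from .geometry import SheetGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "FlowField",
    "FlowFieldSequence",
    "multipass_piv",
    "validate_and_fill",
    "piv_grid",
    "window_physical_size",
]


class PIVError(RuntimeError):
    pass


@dataclass
class FlowField:
    """One gridded velocity field (µm and µm/min)."""

    x: np.ndarray  # (nx,) window-center x positions, µm
    y: np.ndarray  # (ny,) window-center y positions, µm (physical, y up)
    u: np.ndarray  # (ny, nx) µm/min, +x
    v: np.ndarray  # (ny, nx) µm/min, +y
    snr: np.ndarray  # (ny, nx)
    valid: np.ndarray  # (ny, nx) bool
    grid_rows: Optional[np.ndarray] = None  # window-center rows, px
    grid_cols: Optional[np.ndarray] = None  # window-center cols, px

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.u.shape != self.v.shape or self.u.shape != self.valid.shape:
            raise ValueError("u, v, valid must share one grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def sites(self) -> np.ndarray:
        """(ny*nx, 2) physical (x, y) site positions."""
        X, Y = np.meshgrid(self.x, self.y)
        return np.column_stack([X.ravel(), Y.ravel()])

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class FlowFieldSequence:
    """Time-ordered flow fields sharing one grid."""

    fields: list[FlowField]
    frame_interval: float  # minutes
    geometry: Optional[SheetGeometry] = None

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValueError("empty sequence")
        shp = self.fields[0].shape
        for f in self.fields:
            if f.shape != shp:
                raise ValueError("all fields must share one grid")

    def __len__(self) -> int:
        return len(self.fields)

    @property
    def x(self) -> np.ndarray:
        return self.fields[0].x

    @property
    def y(self) -> np.ndarray:
        return self.fields[0].y

    @property
    def grid_spacing(self) -> float:
        return float(abs(np.diff(self.x).mean()))

    def u_stack(self) -> np.ndarray:
        return np.stack([f.u for f in self.fields])

    def v_stack(self) -> np.ndarray:
        return np.stack([f.v for f in self.fields])

    def valid_stack(self) -> np.ndarray:
        return np.stack([f.valid for f in self.fields])


def piv_grid(shape: tuple[int, int], window: int, overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Window-center (rows, cols) in px for windows fully inside ``shape``."""
    step = int(round(window * (1 - overlap)))
    if step <= 0:
        raise ValueError("overlap too large")
    starts_r = np.arange(0, shape[0] - window + 1, step)
    starts_c = np.arange(0, shape[1] - window + 1, step)
    return starts_r + window / 2, starts_c + window / 2


def window_physical_size(window_px: int, pixel_size: float) -> float:
    """Physical side length of a PIV interrogation window, µm."""
    return window_px * pixel_size


def _correlate_windows(wins_a: np.ndarray, wins_b: np.ndarray) -> np.ndarray:
    """Batched linear cross-correlation maps, shape (n, 2w-1, 2w-1).

    Map index (w-1+dy, w-1+dx) corresponds to B displaced by (dy, dx)
    relative to A.  Window means are subtracted first.
    """
    n, w, _ = wins_a.shape
    a = wins_a - wins_a.mean(axis=(1, 2), keepdims=True)
    b = wins_b - wins_b.mean(axis=(1, 2), keepdims=True)
    size = 2 * w
    fa = np.fft.rfft2(a, s=(size, size))
    fb = np.fft.rfft2(b, s=(size, size))
    corr = np.fft.irfft2(fb * np.conj(fa), s=(size, size))
    # reorder circular lags to [-(w-1), w-1]
    corr = np.roll(corr, (w - 1, w - 1), axis=(1, 2))[:, : 2 * w - 1, : 2 * w - 1]
    # unbiased normalization: divide by the overlap area per lag, otherwise the
    # zero-padding envelope pulls the peak (and the sub-pixel fit) toward zero
    lags = np.arange(-(w - 1), w)
    overlap = (w - np.abs(lags))[:, None] * (w - np.abs(lags))[None, :]
    return corr / overlap


def _subpixel(c_m: float, c_0: float, c_p: float) -> float:
    """Three-point Gaussian peak interpolation along one axis."""
    eps = 1e-12
    lm, l0, lp = (np.log(max(c, eps)) for c in (c_m, c_0, c_p))
    denom = 2.0 * (lm + lp - 2.0 * l0)
    if denom >= -1e-15:  # not a local max in log space
        return 0.0
    d = (lm - lp) / denom
    return float(np.clip(d, -1.0, 1.0))


def _peak_and_snr(corr: np.ndarray, search: int, exclusion: int = 3) -> tuple[float, float, float, bool]:
    """Locate the correlation peak with sub-pixel refinement and compute SNR.

    ``search`` limits |displacement| to avoid spurious wrap-region peaks.
    Returns (dy, dx, snr, ok).
    """
    w1 = corr.shape[0]  # 2w-1
    c0 = w1 // 2
    lo, hi = c0 - search, c0 + search + 1
    region = corr[lo:hi, lo:hi]
    idx = np.unravel_index(np.argmax(region), region.shape)
    pi, pj = idx[0] + lo, idx[1] + lo
    peak = corr[pi, pj]
    if peak <= 0:
        return 0.0, 0.0, 0.0, False
    if 0 < pi < w1 - 1:
        dy_sub = _subpixel(corr[pi - 1, pj], peak, corr[pi + 1, pj])
    else:
        dy_sub = 0.0
    if 0 < pj < w1 - 1:
        dx_sub = _subpixel(corr[pi, pj - 1], peak, corr[pi, pj + 1])
    else:
        dx_sub = 0.0
    masked = corr.copy()
    masked[max(0, pi - exclusion) : pi + exclusion + 1, max(0, pj - exclusion) : pj + exclusion + 1] = -np.inf
    second = masked[lo:hi, lo:hi].max()
    snr = float(peak / second) if second > 0 else np.inf
    return pi - c0 + dy_sub, pj - c0 + dx_sub, snr, True


def _single_pass(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window: int,
    offsets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One correlation pass with per-window integer offsets (dy, dx) applied to B."""
    rows_c, cols_c = piv_grid(frame_a.shape, window)
    ny, nx = len(rows_c), len(cols_c)
    starts_r = (rows_c - window / 2).astype(int)
    starts_c = (cols_c - window / 2).astype(int)

    wins_a = []
    wins_b = []
    ok = np.zeros((ny, nx), dtype=bool)
    H, W = frame_a.shape
    for i, r0 in enumerate(starts_r):
        for j, c0 in enumerate(starts_c):
            dy, dx = int(offsets[i, j, 0]), int(offsets[i, j, 1])
            rb, cb = r0 + dy, c0 + dx
            if rb < 0 or cb < 0 or rb + window > H or cb + window > W:
                wins_a.append(np.zeros((window, window)))
                wins_b.append(np.zeros((window, window)))
                continue
            wa = frame_a[r0 : r0 + window, c0 : c0 + window]
            wb = frame_b[rb : rb + window, cb : cb + window]
            if wa.std() == 0 or wb.std() == 0:  # texture-free window
                wins_a.append(np.zeros((window, window)))
                wins_b.append(np.zeros((window, window)))
                continue
            wins_a.append(wa)
            wins_b.append(wb)
            ok[i, j] = True

    corr = _correlate_windows(np.array(wins_a, dtype=float), np.array(wins_b, dtype=float))
    disp = np.zeros((ny, nx, 2))
    snr = np.zeros((ny, nx))
    search = window // 2
    k = 0
    for i in range(ny):
        for j in range(nx):
            if ok[i, j]:
                dy, dx, s, good = _peak_and_snr(corr[k], search)
                if good:
                    disp[i, j] = offsets[i, j] + (dy, dx)
                    snr[i, j] = s
                else:
                    ok[i, j] = False
            k += 1
    return rows_c, cols_c, disp, snr, ok


def _interp_field(rows_old, cols_old, disp_old, ok_old, rows_new, cols_new) -> np.ndarray:
    """Linearly interpolate a displacement field onto a finer grid."""
    filled = disp_old.copy()
    for comp in range(2):
        layer = filled[..., comp]
        if not ok_old.all():
            m = float(np.nanmean(np.where(ok_old, layer, np.nan))) if ok_old.any() else 0.0
            layer[~ok_old] = m
    out = np.zeros((len(rows_new), len(cols_new), 2))
    Rn, Cn = np.meshgrid(rows_new, cols_new, indexing="ij")
    pts = np.column_stack([Rn.ravel(), Cn.ravel()])
    for comp in range(2):
        itp = RegularGridInterpolator(
            (rows_old, cols_old), filled[..., comp], bounds_error=False, fill_value=None
        )
        out[..., comp] = itp(pts).reshape(Rn.shape)
    return out


def multipass_piv(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    windows: Sequence[int] = (64, 64, 32, 32),
    mask: Optional[np.ndarray] = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> FlowField:
    """Estimate a velocity field between two frames.

    Parameters
    ----------
    pixel_size, frame_interval:
        Calibration; with the defaults (1, 1) displacements are returned in
        px/frame.
    windows:
        Interrogation window sizes per pass; default two 64 px passes then
        two 32 px passes, all at 50 % overlap (final grid spacing 16 px).
    mask:
        Optional binary sheet mask; vectors whose interrogation window lies
        entirely outside it are marked invalid.
    origin:
        Physical (x, y) of pixel (0, 0), µm.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share a shape")
    if min(frame_a.shape) < max(windows):
        raise ValueError("frames smaller than the largest interrogation window")

    rows_c = cols_c = None
    disp = snr = ok = None
    prev = None  # (rows, cols, disp, ok)
    for w in windows:
        g_rows, g_cols = piv_grid(frame_a.shape, w)
        if prev is None:
            offsets = np.zeros((len(g_rows), len(g_cols), 2))
        else:
            offsets = np.rint(_interp_field(*prev, g_rows, g_cols))
        rows_c, cols_c, disp, snr, ok = _single_pass(frame_a, frame_b, w, offsets)
        prev = (rows_c, cols_c, disp, ok)

    if mask is not None:
        w = windows[-1]
        for i, rc in enumerate(rows_c):
            for j, cc in enumerate(cols_c):
                r0, c0 = int(rc - w / 2), int(cc - w / 2)
                if not mask[r0 : r0 + w, c0 : c0 + w].any():
                    ok[i, j] = False

    scale = pixel_size / frame_interval
    u = disp[..., 1] * scale          # +columns -> +x
    v = -disp[..., 0] * scale         # +rows -> -y
    x = origin[0] + cols_c * pixel_size
    y = origin[1] - rows_c * pixel_size
    return FlowField(x=x, y=y, u=u, v=v, snr=snr, valid=ok, grid_rows=rows_c, grid_cols=cols_c)


def validate_and_fill(field: FlowField, snr_threshold: float = 1.3) -> FlowField:
    """SNR-filter outliers and fill them from valid neighbors.

    Vectors with SNR below ``snr_threshold`` are marked invalid and replaced
    by the component-wise median of their valid 8-neighbors (left invalid if
    no valid neighbor exists).  A field with more than half its vectors
    invalid is logged as a warning.
    """
    valid = field.valid & (field.snr >= snr_threshold)
    ny, nx = valid.shape
    u = field.u.copy()
    v = field.v.copy()
    filled = valid.copy()
    n_replaced = 0
    for i in range(ny):
        for j in range(nx):
            if valid[i, j]:
                continue
            nb_u, nb_v = [], []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < ny and 0 <= jj < nx and valid[ii, jj]:
                        nb_u.append(field.u[ii, jj])
                        nb_v.append(field.v[ii, jj])
            if nb_u:
                u[i, j] = np.median(nb_u)
                v[i, j] = np.median(nb_v)
                filled[i, j] = True
                n_replaced += 1
    n_prior = max(int(field.valid.sum()), 1)
    frac_bad = 1.0 - valid.sum() / n_prior
    if frac_bad > 0.5:
        logger.warning("more than 50%% of vectors failed the SNR filter (%.0f%%)", 100 * frac_bad)
    if n_replaced:
        logger.info("replaced %d/%d low-SNR vectors", n_replaced, valid.size)
    return FlowField(
        x=field.x, y=field.y, u=u, v=v, snr=field.snr, valid=filled,
        grid_rows=field.grid_rows, grid_cols=field.grid_cols,
    )
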