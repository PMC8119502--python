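"""Velocity-field statistics for collective migration.

Metrics computed from a :class:`~sheetflow.piv.FlowFieldSequence`:

* mean speed over time and space;
* direction angles relative to the outward radial direction and their
  circular dispersion, the angular deviation √(2(1−z)) with z the mean
  resultant length — 0 for perfectly aligned motion, √2 for uniformly
  dispersed directions;
* spatial autocorrelation of the radial velocity component,
  C(Δr) = Σ v(rᵢ)·v(rᵢ+Δr) / √(Σ v²(rᵢ) Σ v²(rᵢ+Δr)), and the local
  coordination C(100 µm);
* finite-time Lyapunov exponents λ from virtual tracers advected through the
  time-evolving field (λ = log largest eigenvalue of the Cauchy–Green strain
  tensor C = FᵀF over a 2 h deformation window) and the percentage of
  positive λ as a measure of chaotic motion;
* characteristic time and length scales from the decay of flow-field variance
  under temporal / spatial coarse-graining, fit to
  σ = A·e^(−t/t_c) + B/√(t/t_imaging) + C   and   σ = A·e^(−l/l_c) + B;
* radial (r/R) profiles in bins of 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .geometry import SheetGeometry
from .piv import FlowFieldSequence

logger = logging.getLogger(__name__)

__all__ = [
    "DirectionSample",
    "AutocorrelationCurve",
    "FTLEMap",
    "ScaleFit",
    "mean_speed",
    "radial_direction_angles",
    "angular_deviation",
    "radial_velocity_autocorrelation",
    "local_coordination",
    "ftle",
    "percent_positive",
    "characteristic_time_scale",
    "characteristic_length_scale",
    "temporal_coarse_grain_curve",
    "spatial_coarse_grain_curve",
    "fit_time_scale_curve",
    "fit_length_scale_curve",
    "radial_profile",
]

#: λ values above this count as positive (absorbs floating-point noise).
POSITIVE_EPS = 1e-6


class MetricError(RuntimeError):
    pass


class FitError(RuntimeError):
    pass


@dataclass
class DirectionSample:
    """Angles (rad) between velocity vectors and the local outward direction."""

    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float).ravel()
        if self.angles.size < 1:
            raise MetricError("empty direction sample")

    @property
    def n(self) -> int:
        return self.angles.size

    def cumulative(self, n_points: int = 181) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative distribution of |θ| over [0, π]."""
        grid = np.linspace(0, np.pi, n_points)
        a = np.sort(np.abs(self.angles))
        frac = np.searchsorted(a, grid, side="right") / a.size
        return grid, frac


@dataclass
class AutocorrelationCurve:
    delta_r: np.ndarray  # bin centers, µm
    c: np.ndarray  # correlation per bin (nan where no pairs)
    pair_counts: np.ndarray


@dataclass
class FTLEMap:
    """λ per tracer quad per deformation window."""

    lam: np.ndarray  # (n_windows, ny-1, nx-1)
    valid: np.ndarray
    deformation_time: float  # minutes
    x: np.ndarray  # (nx-1,) quad anchor positions, µm
    y: np.ndarray


@dataclass
class ScaleFit:
    scale: float  # t_c (min) or l_c (µm); nan when degenerate
    amplitude: float
    offset: float
    stage_coeff: float  # B of the time fit; 0 for the length fit
    residual: float
    degenerate: bool
    grid: np.ndarray  # averaging windows (min or µm)
    sigma: np.ndarray  # measured variance curve


# ---------------------------------------------------------------------------


def mean_speed(seq: FlowFieldSequence) -> float:
    """Mean PIV speed over time and space (valid vectors only), µm/min."""
    u, v, ok = seq.u_stack(), seq.v_stack(), seq.valid_stack()
    if not ok.any():
        raise MetricError("no valid vectors")
    return float(np.hypot(u[ok], v[ok]).mean())


def radial_direction_angles(seq: FlowFieldSequence, geometry: Optional[SheetGeometry] = None) -> DirectionSample:
    """Signed angle from the outward radial direction to each velocity vector.

    Counterclockwise-positive in physical (x, y); vectors with zero speed and
    sites coincident with the sheet center are skipped; pooled over frames.
    """
    geom = geometry or seq.geometry
    if geom is None:
        raise MetricError("no sheet geometry available")
    sites = seq.fields[0].sites()
    rel = sites - np.asarray(geom.center)
    rnorm = np.linalg.norm(rel, axis=1)
    ok_site = rnorm > 0
    e = np.zeros_like(rel)
    e[ok_site] = rel[ok_site] / rnorm[ok_site, None]

    angles = []
    for f in seq.fields:
        u, v = f.u.ravel(), f.v.ravel()
        speed = np.hypot(u, v)
        keep = f.valid.ravel() & ok_site & (speed > 0)
        th = np.arctan2(e[keep, 0] * v[keep] - e[keep, 1] * u[keep],
                        e[keep, 0] * u[keep] + e[keep, 1] * v[keep])
        angles.append(th)
    return DirectionSample(angles=np.concatenate(angles))


def angular_deviation(sample: DirectionSample | np.ndarray) -> float:
    """Circular dispersion √(2(1−z)); z is the mean resultant length."""
    th = sample.angles if isinstance(sample, DirectionSample) else np.asarray(sample, float).ravel()
    if th.size < 1:
        raise MetricError("empty direction sample")
    z = np.hypot(np.cos(th).sum(), np.sin(th).sum()) / th.size
    z = min(z, 1.0)  # guard rounding for perfectly aligned samples
    return float(np.sqrt(2.0 * (1.0 - z)))


# ---------------------------------------------------------------------------


def radial_velocity_autocorrelation(
    seq: FlowFieldSequence,
    geometry: Optional[SheetGeometry] = None,
    bin_width: Optional[float] = None,
) -> AutocorrelationCurve:
    """Spatial autocorrelation of the radial velocity component.

    For each unordered site pair {i, j} at separation Δr the numerator
    accumulates v(rᵢ)·v(rⱼ) and the denominator √(Σv²(rᵢ)·Σv²(rⱼ)) over the
    pair members; bins are one grid spacing wide, C is computed per frame and
    averaged over frames.  C(0) = 1 by construction; bins without pairs are
    returned as NaN.
    """
    geom = geometry or seq.geometry
    if geom is None:
        raise MetricError("no sheet geometry available")
    if bin_width is None:
        bin_width = seq.grid_spacing
    sites_all = seq.fields[0].sites()
    e_all = geom.radial_unit(sites_all)

    max_sep = np.hypot(np.ptp(sites_all[:, 0]), np.ptp(sites_all[:, 1]))
    n_bins = int(np.floor(max_sep / bin_width + 0.5)) + 1  # bins round to nearest
    num = np.zeros(n_bins)
    den_a = np.zeros(n_bins)
    den_b = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    c_sum = np.zeros(n_bins)
    c_n = np.zeros(n_bins, dtype=np.int64)

    cached_bins = None
    cached_key = None
    for f in seq.fields:
        keep = f.valid.ravel()
        if keep.sum() < 2:
            raise MetricError("need at least two valid vectors per frame")
        key = keep.tobytes()
        pts = sites_all[keep]
        vr = (f.u.ravel()[keep] * e_all[keep, 0] + f.v.ravel()[keep] * e_all[keep, 1])
        if key != cached_key:
            d = pdist(pts)
            iu, ju = np.triu_indices(len(pts), k=1)
            cached_bins = (np.minimum((d / bin_width + 0.5).astype(np.int64), n_bins - 1), iu, ju)
            cached_key = key
        bins, iu, ju = cached_bins

        num.fill(0.0); den_a.fill(0.0); den_b.fill(0.0); counts.fill(0)
        np.add.at(num, bins, vr[iu] * vr[ju])
        np.add.at(den_a, bins, vr[iu] ** 2)
        np.add.at(den_b, bins, vr[ju] ** 2)
        np.add.at(counts, bins, 1)
        # self-pairs populate the zero bin: C(0) = 1 exactly
        num[0] += (vr**2).sum()
        den_a[0] += (vr**2).sum()
        den_b[0] += (vr**2).sum()
        counts[0] += len(vr)

        with np.errstate(divide="ignore", invalid="ignore"):
            c = num / np.sqrt(den_a * den_b)
        good = (counts > 0) & np.isfinite(c)
        c_sum[good] += c[good]
        c_n[good] += 1
        c_n_counts = counts  # last frame's counts are representative (shared grid)

    with np.errstate(invalid="ignore"):
        c_mean = np.where(c_n > 0, c_sum / np.maximum(c_n, 1), np.nan)
    centers = np.arange(n_bins) * bin_width
    return AutocorrelationCurve(delta_r=centers, c=c_mean, pair_counts=c_n_counts)


def local_coordination(curve: AutocorrelationCurve, radius: float = 100.0) -> float:
    """Autocorrelation linearly interpolated at Δr = ``radius`` µm."""
    ok = np.isfinite(curve.c)
    dr, c = curve.delta_r[ok], curve.c[ok]
    spacing = np.diff(curve.delta_r).mean() if len(curve.delta_r) > 1 else np.inf
    if not np.any(np.abs(dr - radius) <= spacing):
        raise MetricError(f"no populated autocorrelation bins within one spacing of {radius} µm")
    return float(np.interp(radius, dr, c))


# ---------------------------------------------------------------------------
# FTLE


def _bilinear(x_grid, y_grid, comp, pts):
    """Bilinear interpolation of one velocity component at physical points.

    Points outside the grid bounding box return NaN.
    """
    x, y = pts[:, 0], pts[:, 1]
    nx, ny = len(x_grid), len(y_grid)
    fx = (x - x_grid[0]) / (x_grid[1] - x_grid[0])
    fy = (y - y_grid[0]) / (y_grid[1] - y_grid[0])
    out = np.full(len(pts), np.nan)
    ok = (fx >= 0) & (fx <= nx - 1) & (fy >= 0) & (fy <= ny - 1)
    i = np.clip(np.floor(fx[ok]).astype(int), 0, nx - 2)
    j = np.clip(np.floor(fy[ok]).astype(int), 0, ny - 2)
    tx = fx[ok] - i
    ty = fy[ok] - j
    c = comp
    out[ok] = (
        c[j, i] * (1 - tx) * (1 - ty)
        + c[j, i + 1] * tx * (1 - ty)
        + c[j + 1, i] * (1 - tx) * ty
        + c[j + 1, i + 1] * tx * ty
    )
    return out


def ftle(
    seq: FlowFieldSequence,
    deformation_time: float = 120.0,
    integrator: str = "euler",
) -> FTLEMap:
    """Finite-time Lyapunov exponents of the flow.

    Virtual tracers are seeded on the PIV grid and advected through the
    time-evolving field (bilinear in space, piecewise-constant in time, one
    explicit-Euler — or RK4 — step per frame) over non-overlapping windows of
    ``deformation_time``.  For each quad of four initially neighboring
    tracers the deformation gradient F is estimated by central differences of
    final positions, and λ = ln(largest eigenvalue of FᵀF).  Quads whose
    tracers leave the interpolable domain are invalid.
    """
    dt = seq.frame_interval
    n_steps = int(round(deformation_time / dt))
    if n_steps < 1 or len(seq) < n_steps:
        raise MetricError("sequence shorter than the deformation time")
    n_windows = len(seq) // n_steps
    x, y = seq.x, seq.y
    # interpolation expects ascending grids
    ysort = np.argsort(y)
    y_s = y[ysort]
    X0, Y0 = np.meshgrid(x, y)
    p0 = np.column_stack([X0.ravel(), Y0.ravel()])
    ny, nx = len(y), len(x)
    dx = float(x[1] - x[0]) if nx > 1 else 1.0
    dy = float(y[1] - y[0]) if ny > 1 else 1.0

    lam = np.full((n_windows, ny - 1, nx - 1), np.nan)
    valid = np.zeros((n_windows, ny - 1, nx - 1), dtype=bool)

    for w in range(n_windows):
        pos = p0.copy()
        for s in range(n_steps):
            f = seq.fields[w * n_steps + s]
            u_s = f.u[ysort]
            v_s = f.v[ysort]

            def vel(p):
                return np.column_stack([
                    _bilinear(x, y_s, u_s, p),
                    _bilinear(x, y_s, v_s, p),
                ])

            if integrator == "rk4":
                k1 = vel(pos)
                k2 = vel(pos + 0.5 * dt * k1)
                k3 = vel(pos + 0.5 * dt * k2)
                k4 = vel(pos + dt * k3)
                pos = pos + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            else:
                pos = pos + dt * vel(pos)

        P = pos.reshape(ny, nx, 2)
        # quad (i,j),(i,j+1),(i+1,j),(i+1,j+1): least-squares F = central differences
        d_dx = 0.5 * (P[:-1, 1:] - P[:-1, :-1] + P[1:, 1:] - P[1:, :-1]) / dx
        d_dy = 0.5 * (P[1:, :-1] - P[:-1, :-1] + P[1:, 1:] - P[:-1, 1:]) / dy
        # F = [[dX/dx, dX/dy], [dY/dx, dY/dy]]; eigenvalues of C = FᵀF
        a = d_dx[..., 0]; b = d_dy[..., 0]; c = d_dx[..., 1]; d = d_dy[..., 1]
        c11 = a * a + c * c
        c12 = a * b + c * d
        c22 = b * b + d * d
        tr = c11 + c22
        disc = np.sqrt(np.maximum((c11 - c22) ** 2 + 4 * c12**2, 0.0))
        eig_max = 0.5 * (tr + disc)
        with np.errstate(divide="ignore", invalid="ignore"):
            lw = np.log(eig_max)
        ok = np.isfinite(lw)
        lam[w][ok] = lw[ok]
        valid[w] = ok

    frac_invalid = 1.0 - valid.mean()
    if frac_invalid > 0.8:
        raise MetricError(f"{100*frac_invalid:.0f}% of tracer quads left the domain")
    return FTLEMap(lam=lam, valid=valid, deformation_time=deformation_time, x=x[:-1], y=y[:-1])


def percent_positive(ftle_map: FTLEMap) -> float:
    """Percentage of valid λ values above zero (chaotic-motion measure)."""
    ok = ftle_map.valid
    if not ok.any():
        raise MetricError("no valid λ values")
    return float(100.0 * (ftle_map.lam[ok] > POSITIVE_EPS).mean())


# ---------------------------------------------------------------------------
# coarse-graining scales


def _field_stack(seq: FlowFieldSequence) -> np.ndarray:
    """(T, ny, nx, 2) with invalid vectors as NaN."""
    u, v, ok = seq.u_stack(), seq.v_stack(), seq.valid_stack()
    out = np.stack([u, v], axis=-1).astype(float)
    out[~ok] = np.nan
    return out


def _multistart_fit(model, sigma, grid, scale_candidates, n_params) -> tuple[np.ndarray, float]:
    best = None
    for s0 in scale_candidates:
        x0 = np.array([max(sigma[0] - sigma[-1], 1e-12), s0, *([max(sigma[-1], 1e-12)] * (n_params - 2))])
        try:
            res = least_squares(
                lambda p: model(p, grid) - sigma, x0,
                bounds=(np.zeros(n_params), np.full(n_params, np.inf)),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("nonlinear fit did not converge from any start")
    return best.x, float(best.cost)


def temporal_coarse_grain_curve(
    seq: FlowFieldSequence, max_window: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """σ(t): flow-field variance after time-averaging over windows of t.

    The field is averaged per site over every sliding window of t frames;
    the variance over sites and components is computed per window placement
    and averaged over placements.  Returns (t in minutes, σ).
    """
    F = _field_stack(seq)
    T = F.shape[0]
    K = max_window if max_window is not None else max(T // 2, 2)
    if K < 8:
        raise MetricError("need at least 8 distinct averaging intervals")
    S = np.nancumsum(np.concatenate([np.zeros((1, *F.shape[1:])), F], axis=0), axis=0)
    sigma = np.empty(K)
    for k in range(1, K + 1):
        means = (S[k:] - S[:-k]) / k  # (T-k+1, ny, nx, 2) window means per placement
        var = np.nanvar(means.reshape(means.shape[0], -1), axis=1)
        sigma[k - 1] = var.mean()
    return np.arange(1, K + 1) * seq.frame_interval, sigma


def spatial_coarse_grain_curve(
    seq: FlowFieldSequence,
    max_block: Optional[int] = None,
    block_sizes: Optional[Sequence[int]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """σ(l): flow-field variance after block-averaging over squares of side l.

    Returns (l in µm, σ), with σ the variance of the block means over
    blocks and components, averaged over frames.  ``block_sizes`` (in grid
    sites) overrides the default 1..max_block range — e.g. to use fit windows
    proportional to the expected scale when comparing two conditions.
    """
    F = _field_stack(seq)
    T, ny, nx, _ = F.shape
    if min(ny, nx) < 16:
        raise MetricError("grid too small for spatial coarse-graining (need ≥ 16 sites per axis)")
    if block_sizes is None:
        Kb = max_block if max_block is not None else min(ny, nx) // 4
        block_sizes = range(1, Kb + 1)
    sizes = [int(b) for b in block_sizes]
    sigma = np.empty(len(sizes))
    for i, b in enumerate(sizes):
        my, mx = (ny // b) * b, (nx // b) * b
        if my == 0 or mx == 0:
            raise MetricError(f"block size {b} exceeds the grid")
        blocks = F[:, :my, :mx].reshape(T, my // b, b, mx // b, b, 2)
        means = np.nanmean(blocks, axis=(2, 4))
        sigma[i] = np.nanvar(means.reshape(T, -1), axis=1).mean()
    return np.array(sizes) * seq.grid_spacing, sigma


def fit_time_scale_curve(t_grid: np.ndarray, sigma: np.ndarray, t_imaging: float) -> ScaleFit:
    """Fit σ = A·e^(−t/t_c) + B/√(t/t_imaging) + C, all parameters ≥ 0.

    Trust-region nonlinear least squares from 5 log-spaced t_c starts.  A
    curve with < 5 % relative decay is degenerate (t_c unidentifiable).
    """
    t_grid = np.asarray(t_grid, float)
    sigma = np.asarray(sigma, float)
    if sigma[0] <= 0 or (sigma[0] - sigma.min()) < 0.05 * sigma[0]:
        logger.warning("σ(t) is nearly constant: t_c unidentifiable")
        return ScaleFit(np.nan, np.nan, float(sigma.mean()), 0.0, 0.0, True, t_grid, sigma)

    def model(p, t):
        A, tc, B, C = p
        return A * np.exp(-t / tc) + B / np.sqrt(t / t_imaging) + C

    starts = np.geomspace(t_grid[0], t_grid[-1] * 2, 5)
    p, cost = _multistart_fit(model, sigma, t_grid, starts, 4)
    return ScaleFit(float(p[1]), float(p[0]), float(p[3]), float(p[2]), cost, False, t_grid, sigma)


def fit_length_scale_curve(l_grid: np.ndarray, sigma: np.ndarray, spacing: Optional[float] = None) -> ScaleFit:
    """Fit σ = A·e^(−l/l_c) + B, parameters ≥ 0 (multi-start as above)."""
    l_grid = np.asarray(l_grid, float)
    sigma = np.asarray(sigma, float)
    if sigma[0] <= 0 or (sigma[0] - sigma.min()) < 0.05 * sigma[0]:
        logger.warning("σ(l) is nearly constant: l_c unidentifiable")
        return ScaleFit(np.nan, np.nan, float(sigma.mean()), 0.0, 0.0, True, l_grid, sigma)

    def model(p, l):
        A, lc, B = p
        return A * np.exp(-l / lc) + B

    starts = np.geomspace(l_grid[0], l_grid[-1] * 2, 5)
    p, cost = _multistart_fit(model, sigma, l_grid, starts, 3)
    if spacing is not None and p[1] < 1.5 * spacing:
        logger.info("fitted l_c (%.1f µm) is near the grid resolution", p[1])
    return ScaleFit(float(p[1]), float(p[0]), float(p[2]), 0.0, cost, False, l_grid, sigma)


def characteristic_time_scale(
    seq: FlowFieldSequence,
    max_window: Optional[int] = None,
    t_imaging: Optional[float] = None,
) -> ScaleFit:
    """Characteristic time scale t_c of the flow from temporal coarse-graining.

    σ(t) from :func:`temporal_coarse_grain_curve` is fit to
    σ = A·e^(−t/t_c) + B/√(t/t_imaging) + C with all parameters non-negative
    (the B term models finite stage-repositioning accuracy; ``t_imaging``
    defaults to the frame interval).  When estimating one t_c from several
    replicate sequences, average their σ(t) curves and call
    :func:`fit_time_scale_curve` once.
    """
    t_grid, sigma = temporal_coarse_grain_curve(seq, max_window)
    t_img = t_imaging if t_imaging is not None else seq.frame_interval
    return fit_time_scale_curve(t_grid, sigma, t_img)


def characteristic_length_scale(
    seq: FlowFieldSequence,
    max_block: Optional[int] = None,
) -> ScaleFit:
    """Characteristic length scale l_c from spatial coarse-graining.

    σ(l) from :func:`spatial_coarse_grain_curve` fit to σ = A·e^(−l/l_c) + B.
    Near-uniform fields are reported degenerate; for pooled estimates over
    replicates, average curves and use :func:`fit_length_scale_curve`.
    """
    l_grid, sigma = spatial_coarse_grain_curve(seq, max_block)
    return fit_length_scale_curve(l_grid, sigma, seq.grid_spacing)


# ---------------------------------------------------------------------------


def radial_profile(
    values: np.ndarray,
    sites: np.ndarray,
    geometry: SheetGeometry,
    frame_indices: Optional[np.ndarray] = None,
    bin_width: float = 0.05,
    r_max: float = 1.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of a per-site scalar in r/R bins of ``bin_width``.

    ``values`` is (n_sites,) or (n_frames, n_sites); ``sites`` the physical
    (x, y) positions.  Sites beyond r/R = ``r_max`` are excluded.  Returns
    (bin_centers, bin_means) with NaN for unpopulated bins.
    """
    vals = np.atleast_2d(np.asarray(values, dtype=float))
    nf = vals.shape[0]
    frames = frame_indices if frame_indices is not None else np.zeros(nf, dtype=int)
    n_bins = int(np.ceil(r_max / bin_width))
    tot = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    r_site = np.linalg.norm(np.asarray(sites, float) - np.asarray(geometry.center), axis=1)
    for fi in range(nf):
        rr = r_site / geometry.radius_at(int(frames[fi]))
        ok = (rr <= r_max) & np.isfinite(vals[fi])
        b = np.minimum((rr[ok] / bin_width).astype(int), n_bins - 1)
        np.add.at(tot, b, vals[fi, ok])
        np.add.at(cnt, b, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return centers, means
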