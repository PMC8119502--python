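"""Synthetic data with known ground truth for the migration-analysis pipeline.

The raw experiment is time-lapse phase-contrast imaging of a roughly circular
epithelial sheet expanding into free space (one field of view per sheet edge,
0.582 µm/pixel, one frame every 3 minutes for 12 h).  This module emulates the
statistical structure that the downstream analysis assumes, with every
generating parameter recorded as ground truth:

* velocity-field sequences whose direction angles about the outward radial
  direction have an exactly von Mises(0, κ) marginal, a tunable spatial
  correlation length and a tunable AR(1) temporal persistence;
* speckle-textured sheet movies whose leading edge advances at a controlled
  rate with tunable roughness;
* nuclei point patterns with controlled radial density profiles, rendered as
  Gaussian spots;
* analytic edge curves (line / sinusoid / circular arc) with known length and
  curvature.

Directionality fields use a Gaussian copula: a latent unit-variance Gaussian
random field carries the spatial and temporal correlation (Gaussian kernel of
scale ``correlation_length``; AR(1) coefficient ``exp(-Δt/persistence_time)``)
and is mapped through the von Mises quantile function, so the marginal angle
distribution is exactly von Mises regardless of the correlation scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.special import ndtr

from .geometry import SheetGeometry
from .piv import FlowField, FlowFieldSequence, piv_grid

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "generate_flow_sequence",
    "generate_sheet_movie",
    "generate_nuclei_image",
    "generate_edge_curve",
    "ImageStack",
]

#: Treat the von Mises concentration as infinite above this value (angles == 0).
KAPPA_INF = 1e6


class ParameterError(ValueError):
    pass


@dataclass
class ImageStack:
    """Ordered grayscale frames plus physical calibration."""

    frames: np.ndarray  # (T, H, W)
    pixel_size: float  # µm/pixel
    frame_interval: float  # minutes
    stage_position: tuple[float, float] = (0.0, 0.0)  # physical (x, y) of pixel (0,0), µm

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ParameterError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class SyntheticParams:
    """Generating parameters for all synthetic data.

    Defaults mirror the imaging conditions of the assay being emulated
    (0.582 µm/pixel, a frame every 3 min, 1024 × 1344 px fields of view) and
    plausible MCF10A-scale kinematics (mean speeds of a fraction of a µm/min,
    edge advance of tens of µm/h, coordination over a few cell lengths).
    """

    seed: int = 0
    n_frames: int = 40
    frame_interval: float = 3.0  # minutes
    pixel_size: float = 0.582  # µm/pixel
    image_shape: tuple[int, int] = (1024, 1344)  # (rows, cols)
    mean_speed: float = 0.5  # µm/min
    direction_concentration: float = 4.0  # von Mises κ about the outward direction
    correlation_length: float = 30.0  # µm
    persistence_time: float = 30.0  # minutes
    sheet_radius0: float = 2000.0  # µm
    expansion_rate: float = 20.0  # µm/h
    edge_roughness: float = 8.0  # µm, radial perturbation amplitude of the boundary
    texture_scale: float = 3.0  # px, speckle feature size
    noise_level: float = 5.0  # grey levels, background noise std (12-bit scale)

    def validate(self) -> None:
        if self.direction_concentration < 0:
            raise ParameterError("direction concentration κ must be ≥ 0")
        for name in ("frame_interval", "pixel_size", "mean_speed", "correlation_length",
                     "persistence_time", "sheet_radius0"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.n_frames < 1:
            raise ParameterError("need at least one frame")
        if min(self.image_shape) < 64:
            raise ParameterError("image must fit at least one 64 px PIV window per axis")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    true_parameters: SyntheticParams
    true_edge_per_frame: Optional[list[np.ndarray]] = None  # (N,2) float (row, col) px
    true_mask_per_frame: Optional[np.ndarray] = None  # (T, H, W) bool
    true_velocity: Optional[np.ndarray] = None  # (T, ny, nx, 2) µm/min (u, v)
    true_angles: Optional[np.ndarray] = None  # (T, ny, nx) rad, about outward radial
    true_centroids: Optional[np.ndarray] = None  # (n, 2) float (row, col) px
    geometry: Optional[SheetGeometry] = None


# ---------------------------------------------------------------------------
# latent Gaussian field machinery

def _unit_smoothed_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """White noise smoothed with a periodic Gaussian kernel, exactly unit variance.

    Periodic boundary keeps the field stationary; normalization by the kernel
    energy makes every pixel an exact N(0, 1) draw.
    """
    w = rng.standard_normal(shape)
    if sigma <= 0:
        return w
    sm = gaussian_filter(w, sigma, mode="wrap")
    delta = np.zeros(shape)
    delta[0, 0] = 1.0
    kernel = gaussian_filter(delta, sigma, mode="wrap")
    return sm / np.sqrt((kernel**2).sum())


def _ar1_gaussian_field(
    rng: np.random.Generator, n_frames: int, shape: tuple[int, int], sigma: float, ar_coeff: float
) -> np.ndarray:
    """(T, ny, nx) field, unit marginal variance, AR(1) in time."""
    g = np.empty((n_frames, *shape))
    g[0] = _unit_smoothed_noise(rng, shape, sigma)
    innov = np.sqrt(max(0.0, 1.0 - ar_coeff**2))
    for t in range(1, n_frames):
        g[t] = ar_coeff * g[t - 1] + innov * _unit_smoothed_noise(rng, shape, sigma)
    return g


def _vonmises_quantile(q: np.ndarray, kappa: float, n_grid: int = 4097) -> np.ndarray:
    """von Mises(0, κ) quantile function via a dense CDF interpolation table."""
    if kappa == 0:
        return (2.0 * q - 1.0) * np.pi
    grid = np.linspace(-np.pi, np.pi, n_grid)
    cdf = stats.vonmises.cdf(grid, kappa)
    return np.interp(q, cdf, grid)


# ---------------------------------------------------------------------------
# flow sequences

def generate_flow_sequence(
    params: SyntheticParams,
    grid_shape: tuple[int, int] = (40, 40),
    grid_spacing: Optional[float] = None,
) -> tuple[FlowFieldSequence, GroundTruth]:
    """Generate a velocity-field sequence on a PIV-style grid.

    Vectors have magnitude ``mean_speed`` and directions von Mises(0, κ)
    about the outward radial direction of a sheet whose center sits below the
    grid at distance ``sheet_radius0``; the latent angle field is spatially
    correlated over ``correlation_length`` and AR(1)-persistent over
    ``persistence_time``.  Deterministic given the seed.
    """
    params.validate()
    ny, nx = grid_shape
    if grid_spacing is None:
        grid_spacing = 16 * params.pixel_size  # final PIV grid convention
    rng = np.random.default_rng(params.seed)

    kappa = params.direction_concentration
    sigma_grid = params.correlation_length / grid_spacing
    ar = float(np.exp(-params.frame_interval / params.persistence_time))

    if kappa >= KAPPA_INF:
        theta = np.zeros((params.n_frames, ny, nx))
    else:
        g = _ar1_gaussian_field(rng, params.n_frames, (ny, nx), sigma_grid, ar)
        theta = _vonmises_quantile(ndtr(g), kappa)

    # grid sits above the sheet center so the outward direction is ~+y
    x = (np.arange(nx) - (nx - 1) / 2) * grid_spacing
    y_lo = params.sheet_radius0 - (ny - 1) * grid_spacing / 2
    y = y_lo + np.arange(ny) * grid_spacing
    X, Y = np.meshgrid(x, y)
    phi_out = np.arctan2(Y, X)  # outward angle at each site, center at origin

    ang = phi_out[None] + theta
    u = params.mean_speed * np.cos(ang)
    v = params.mean_speed * np.sin(ang)

    duration_h = params.n_frames * params.frame_interval / 60.0
    radius = params.sheet_radius0 + params.expansion_rate * np.arange(params.n_frames) * params.frame_interval / 60.0
    geom = SheetGeometry(center=(0.0, 0.0), radius=radius, frame_interval=params.frame_interval)

    ones = np.ones((ny, nx))
    fields = [
        FlowField(x=x, y=y, u=u[t], v=v[t], snr=np.full((ny, nx), np.inf), valid=ones.astype(bool))
        for t in range(params.n_frames)
    ]
    seq = FlowFieldSequence(fields=fields, frame_interval=params.frame_interval, geometry=geom)
    truth = GroundTruth(
        true_parameters=params,
        true_velocity=np.stack([u, v], axis=-1),
        true_angles=theta,
        geometry=geom,
    )
    return seq, truth


# ---------------------------------------------------------------------------
# sheet movies

def _edge_roughness_profile(
    rng: np.random.Generator, n_frames: int, n_samples: int, amplitude: float,
    smooth_samples: float, ar: float,
) -> np.ndarray:
    """(T, n_samples) radial perturbation of the boundary, µm, AR(1) in time."""
    if amplitude <= 0:
        return np.zeros((n_frames, n_samples))
    prof = np.empty((n_frames, n_samples))
    def draw() -> np.ndarray:
        w = rng.standard_normal(n_samples)
        sm = gaussian_filter1d(w, smooth_samples, mode="wrap")
        delta = np.zeros(n_samples)
        delta[0] = 1.0
        k = gaussian_filter1d(delta, smooth_samples, mode="wrap")
        return sm / np.sqrt((k**2).sum())
    prof[0] = draw()
    innov = np.sqrt(max(0.0, 1.0 - ar**2))
    for t in range(1, n_frames):
        prof[t] = ar * prof[t - 1] + innov * draw()
    return amplitude * prof


def generate_sheet_movie(
    params: SyntheticParams,
    straight_edge: bool = False,
    advect_texture: bool = True,
) -> tuple[ImageStack, GroundTruth]:
    """Render a speckle-textured sheet whose edge advances up the frame.

    The sheet is a disk of radius R(t) = R₀ + expansion_rate·t centered far
    below the image, so within the field of view the leading edge is a gently
    curved, rough line advancing toward the top.  Texture inside the sheet is
    band-limited speckle (feature size ``texture_scale``) that advects with
    the mean motion; outside is low-amplitude noise.

    With ``straight_edge=True`` the boundary is an exactly horizontal line
    spanning the image (the minimum-edge-length calibration case).
    """
    params.validate()
    H, W = params.image_shape
    ps = params.pixel_size
    rng = np.random.default_rng(params.seed)
    T = params.n_frames

    advance_px = params.expansion_rate / 60.0 * params.frame_interval / ps  # px/frame
    edge_row0 = 0.70 * H  # boundary starts in the lower part of the frame
    final_row = edge_row0 - advance_px * (T - 1) - params.edge_roughness / ps - 4
    if final_row <= 1:
        raise ParameterError("sheet would exit the frame before n_frames")

    R0_px = params.sheet_radius0 / ps
    center_row = edge_row0 + R0_px  # sheet center far below the image
    center_col = (W - 1) / 2

    # static speckle texture on an extended canvas, advected upward over time
    total_shift = int(np.ceil(advance_px * T)) + 2
    canvas = rng.standard_normal((H + total_shift, W))
    canvas = gaussian_filter(canvas, params.texture_scale / 2.0, mode="wrap")
    canvas /= canvas.std()

    n_phi = 4096
    ar = float(np.exp(-params.frame_interval / params.persistence_time))
    smooth = params.correlation_length / ps / (2 * np.pi * R0_px) * n_phi  # kernel in φ-samples
    rough = _edge_roughness_profile(rng, T, n_phi, params.edge_roughness, max(smooth, 1.0), ar)
    phi_samples = np.linspace(-np.pi / 2 - 0.5, -np.pi / 2 + 0.5, n_phi)  # arc facing the image

    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    frames = np.empty((T, H, W), dtype=np.uint16)
    masks = np.empty((T, H, W), dtype=bool)
    edges: list[np.ndarray] = []

    col_axis = np.arange(W)
    for t in range(T):
        R_px = R0_px + advance_px * t
        if straight_edge:
            boundary_row = np.full(W, edge_row0 - advance_px * t)
        else:
            # boundary row per column: circle + roughness sampled by angle
            dx = col_axis - center_col
            phi_col = -np.pi / 2 + np.arctan2(dx, R_px)  # boundary angle seen from center
            dr = np.interp(phi_col, phi_samples, rough[t] / ps)
            boundary_row = center_row - np.sqrt(np.maximum(R_px**2 - dx**2, 0.0)) - dr
        mask = rows >= boundary_row[None, :]
        masks[t] = mask

        shift = int(round(advance_px * t)) if advect_texture else 0
        tex = canvas[total_shift - shift : total_shift - shift + H, :]
        img = np.where(mask, 800.0 + 350.0 * tex, 150.0)
        img = img + rng.standard_normal((H, W)) * params.noise_level
        frames[t] = np.clip(img, 0, 4095).astype(np.uint16)

        edges.append(np.column_stack([boundary_row, col_axis.astype(float)]))

    geom = SheetGeometry(
        center=(center_col * ps, -center_row * ps),
        radius=np.array([(R0_px + advance_px * t) * ps for t in range(T)]),
        frame_interval=params.frame_interval,
    )
    stack = ImageStack(frames=frames, pixel_size=ps, frame_interval=params.frame_interval)
    truth = GroundTruth(
        true_parameters=params,
        true_edge_per_frame=edges,
        true_mask_per_frame=masks,
        geometry=geom,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# nuclei images

def generate_nuclei_image(
    params: SyntheticParams,
    n_cells: int,
    profile: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    image_shape: Optional[tuple[int, int]] = None,
    min_spacing: float = 6.0,
    spot_sigma: float = 1.8,
    amplitude: float = 2000.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render ``n_cells`` Gaussian nuclear spots inside a disk of ``sheet_radius0``.

    ``profile(r_over_R)`` gives the relative density per unit area as a
    function of normalized radius (uniform if omitted); placement respects a
    minimum center spacing of ``min_spacing`` px.  Fails if the requested
    count cannot be packed at that spacing.
    """
    params.validate()
    if n_cells < 0:
        raise ParameterError("n_cells must be ≥ 0")
    shape = image_shape if image_shape is not None else params.image_shape
    H, W = shape
    ps = params.pixel_size
    R_px = params.sheet_radius0 / ps
    center = np.array([(H - 1) / 2, (W - 1) / 2])
    rng = np.random.default_rng(params.seed)

    if profile is None:
        profile = lambda x: np.ones_like(x)
    # rejection sampling envelope over the profile
    xs = np.linspace(0, 1, 512)
    pmax = float(np.max(profile(xs)))
    if pmax <= 0:
        raise ParameterError("profile must be positive somewhere")

    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = max(5000, 300 * max(n_cells, 1))
    while len(pts) < n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ParameterError(
                f"could not place {n_cells} nuclei at spacing {min_spacing} px "
                f"(packing capacity exceeded after {attempts} attempts)"
            )
        r = R_px * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        p = center + r * np.array([np.sin(phi), np.cos(phi)])
        if not (0 <= p[0] < H and 0 <= p[1] < W):
            continue
        if rng.uniform() > profile(np.array([r / R_px]))[0] / pmax:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_spacing:
            continue
        pts.append(p)
    centroids = np.array(pts).reshape(-1, 2)

    img = np.full((H, W), 100.0)
    rr = np.arange(H)
    cc = np.arange(W)
    half = int(np.ceil(4 * spot_sigma))
    for (r0, c0) in centroids:
        r_lo, r_hi = max(0, int(r0) - half), min(H, int(r0) + half + 1)
        c_lo, c_hi = max(0, int(c0) - half), min(W, int(c0) + half + 1)
        dr = rr[r_lo:r_hi, None] - r0
        dc = cc[None, c_lo:c_hi] - c0
        img[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(-(dr**2 + dc**2) / (2 * spot_sigma**2))
    img += rng.standard_normal((H, W)) * params.noise_level
    frames = np.clip(img, 0, 65535).astype(np.uint16)[None]

    geom = SheetGeometry(
        center=(center[1] * ps, -center[0] * ps),
        radius=np.array([params.sheet_radius0]),
        frame_interval=params.frame_interval,
    )
    stack = ImageStack(frames=frames, pixel_size=ps, frame_interval=params.frame_interval)
    truth = GroundTruth(true_parameters=params, true_centroids=centroids, geometry=geom)
    return stack, truth


# ---------------------------------------------------------------------------
# analytic edge curves

def generate_edge_curve(shape: str, **shape_params) -> np.ndarray:
    """Analytic edge fixtures as ordered (row, col) point arrays (pixel units).

    Shapes
    ------
    ``line``: ``width`` columns at ``row`` (default 0); length = (width−1) px.
    ``sinusoid``: ``amplitude`` a and ``wavelength`` λ over one period
      (y = a·sin(2πx/λ)), sampled at ``n`` points.
    ``circular-arc``: ``radius`` R, ``span`` radians (default π), ``n`` points;
      |Menger curvature| = 1/R at interior points.
    """
    if shape == "line":
        width = int(shape_params.get("width", 1024))
        row = float(shape_params.get("row", 0.0))
        cols = np.arange(width, dtype=float)
        return np.column_stack([np.full(width, row), cols])
    if shape == "sinusoid":
        a = float(shape_params.get("amplitude", 20.0))
        lam = float(shape_params.get("wavelength", 200.0))
        n = int(shape_params.get("n", 4001))
        x = np.linspace(0, lam, n)
        return np.column_stack([a * np.sin(2 * np.pi * x / lam), x])
    if shape in ("circular-arc", "arc"):
        R = float(shape_params["radius"])
        span = float(shape_params.get("span", np.pi))
        n = int(shape_params.get("n", 1001))
        th = np.linspace(0, span, n)
        return np.column_stack([R * np.sin(th), R * (1 - np.cos(th))])
    raise ParameterError(f"unknown edge shape {shape!r}")
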