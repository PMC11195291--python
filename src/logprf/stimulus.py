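"""Bar-aperture stimulus movies and the log-eccentricity warp.

A *fixed-bar* stimulus is a bar of constant width drifting at constant speed
across a circular aperture.  The *log-bar* stimulus is obtained by warping
every frame of the fixed-bar movie along the eccentricity axis with

    r' = c * ln(1 + k * r),        c = rmax / ln(1 + k * rmax)

so that the aperture edge maps onto itself while content is compressed
toward the fovea: the warped bar travels slowly and thinly near fixation
and fast and wide in the periphery, approximating constant speed and width
on a log-magnified cortical surface.  The natural logarithm is used
throughout; a change of base is absorbed by ``c`` so results are
base-invariant.

Coordinate convention: visual-field degrees, x rightward, y upward, origin at
fixation; polar angle counter-clockwise from the positive x-axis; pixel
centers at half-integer pixel offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "FieldGrid",
    "WarpSpec",
    "SweepSpec",
    "RunSpec",
    "StimulusMovie",
    "scale_constant",
    "log_map",
    "inverse_log_map",
    "make_bar_frame",
    "make_sweep",
    "assemble_run",
    "warp_movie",
    "preprocess_movie",
    "default_run",
    "DEFAULT_DIRECTIONS",
]

#: k below this is treated as the zero-distortion identity limit.
K_IDENTITY_EPS = 1e-6

#: Default sweep direction set: 4 orientations x 2 motion senses.
DEFAULT_DIRECTIONS = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldGrid:
    """Pixel raster covering the visual field.

    Parameters
    ----------
    width_px, height_px : int
        Raster size in pixels.
    deg_per_px : float
        Degrees of visual angle per pixel (isotropic).
    center : tuple of float, optional
        Pixel coordinate (col, row) of fixation. Defaults to the geometric
        center of the raster.
    """

    width_px: int
    height_px: int
    deg_per_px: float
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.deg_per_px <= 0:
            raise ValueError(f"deg_per_px must be positive, got {self.deg_per_px}")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("grid must contain at least one pixel")

    @classmethod
    def square(cls, n_px: int, fov_deg: float) -> "FieldGrid":
        """Square grid of ``n_px`` pixels spanning ``fov_deg`` degrees."""
        return cls(width_px=n_px, height_px=n_px, deg_per_px=fov_deg / n_px)

    @property
    def center_px(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return (self.width_px / 2.0, self.height_px / 2.0)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) degree coordinates of pixel centers, shape (H, W) each."""
        cx, cy = self.center_px
        cols = np.arange(self.width_px) + 0.5
        rows = np.arange(self.height_px) + 0.5
        x = (cols - cx) * self.deg_per_px
        y = (cy - rows) * self.deg_per_px  # y grows upward
        return np.meshgrid(x, y)

    def eccentricity(self) -> np.ndarray:
        x, y = self.coords()
        return np.hypot(x, y)

    def deg_to_px(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Degree coordinates -> fractional (row, col) pixel-center coords."""
        cx, cy = self.center_px
        col = np.asarray(x) / self.deg_per_px + cx - 0.5
        row = cy - np.asarray(y) / self.deg_per_px - 0.5
        return row, col


@dataclass(frozen=True)
class WarpSpec:
    """Parameters of the log-eccentricity mapping r' = c*ln(1 + k*r).

    ``c`` is derived as ``rmax / ln(1 + k*rmax)`` unless supplied, which
    pins the fixed point warp(rmax) = rmax.  ``k`` below ``K_IDENTITY_EPS``
    selects the identity (zero-distortion) limit.
    """

    k: float
    rmax: float
    c: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rmax <= 0:
            raise ValueError(f"rmax must be positive, got {self.rmax}")
        if self.k < 0:
            raise ValueError(f"k must be non-negative, got {self.k}")
        if self.c is None:
            c = self.rmax if self.is_identity else scale_constant(self.k, self.rmax)
            object.__setattr__(self, "c", c)

    @property
    def is_identity(self) -> bool:
        return self.k < K_IDENTITY_EPS


@dataclass(frozen=True)
class SweepSpec:
    """One bar traverse: motion direction, bar geometry and timing.

    ``direction`` is the angle (degrees CCW from +x) of bar *motion*; the bar
    itself is perpendicular to it.  ``bar_width`` and ``speed`` are in fixed
    (unwarped) visual space.
    """

    direction: float
    bar_width: float = 2.0
    speed: float = 0.4
    duration: float = 45.0

    def __post_init__(self) -> None:
        if self.bar_width <= 0 or self.speed <= 0 or self.duration <= 0:
            raise ValueError("bar_width, speed and duration must be positive")

    def traverse_length(self) -> float:
        """Distance covered: duration * speed (aperture diameter + bar width)."""
        return self.duration * self.speed


@dataclass(frozen=True)
class RunSpec:
    """A full run: pre-blank, ordered sweeps, post-blank, timing, rng seed."""

    sweeps: tuple[SweepSpec, ...]
    pre_blank_s: float = 2.0
    post_blank_s: float = 4.0
    frame_rate_hz: float = 10.0
    rng_seed: int = 0

    @property
    def total_duration_s(self) -> float:
        return self.pre_blank_s + sum(s.duration for s in self.sweeps) + self.post_blank_s


def default_run(
    rng_seed: int = 0,
    frame_rate_hz: float = 10.0,
    directions: Sequence[float] = DEFAULT_DIRECTIONS,
    bar_width: float = 2.0,
    speed: float = 0.4,
    sweep_duration: float = 45.0,
    pre_blank_s: float = 2.0,
    post_blank_s: float = 4.0,
) -> RunSpec:
    """Standard run: 2 s blank + 8 x 45 s sweeps + 4 s blank = 366 s.

    The sweep-direction order is a seeded pseudorandom shuffle of
    ``directions`` (one sweep per direction).
    """
    order = np.random.default_rng(rng_seed).permutation(len(directions))
    sweeps = tuple(
        SweepSpec(direction=float(directions[i]), bar_width=bar_width,
                  speed=speed, duration=sweep_duration)
        for i in order
    )
    return RunSpec(sweeps=sweeps, pre_blank_s=pre_blank_s, post_blank_s=post_blank_s,
                   frame_rate_hz=frame_rate_hz, rng_seed=rng_seed)


@dataclass
class StimulusMovie:
    """Aperture movie: frames (H, W, T), spatial calibration, frame timing.

    ``frames`` holds {0,1} values after binarization, or fractional coverage
    in [0,1] when preprocessing is asked to keep it.
    """

    frames: np.ndarray
    grid: FieldGrid
    frame_duration_s: float
    label: str = "fixed"

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3D (H, W, T), got shape {self.frames.shape}")
        if self.frames.shape[0] != self.grid.height_px or self.frames.shape[1] != self.grid.width_px:
            raise ValueError("frames shape does not match grid")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_duration_s

    def is_binary(self) -> bool:
        u = np.unique(self.frames)
        return bool(np.all(np.isin(u, (0, 1))))


# ---------------------------------------------------------------------------
# warp maps
# ---------------------------------------------------------------------------

def scale_constant(k: float, rmax: float) -> float:
    """Scale constant c = rmax / ln(1 + k*rmax) pinning warp(rmax) = rmax."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if rmax <= 0:
        raise ValueError(f"rmax must be positive, got {rmax}")
    return rmax / np.log1p(k * rmax)


def log_map(r, spec: WarpSpec):
    """Forward warp r -> r' = c*ln(1 + k*r); identity for k below the eps."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("eccentricity r must be non-negative")
    if spec.is_identity:
        out = r.copy()
    else:
        out = spec.c * np.log1p(spec.k * r)
    return float(out) if out.ndim == 0 else out


def inverse_log_map(r_prime, spec: WarpSpec):
    """Inverse warp r' -> r = (exp(r'/c) - 1)/k; identity in the k->0 limit."""
    r_prime = np.asarray(r_prime, dtype=float)
    if np.any(r_prime < 0):
        raise ValueError("eccentricity r' must be non-negative")
    if spec.is_identity:
        out = r_prime.copy()
    else:
        out = np.expm1(r_prime / spec.c) / spec.k
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# frame and movie construction
# ---------------------------------------------------------------------------

def make_bar_frame(
    bar_center_offset: float,
    sweep: SweepSpec,
    grid: FieldGrid,
    rmax: float,
) -> np.ndarray:
    """Rasterize one bar frame.

    A pixel is on iff its signed projection onto the motion axis lies within
    ``bar_width/2`` of ``bar_center_offset`` and its eccentricity is at most
    ``rmax``.  Returns a uint8 (H, W) mask.
    """
    if sweep.bar_width < grid.deg_per_px:
        warnings.warn(
            f"bar width {sweep.bar_width}° is thinner than one pixel "
            f"({grid.deg_per_px}°/px); the rasterized bar may be broken",
            stacklevel=2,
        )
    x, y = grid.coords()
    theta = np.deg2rad(sweep.direction)
    proj = x * np.cos(theta) + y * np.sin(theta)
    mask = (np.abs(proj - bar_center_offset) <= sweep.bar_width / 2.0) & (
        np.hypot(x, y) <= rmax
    )
    return mask.astype(np.uint8)


def make_sweep(
    sweep: SweepSpec,
    run: RunSpec,
    grid: FieldGrid,
    rmax: float,
) -> np.ndarray:
    """Frames of one full traverse, shape (H, W, n_frames).

    The bar center advances linearly at ``sweep.speed`` starting just outside
    the aperture at -(rmax + bar_width/2); at the stated settings (speed 0.4°/s
    for 45 s) the traverse covers 18° = 16° aperture + 2° bar.
    """
    n_frames = int(round(sweep.duration * run.frame_rate_hz))
    start = -(rmax + sweep.bar_width / 2.0)
    times = np.arange(n_frames) / run.frame_rate_hz
    offsets = start + sweep.speed * times
    frames = np.empty((grid.height_px, grid.width_px, n_frames), dtype=np.uint8)
    for i, off in enumerate(offsets):
        frames[:, :, i] = make_bar_frame(float(off), sweep, grid, rmax)
    return frames


def assemble_run(run: RunSpec, grid: FieldGrid, rmax: float) -> StimulusMovie:
    """Assemble pre-blank + sweeps + post-blank into one movie.

    Blank periods are all-zero frames.  The sweep order is whatever
    ``run.sweeps`` contains (seeded shuffling happens in :func:`default_run`),
    so the same RunSpec always yields a bit-identical movie.  Segments are
    laid out on one global timeline so the total frame count is always
    round(total_duration * frame_rate), independent of per-segment rounding.
    """
    fps = run.frame_rate_hz
    n_total = int(round(run.total_duration_s * fps))
    frames = np.zeros((grid.height_px, grid.width_px, n_total), dtype=np.uint8)
    t0 = run.pre_blank_s
    for sweep in run.sweeps:
        j0 = int(round(t0 * fps))
        j1 = min(int(round((t0 + sweep.duration) * fps)), n_total)
        start = -(rmax + sweep.bar_width / 2.0)
        for j in range(j0, j1):
            offset = start + sweep.speed * (j / fps - t0)
            frames[:, :, j] = make_bar_frame(float(offset), sweep, grid, rmax)
        t0 += sweep.duration
    return StimulusMovie(frames=frames, grid=grid, frame_duration_s=1.0 / fps,
                         label="fixed")


# ---------------------------------------------------------------------------
# warping movies
# ---------------------------------------------------------------------------

def warp_matrix(grid: FieldGrid, spec: WarpSpec) -> sparse.csr_matrix:
    """Sparse backward-sampling operator for the log warp on ``grid``.

    Row p of the returned (npix, npix) matrix holds the bilinear weights of
    the source pixels feeding output pixel p: the output pixel at polar
    (theta, r) samples the source at (theta, log_map(r)), so displayed
    content is displaced toward the fovea and the drifting bar advances
    exponentially in eccentricity — linearly in the log coordinate, i.e. at
    constant speed on a log-magnified cortex.  The aperture edge maps onto
    itself; output pixels beyond rmax stay zero.
    """
    x, y = grid.coords()
    r_out = np.hypot(x, y)
    theta = np.arctan2(y, x)
    r_src = log_map(r_out.ravel(), spec).reshape(r_out.shape)
    src_x = r_src * np.cos(theta)
    src_y = r_src * np.sin(theta)
    row_f, col_f = grid.deg_to_px(src_x, src_y)

    H, W = grid.height_px, grid.width_px
    npix = H * W
    valid = (r_out <= spec.rmax).ravel()
    out_idx = np.flatnonzero(valid)
    row_f = row_f.ravel()[valid]
    col_f = col_f.ravel()[valid]

    r0 = np.floor(row_f).astype(np.int64)
    c0 = np.floor(col_f).astype(np.int64)
    fr = row_f - r0
    fc = col_f - c0

    rows_out, cols_in, weights = [], [], []
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W) & (w > 0)
        rows_out.append(out_idx[ok])
        cols_in.append(rr[ok] * W + cc[ok])
        weights.append(w[ok])
    mat = sparse.coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows_out), np.concatenate(cols_in))),
        shape=(npix, npix),
    )
    return mat.tocsr()


def warp_movie(movie: StimulusMovie, spec: WarpSpec, binarize: bool = True) -> StimulusMovie:
    """Warp a fixed-space movie into log-eccentricity space, frame by frame.

    Backward (inverse) mapping with bilinear sampling avoids holes; the
    interpolated frames are re-thresholded at 0.5 to restore binary masks
    unless ``binarize=False``.  In the k->0 identity limit the frames are
    returned unchanged (relabelled) to avoid numerical cancellation.
    """
    if spec.is_identity:
        return StimulusMovie(frames=movie.frames.copy(), grid=movie.grid,
                             frame_duration_s=movie.frame_duration_s, label="log")
    mat = warp_matrix(movie.grid, spec)
    H, W, T = movie.frames.shape
    flat = movie.frames.reshape(H * W, T).astype(np.float32)
    warped = mat @ flat
    if binarize:
        warped = (warped >= 0.5).astype(np.uint8)
    out = warped.reshape(H, W, T)
    return StimulusMovie(frames=out, grid=movie.grid,
                         frame_duration_s=movie.frame_duration_s, label="log")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _overlap_operator(n_src: int, n_dst: int) -> sparse.csr_matrix:
    """(n_dst, n_src) area-averaging operator for 1-D linear downsampling.

    Each destination sample is the mean of the source signal over its
    interval; rows sum to 1.  Exact block mean for integer ratios.
    """
    if n_dst > n_src:
        raise ValueError(f"upsampling requested ({n_src} -> {n_dst})")
    edges = np.linspace(0.0, n_src, n_dst + 1)
    rows, cols, vals = [], [], []
    for i in range(n_dst):
        lo, hi = edges[i], edges[i + 1]
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_src)):
            ov = min(hi, j + 1) - max(lo, j)
            if ov > 0:
                rows.append(i)
                cols.append(j)
                vals.append(ov / (hi - lo))
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n_dst, n_src))


def preprocess_movie(
    movie: StimulusMovie,
    target_px: int = 108,
    target_frames: int = 366,
    binarize: bool = True,
    chunk: int = 512,
) -> StimulusMovie:
    """Spatially and temporally downsample a movie for model fitting.

    Linear (area-averaging) resampling along each spatial axis and along
    time, then rebinarization at threshold 0.5 (set ``binarize=False`` to
    keep fractional bar coverage).  Defaults reproduce the 540x540 -> 108x108
    spatial and -> 366-frame temporal reduction.
    """
    H, W, T = movie.frames.shape
    if target_px > H or target_px > W:
        raise ValueError(f"spatial upsampling requested ({H}x{W} -> {target_px})")
    if target_frames > T:
        raise ValueError(f"temporal upsampling requested ({T} -> {target_frames})")

    op_r = _overlap_operator(H, target_px)
    op_c = _overlap_operator(W, target_px).T
    # spatial stage in temporal chunks to bound memory on long native movies
    spat = np.empty((target_px, target_px, T), dtype=np.float32)
    for t0 in range(0, T, chunk):
        t1 = min(t0 + chunk, T)
        blk = movie.frames[:, :, t0:t1].astype(np.float32)
        for t in range(t1 - t0):
            spat[:, :, t0 + t] = op_r @ blk[:, :, t] @ op_c
    op_t = _overlap_operator(T, target_frames)
    out = (op_t @ spat.reshape(-1, T).T).T.reshape(target_px, target_px, target_frames)
    if binarize:
        out = (out >= 0.5).astype(np.uint8)
    new_grid = FieldGrid(
        width_px=target_px,
        height_px=target_px,
        deg_per_px=movie.grid.deg_per_px * W / target_px,
    )
    return StimulusMovie(
        frames=out,
        grid=new_grid,
        frame_duration_s=movie.duration_s / target_frames,
        label=movie.label,
    )
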