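"""Two-stage pRF estimation with alternating HRF fitting.

Per unit (voxel/vertex) the estimator maximizes the Pearson correlation
between the predicted and observed time course.  Stage one is an exhaustive
coarse grid search over center and size seeds; stage two refines the best
seed with a derivative-free simplex (Nelder-Mead, fminsearch-equivalent),
with sigma optimized in log-space to enforce positivity.  The population HRF
is estimated by alternating: hold pRFs fixed and fit the six HRF parameters
on a high-VE subset of units, take the element-wise median, re-fit pRFs with
the new HRF, and repeat for three iterations.

A :class:`StimulusPredictor` caches the flattened stimulus matrix and the
sampled HRF kernel so that one objective evaluation costs a single BLAS
matrix-vector product plus a short convolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal

from logprf.forward_model import PRFParams, TimeCourse
from logprf.hemodynamics import HRFParams, hrf_curve
from logprf.stimulus import StimulusMovie

try:  # optional JIT fast path for the refinement objective
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _neg_corr_jit(S, bbox, x1d, ny1d, kernel, z_data, mu_x, mu_y, sigma, wsig):
        """Fused -correlation objective on a (T, H, W) float32 stimulus.

        Windows the separable Gaussian at +/- wsig*sigma and, per frame and
        row, visits only the intersection of that window with the row's
        precomputed nonzero column extent (the bar is spatially sparse).
        The overlap trace is convolved with the HRF kernel (truncated) and
        correlated with the z-scored data.  Returns 1.0 (worst) for a
        zero-variance prediction.
        """
        T, H, W = S.shape
        r = wsig * sigma
        c0 = np.searchsorted(x1d, mu_x - r)
        c1 = np.searchsorted(x1d, mu_x + r, side="right")
        r0 = np.searchsorted(ny1d, -(mu_y + r))
        r1 = np.searchsorted(ny1d, -(mu_y - r), side="right")
        if c1 <= c0 or r1 <= r0:
            return 1.0
        inv = 1.0 / (2.0 * sigma * sigma)
        gy = np.empty(r1 - r0, np.float32)
        for i in range(r1 - r0):
            d = -ny1d[r0 + i] - mu_y
            gy[i] = np.exp(-d * d * inv)
        gx = np.empty(c1 - c0, np.float32)
        for i in range(c1 - c0):
            d = x1d[c0 + i] - mu_x
            gx[i] = np.exp(-d * d * inv)
        overlap = np.zeros(T, np.float32)
        for t in range(T):
            tot = np.float32(0.0)
            for h in range(r0, r1):
                cA = max(c0, bbox[t, h, 0])
                cB = min(c1, bbox[t, h, 1])
                if cA >= cB:
                    continue
                row = S[t, h]
                acc = np.float32(0.0)
                for c in range(cA, cB):
                    acc += row[c] * gx[c - c0]
                tot += gy[h - r0] * acc
            overlap[t] = tot
        K = kernel.shape[0]
        mean = 0.0
        pred = np.empty(T, np.float64)
        for t in range(T):
            kmax = t + 1 if t + 1 < K else K
            acc2 = 0.0
            for k in range(kmax):
                acc2 += overlap[t - k] * kernel[k]
            pred[t] = acc2
            mean += acc2
        mean /= T
        ss = 0.0
        dot = 0.0
        for t in range(T):
            d2 = pred[t] - mean
            ss += d2 * d2
            dot += d2 * z_data[t]
        if ss <= 0.0:
            return 1.0
        return -dot / np.sqrt(ss * T)

__all__ = [
    "GridSearchSpec",
    "RetentionRule",
    "FitResult",
    "FitConfig",
    "StimulusPredictor",
    "objective",
    "grid_search",
    "refine_fit",
    "estimate_hrf",
    "alternate_fit",
    "apply_filters",
    "fit_dataset",
    "results_to_frame",
]


# ---------------------------------------------------------------------------
# specs and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSearchSpec:
    """Coarse seed grid: centers on a square lattice, sizes linearly spaced.

    Defaults: mu_x, mu_y each linearly sampled from -8 to 8 in 20 steps and
    sigma from 1 to 5 in 20 steps (8000 seeds).  The sigma seed range
    deliberately exceeds expected pRF sizes (convergence is steeper when
    starting large).
    """

    center_min: float = -8.0
    center_max: float = 8.0
    center_steps: int = 20
    sigma_min: float = 1.0
    sigma_max: float = 5.0
    sigma_steps: int = 20

    def __post_init__(self) -> None:
        if self.center_steps < 2 or self.sigma_steps < 2:
            raise ValueError("steps must be >= 2")
        if self.center_min >= self.center_max or self.sigma_min >= self.sigma_max:
            raise ValueError("min must be < max")

    @property
    def n_seeds(self) -> int:
        return self.center_steps**2 * self.sigma_steps

    def seeds(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (mu_x, mu_y, sigma) seed arrays in C-order.

        Linear index runs sigma fastest, then mu_y, then mu_x, so ties in the
        grid search break toward the lowest linear index deterministically.
        """
        centers = np.linspace(self.center_min, self.center_max, self.center_steps)
        sigmas = np.linspace(self.sigma_min, self.sigma_max, self.sigma_steps)
        mx, my, sg = np.meshgrid(centers, centers, sigmas, indexing="ij")
        return mx.ravel(), my.ravel(), sg.ravel()


@dataclass(frozen=True)
class RetentionRule:
    """Post-fit retention: ecc < max_ecc AND sigma > min_sigma AND VE > min_ve.

    All inequalities strict, as stated ("less than 8° eccentricity", "size
    greater than 0.05°", "variance explained > 10%").
    """

    max_ecc: float = 8.0
    min_sigma: float = 0.05
    min_ve: float = 0.10

    def __post_init__(self) -> None:
        if self.max_ecc <= 0 or self.min_sigma <= 0 or self.min_ve <= 0:
            raise ValueError("retention thresholds must be positive")

    def keep(self, ecc: float, sigma: float, ve: float) -> bool:
        return (ecc < self.max_ecc) and (sigma > self.min_sigma) and (ve > self.min_ve)


@dataclass
class FitResult:
    """Estimated pRF with its goodness of fit and retention flag."""

    prf: PRFParams
    correlation: float
    variance_explained: float
    seed_used: PRFParams | None = None
    retained: bool = False
    converged: bool = True
    valid: bool = True

    @classmethod
    def invalid(cls, seed: PRFParams | None = None) -> "FitResult":
        return cls(prf=PRFParams(0.0, 0.0, 1.0), correlation=np.nan,
                   variance_explained=np.nan, seed_used=seed, retained=False,
                   converged=False, valid=False)


@dataclass(frozen=True)
class FitConfig:
    """Settings for the full alternating fit."""

    grid: GridSearchSpec = GridSearchSpec()
    hrf_init: HRFParams = HRFParams.canonical()
    fit_hrf: bool = True
    n_iterations: int = 3
    hrf_select_frac: float = 0.15
    hrf_min_ve: float = 0.20
    retention: RetentionRule = RetentionRule()


# ---------------------------------------------------------------------------
# predictor cache
# ---------------------------------------------------------------------------

def _zscore_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores and a validity mask (rows with nonzero variance)."""
    mat = np.atleast_2d(np.asarray(mat, dtype=np.float64))
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.zeros_like(mat)
    np.divide(mat - mean, sd, out=z, where=sd > 0)
    return z, ok


class StimulusPredictor:
    """Cached forward model for one (stimulus, HRF) pair.

    Stores the stimulus as an (npix, T) float32 matrix and the HRF as a
    sampled kernel; ``predict`` then needs one Gaussian evaluation, one
    matrix-vector product and one short convolution.
    """

    #: Gaussian support radius used to window single-pRF evaluations.
    WINDOW_SIGMAS = 4.0

    def __init__(self, stim: StimulusMovie, hrf: HRFParams,
                 kernel_duration_s: float = 40.0):
        H, W, T = stim.frames.shape
        self.stim = stim
        self.n_frames = T
        self.dt = stim.frame_duration_s
        self._S = np.ascontiguousarray(
            stim.frames.reshape(H * W, T).astype(np.float32)
        )
        # (W, T, H) layout so windowed single-pRF evaluations are two small
        # BLAS contractions on contiguous views (x first, then y)
        self._Swth = np.ascontiguousarray(
            stim.frames.transpose(1, 2, 0).astype(np.float32)
        )
        x, y = stim.grid.coords()
        self._x = x.ravel().astype(np.float32)
        self._y = y.ravel().astype(np.float32)
        self._x1d = x[0, :].astype(np.float32)       # increasing
        self._y1d = y[:, 0].astype(np.float32)       # decreasing (y up)
        self._ny1d = np.ascontiguousarray(-self._y1d)  # ascending, for searches
        # JIT objective uses a time-major copy plus, per frame and row, the
        # nonzero column extent (the bar covers a small fraction of a frame)
        if _HAVE_NUMBA:
            self._Sjit = np.ascontiguousarray(
                np.moveaxis(stim.frames, 2, 0).astype(np.float32)
            )
            on = self._Sjit > 0  # (T, H, W)
            any_on = on.any(axis=2)
            first = on.argmax(axis=2)
            last = W - on[:, :, ::-1].argmax(axis=2)
            ext = np.zeros((T, H, 2), dtype=np.int64)
            ext[:, :, 0] = np.where(any_on, first, 0)
            ext[:, :, 1] = np.where(any_on, last, 0)
            self._bbox = ext
        else:
            self._Sjit = None
            self._bbox = None
        self._kernel_duration_s = kernel_duration_s
        self.set_hrf(hrf)

    def set_hrf(self, hrf: HRFParams) -> None:
        self.hrf = hrf
        n_kernel = int(np.ceil(self._kernel_duration_s / self.dt)) + 1
        self._kernel = hrf_curve(hrf, np.arange(n_kernel) * self.dt)

    # -- single pRF ---------------------------------------------------------
    def overlap(self, mu_x: float, mu_y: float, sigma: float) -> np.ndarray:
        """Per-frame stimulus/Gaussian dot product.

        The separable Gaussian is applied as two BLAS contractions over a
        window of +/- WINDOW_SIGMAS * sigma around the center (clipped to
        the grid); outside it the weight is below exp(-8) of peak,
        negligible against the correlation objective's tolerances.
        """
        T = self.n_frames
        H = self.stim.grid.height_px
        r = self.WINDOW_SIGMAS * sigma
        x, y = self._x1d, self._y1d
        c0 = int(np.searchsorted(x, mu_x - r, side="left"))
        c1 = int(np.searchsorted(x, mu_x + r, side="right"))
        # y runs downward in row order
        r0 = int(np.searchsorted(-y, -(mu_y + r), side="left"))
        r1 = int(np.searchsorted(-y, -(mu_y - r), side="right"))
        if c1 <= c0 or r1 <= r0:  # window entirely off-grid
            return np.zeros(T, dtype=np.float64)
        inv = np.float32(1.0 / (2.0 * sigma * sigma))
        gx = np.exp(-((x[c0:c1] - np.float32(mu_x)) ** 2) * inv)
        gy = np.exp(-((y[r0:r1] - np.float32(mu_y)) ** 2) * inv)
        # sum over x within the window, then over y
        m = gx @ self._Swth[c0:c1].reshape(c1 - c0, T * H)
        out = m.reshape(T, H)[:, r0:r1] @ gy
        return out.astype(np.float64)

    def convolve(self, trace: np.ndarray) -> np.ndarray:
        return np.convolve(trace, self._kernel)[: self.n_frames]

    def predict(self, mu_x: float, mu_y: float, sigma: float) -> np.ndarray:
        return self.convolve(self.overlap(mu_x, mu_y, sigma))

    def predict_prf(self, prf: PRFParams) -> np.ndarray:
        return self.predict(prf.mu_x, prf.mu_y, prf.sigma)

    def neg_corr(self, z_data: np.ndarray, mu_x: float, mu_y: float,
                 sigma: float) -> float:
        """-correlation of the prediction with z-scored data (1.0 if invalid)."""
        if self._Sjit is not None:
            return float(_neg_corr_jit(
                self._Sjit, self._bbox, self._x1d, self._ny1d, self._kernel,
                z_data, np.float32(mu_x), np.float32(mu_y), np.float32(sigma),
                np.float32(self.WINDOW_SIGMAS),
            ))
        pred = self.predict(mu_x, mu_y, sigma)
        sd = pred.std()
        if sd == 0 or not np.isfinite(sd):
            return 1.0
        zp = (pred - pred.mean()) / sd
        return -float(zp @ z_data) / z_data.shape[0]

    # -- batches ------------------------------------------------------------
    def predict_batch(self, mu_x: np.ndarray, mu_y: np.ndarray,
                      sigma: np.ndarray, block: int = 2048) -> np.ndarray:
        """Predictions for many pRFs, shape (n, T)."""
        mu_x = np.asarray(mu_x, dtype=np.float32)
        mu_y = np.asarray(mu_y, dtype=np.float32)
        sigma = np.asarray(sigma, dtype=np.float32)
        n = mu_x.shape[0]
        out = np.empty((n, self.n_frames), dtype=np.float64)
        for i0 in range(0, n, block):
            i1 = min(i0 + block, n)
            dx = self._x[None, :] - mu_x[i0:i1, None]
            dy = self._y[None, :] - mu_y[i0:i1, None]
            G = np.exp(-(dx * dx + dy * dy) / (2.0 * sigma[i0:i1, None] ** 2))
            overlaps = G @ self._S
            out[i0:i1] = signal.fftconvolve(
                overlaps.astype(np.float64), self._kernel[None, :], axes=1
            )[:, : self.n_frames]
        return out


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _as_values(data) -> np.ndarray:
    if isinstance(data, TimeCourse):
        return data.values
    return np.asarray(data, dtype=float)


def objective(data, prediction) -> float:
    """Pearson correlation between data and prediction.

    Returns NaN (flagged-invalid, not an exception) when either input has
    zero variance so batch fitting can continue.
    """
    a = _as_values(data)
    b = _as_values(prediction)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# stage 1: grid search
# ---------------------------------------------------------------------------

def _seed_zscores(predictor: StimulusPredictor, spec: GridSearchSpec):
    """Z-scored predictions for every seed, plus the seed parameter arrays."""
    mx, my, sg = spec.seeds()
    preds = predictor.predict_batch(mx, my, sg)
    z, ok = _zscore_rows(preds)
    return z, ok, (mx, my, sg)


def grid_search_batch(
    data: np.ndarray,
    predictor: StimulusPredictor,
    spec: GridSearchSpec,
) -> tuple[list[PRFParams], np.ndarray]:
    """Best seed per row of ``data`` (n_units, T); ties break to lowest index.

    Returns (seeds, correlations); a unit with zero variance gets correlation
    NaN and the first seed.
    """
    z_seeds, ok, (mx, my, sg) = _seed_zscores(predictor, spec)
    z_data, data_ok = _zscore_rows(np.atleast_2d(data))
    T = z_data.shape[1]
    corr = (z_seeds @ z_data.T) / T  # (n_seeds, n_units)
    corr[~ok, :] = -np.inf
    best = np.argmax(corr, axis=0)
    best_corr = corr[best, np.arange(corr.shape[1])]
    best_corr = np.where(data_ok, best_corr, np.nan)
    seeds = [PRFParams(float(mx[i]), float(my[i]), float(sg[i])) for i in best]
    return seeds, best_corr


def grid_search(
    data,
    stim: StimulusMovie,
    hrf: HRFParams,
    spec: GridSearchSpec = GridSearchSpec(),
    predictor: StimulusPredictor | None = None,
) -> PRFParams:
    """Exhaustive coarse search over all center x size seeds; returns argmax."""
    if predictor is None:
        predictor = StimulusPredictor(stim, hrf)
    seeds, _ = grid_search_batch(_as_values(data)[None, :], predictor, spec)
    return seeds[0]


# ---------------------------------------------------------------------------
# stage 2: simplex refinement
# ---------------------------------------------------------------------------

_NM_XATOL = 1e-4
_NM_FATOL = 1e-4


def refine_fit(
    data,
    stim: StimulusMovie,
    hrf: HRFParams,
    seed: PRFParams,
    predictor: StimulusPredictor | None = None,
) -> FitResult:
    """Nelder-Mead refinement of (mu_x, mu_y, sigma) from a grid seed.

    Sigma is optimized as log(sigma) so the returned size is always positive.
    The result never scores below its seed: if the simplex somehow ends worse
    the seed is returned.  Non-convergence returns the best iterate with
    ``converged=False``.
    """
    if predictor is None:
        predictor = StimulusPredictor(stim, hrf)
    values = _as_values(data)
    sd = values.std()
    if sd == 0:
        return FitResult.invalid(seed)
    z_data = (values - values.mean()) / sd

    def neg_corr(p: np.ndarray) -> float:
        return predictor.neg_corr(z_data, p[0], p[1], math.exp(p[2]))

    x0 = np.array([seed.mu_x, seed.mu_y, math.log(seed.sigma)])
    res = optimize.minimize(
        neg_corr,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": _NM_XATOL,
            "fatol": _NM_FATOL,
            "maxfev": 400 * 3,
            "disp": False,
        },
    )
    seed_score = -neg_corr(x0)
    score = -res.fun
    if score >= seed_score:
        prf = PRFParams(float(res.x[0]), float(res.x[1]), float(math.exp(res.x[2])))
        corr = score
    else:  # accept-best contract
        prf = seed
        corr = seed_score
    return FitResult(
        prf=prf,
        correlation=float(corr),
        variance_explained=float(corr**2),
        seed_used=seed,
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# HRF estimation
# ---------------------------------------------------------------------------

def _hrf_to_vector(p: HRFParams) -> np.ndarray:
    return np.array([p.delta, math.log(p.alpha1), math.log(p.alpha2),
                     math.log(p.beta1), math.log(p.beta2), math.log(p.ratio)])


def _vector_to_hrf(q: np.ndarray) -> HRFParams:
    return HRFParams(delta=float(q[0]), alpha1=float(math.exp(q[1])),
                     alpha2=float(math.exp(q[2])), beta1=float(math.exp(q[3])),
                     beta2=float(math.exp(q[4])), ratio=float(math.exp(q[5])))


def _fit_hrf_single(overlap: np.ndarray, z_data: np.ndarray, dt: float,
                    init: HRFParams, kernel_duration_s: float = 40.0) -> HRFParams:
    n = z_data.shape[0]
    n_kernel = int(np.ceil(kernel_duration_s / dt)) + 1
    t_kernel = np.arange(n_kernel) * dt

    def neg_corr(q: np.ndarray) -> float:
        kernel = hrf_curve(_vector_to_hrf(q), t_kernel)
        pred = np.convolve(overlap, kernel)[:n]
        sd = pred.std()
        if sd == 0 or not np.isfinite(sd):
            return 1.0
        zp = (pred - pred.mean()) / sd
        return -float(zp @ z_data) / n

    # tighter tolerances than the pRF stage: the HRF landscape has a long
    # shallow valley (delay trades off against gamma shape)
    res = optimize.minimize(
        neg_corr,
        _hrf_to_vector(init),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxfev": 2000 * 6},
    )
    return _vector_to_hrf(res.x)


def estimate_hrf(
    data: np.ndarray,
    prfs: list[PRFParams],
    stim: StimulusMovie,
    init: HRFParams,
    variance_explained: np.ndarray | None = None,
    select_frac: float = 0.15,
    min_ve: float = 0.20,
    predictor: StimulusPredictor | None = None,
) -> HRFParams:
    """Population HRF: per-unit 6-parameter fits at fixed pRFs, then median.

    Units are restricted to those with VE > ``min_ve``; of these, the top
    ``ceil(select_frac * count)`` by VE are fit (deterministic selection).
    The element-wise median of the fitted parameters is returned.  An empty
    selection falls back to ``init`` with a warning.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if predictor is None:
        predictor = StimulusPredictor(stim, init)
    if variance_explained is None:
        variance_explained = np.array([
            np.nan_to_num(objective(data[i], predictor.predict_prf(prfs[i])),
                          nan=0.0) ** 2
            for i in range(data.shape[0])
        ])
    variance_explained = np.asarray(variance_explained, dtype=float)
    eligible = np.flatnonzero(np.nan_to_num(variance_explained, nan=0.0) > min_ve)
    if eligible.size == 0:
        warnings.warn("no units pass the VE threshold for HRF estimation; "
                      "keeping the initial HRF", stacklevel=2)
        return init
    n_sel = math.ceil(select_frac * eligible.size)
    order = eligible[np.argsort(-variance_explained[eligible], kind="stable")]
    selected = order[:n_sel]

    fitted = []
    for i in selected:
        overlap = predictor.overlap(prfs[i].mu_x, prfs[i].mu_y, prfs[i].sigma)
        values = data[i]
        sd = values.std()
        if sd == 0:
            continue
        z_data = (values - values.mean()) / sd
        fitted.append(_hrf_to_vector(
            _fit_hrf_single(overlap, z_data, predictor.dt, init)
        ))
    if not fitted:
        warnings.warn("HRF estimation produced no valid fits; keeping the "
                      "initial HRF", stacklevel=2)
        return init
    return _vector_to_hrf(np.median(np.array(fitted), axis=0))


# ---------------------------------------------------------------------------
# dataset fitting and alternation
# ---------------------------------------------------------------------------

def fit_dataset(
    data: np.ndarray,
    stim: StimulusMovie,
    hrf: HRFParams,
    grid: GridSearchSpec = GridSearchSpec(),
    refine: bool = True,
    predictor: StimulusPredictor | None = None,
    progress: bool = False,
) -> list[FitResult]:
    """Grid search + optional refinement for every row of ``data`` (n, T)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if predictor is None:
        predictor = StimulusPredictor(stim, hrf)
    seeds, seed_corr = grid_search_batch(data, predictor, grid)
    units = range(data.shape[0])
    if progress:
        from tqdm import tqdm
        units = tqdm(units, desc="refine", unit="unit")
    results = []
    for i in units:
        if not np.isfinite(seed_corr[i]):
            results.append(FitResult.invalid(seeds[i]))
        elif refine:
            results.append(refine_fit(data[i], stim, hrf, seeds[i],
                                      predictor=predictor))
        else:
            results.append(FitResult(
                prf=seeds[i], correlation=float(seed_corr[i]),
                variance_explained=float(seed_corr[i] ** 2),
                seed_used=seeds[i],
            ))
    return results


def alternate_fit(
    data: np.ndarray,
    stim: StimulusMovie,
    config: FitConfig = FitConfig(),
    progress: bool = False,
) -> tuple[HRFParams, list[FitResult]]:
    """Alternating pRF/HRF estimation.

    Each iteration fixes the HRF and fits pRFs (grid search + refinement),
    then fixes the pRFs and re-estimates the HRF on the high-VE subset; the
    configured number of iterations (default 3) ends with a pRF fit under
    the converged HRF.  With ``fit_hrf=False`` this reduces to a single-pass
    fit with ``hrf_init``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    hrf = config.hrf_init
    predictor = StimulusPredictor(stim, hrf)
    if not config.fit_hrf:
        results = fit_dataset(data, stim, hrf, config.grid,
                              predictor=predictor, progress=progress)
        return hrf, apply_filters(results, config.retention)
    # initial pRFs: full fit under the initial HRF (estimating the HRF
    # against unrefined grid seeds lets it distort to compensate for the
    # seeds' coarseness and drags the alternation to a biased fixed point)
    results = fit_dataset(data, stim, hrf, config.grid, predictor=predictor,
                          progress=progress)
    for _ in range(config.n_iterations):
        # HRF stage: pRFs held fixed at current estimates
        hrf = estimate_hrf(
            data,
            [r.prf for r in results],
            stim,
            hrf,
            variance_explained=np.array([r.variance_explained for r in results]),
            select_frac=config.hrf_select_frac,
            min_ve=config.hrf_min_ve,
            predictor=predictor,
        )
        predictor.set_hrf(hrf)
        # pRF stage: HRF held fixed, grid search + simplex refinement
        results = fit_dataset(data, stim, hrf, config.grid,
                              predictor=predictor, progress=progress)
    return hrf, apply_filters(results, config.retention)


def apply_filters(results: list[FitResult], rule: RetentionRule = RetentionRule()) -> list[FitResult]:
    """Set retention flags; invalid fits are never retained."""
    out = []
    for r in results:
        retained = bool(
            r.valid
            and np.isfinite(r.variance_explained)
            and rule.keep(r.prf.eccentricity, r.prf.sigma, r.variance_explained)
        )
        out.append(replace(r, retained=retained))
    return out


def results_to_frame(results: list[FitResult]) -> pd.DataFrame:
    """Tabulate fits: one row per unit with polar coordinates and flags."""
    rows = []
    for i, r in enumerate(results):
        rows.append({
            "unit_id": i,
            "mu_x": r.prf.mu_x,
            "mu_y": r.prf.mu_y,
            "sigma": r.prf.sigma,
            "polar_angle": r.prf.polar_angle,
            "eccentricity": r.prf.eccentricity,
            "correlation": r.correlation,
            "variance_explained": r.variance_explained,
            "retained": r.retained,
        })
    return pd.DataFrame(rows)
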