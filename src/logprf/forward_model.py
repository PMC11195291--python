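"""Gaussian pRF forward model: spatial weight field and predicted BOLD.

The pRF is an isotropic, unit-peak 2-D Gaussian

    G(x, y) = exp(-((x - mu_x)^2 + (y - mu_y)^2) / (2 sigma^2))

and the predicted time course is the per-frame spatial dot product of the
stimulus aperture with G, convolved with the HRF.  G is left unnormalized
(unit peak) and the prediction unscaled: the fitting objective is a Pearson
correlation, which is invariant to affine scaling, so neither an amplitude
nor a baseline parameter is fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from logprf.hemodynamics import HRFParams, convolve_hrf
from logprf.stimulus import FieldGrid, StimulusMovie

__all__ = ["PRFParams", "TimeCourse", "gaussian_field", "predict_timecourse", "overlap_trace"]


@dataclass(frozen=True)
class PRFParams:
    """One pRF: center (mu_x, mu_y) and size sigma, all in degrees."""

    mu_x: float
    mu_y: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.mu_x, self.mu_y))

    @property
    def polar_angle(self) -> float:
        """Polar angle in radians, CCW from the positive x-axis."""
        return float(np.arctan2(self.mu_y, self.mu_x))


@dataclass
class TimeCourse:
    """Uniformly sampled signal with its sampling interval in seconds."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.shape[0]


def gaussian_field(prf: PRFParams, grid: FieldGrid) -> np.ndarray:
    """Unit-peak Gaussian evaluated at pixel-center degree coordinates, (H, W)."""
    x, y = grid.coords()
    return np.exp(-((x - prf.mu_x) ** 2 + (y - prf.mu_y) ** 2) / (2.0 * prf.sigma**2))


def overlap_trace(stim: StimulusMovie, prf: PRFParams) -> np.ndarray:
    """Pre-convolution overlap: sum_pixels S(x,y,t) * G(x,y) per frame."""
    g = gaussian_field(prf, stim.grid)
    return np.tensordot(stim.frames.astype(float), g, axes=([0, 1], [0, 1]))


def predict_timecourse(
    stim: StimulusMovie,
    prf: PRFParams,
    hrf: HRFParams,
) -> TimeCourse:
    """Predicted BOLD: spatial overlap per frame, convolved with the HRF.

    Output is sampled at the stimulus frame duration.
    """
    overlap = overlap_trace(stim, prf)
    values = convolve_hrf(overlap, hrf, dt=stim.frame_duration_s)
    return TimeCourse(values=values, dt=stim.frame_duration_s)
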