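"""Parametric double-gamma hemodynamic response function.

The HRF is the difference of two gamma densities — a positive response lobe
and a scaled undershoot — shifted by an onset delay:

    h(t) = g(t - delta; alpha1, beta1) - g(t - delta; alpha2, beta2) / ratio

with g the gamma probability density in shape/rate form,
g(s; a, b) = b^a s^(a-1) exp(-b s) / Gamma(a), and h = 0 for t <= delta.
Defaults are the SPM canonical parameters (delta=0, alpha1=6, alpha2=16,
beta1=beta2=1, ratio=6), whose positive lobe peaks at (alpha1-1)/beta1 = 5 s.

A peak-time parameterization (time-to-peak of each lobe rather than gamma
shape) is exposed through :meth:`HRFParams.from_peak_times` /
:meth:`HRFParams.to_peak_times`; the two are related by
``alpha = peak * beta + 1`` since the mode of g(.; a, b) is (a-1)/b.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = ["HRFParams", "hrf_curve", "convolve_hrf"]


@dataclass(frozen=True)
class HRFParams:
    """Six double-gamma parameters.

    delta : onset delay (s); alpha1/beta1 : shape/rate of the response lobe;
    alpha2/beta2 : shape/rate of the undershoot; ratio : response-to-
    undershoot amplitude ratio (undershoot scaled by 1/ratio; 0 disables it).
    """

    delta: float = 0.0
    alpha1: float = 6.0
    alpha2: float = 16.0
    beta1: float = 1.0
    beta2: float = 1.0
    ratio: float = 6.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "beta1", "beta2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.ratio < 0:
            raise ValueError(f"ratio must be non-negative, got {self.ratio}")

    @classmethod
    def canonical(cls) -> "HRFParams":
        return cls()

    @property
    def peak_time(self) -> float:
        """Time of the positive lobe's maximum: (alpha1-1)/beta1 + delta."""
        return (self.alpha1 - 1.0) / self.beta1 + self.delta

    @classmethod
    def from_peak_times(
        cls,
        peak1: float,
        peak2: float,
        beta1: float = 1.0,
        beta2: float = 1.0,
        ratio: float = 6.0,
        delta: float = 0.0,
    ) -> "HRFParams":
        """Build from lobe peak times (seconds after delta) and rates."""
        return cls(delta=delta, alpha1=peak1 * beta1 + 1.0, alpha2=peak2 * beta2 + 1.0,
                   beta1=beta1, beta2=beta2, ratio=ratio)

    def to_peak_times(self) -> dict:
        return {
            "peak1": (self.alpha1 - 1.0) / self.beta1,
            "peak2": (self.alpha2 - 1.0) / self.beta2,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "ratio": self.ratio,
            "delta": self.delta,
        }

    def as_dict(self) -> dict:
        return asdict(self)


def hrf_curve(params: HRFParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the double-gamma HRF at sample times ``t`` (seconds).

    Zero for t <= delta (causality). ``t`` may be any sorted vector.
    """
    t = np.asarray(t, dtype=float)
    ts = t - params.delta
    pos = stats.gamma.pdf(ts, a=params.alpha1, scale=1.0 / params.beta1)
    if params.ratio > 0:
        neg = stats.gamma.pdf(ts, a=params.alpha2, scale=1.0 / params.beta2) / params.ratio
    else:
        neg = 0.0
    h = pos - neg
    return np.where(ts > 0, h, 0.0)


def convolve_hrf(
    signal: np.ndarray,
    params: HRFParams,
    dt: float,
    kernel_duration_s: float = 40.0,
) -> np.ndarray:
    """Causal discrete convolution with the sampled HRF, truncated to input length.

    The kernel is ``hrf_curve`` sampled at t = 0, dt, 2dt, ... up to
    ``kernel_duration_s``; a unit impulse therefore returns the sampled HRF
    itself (no dt scaling — the correlation objective is scale-invariant).
    """
    signal = np.asarray(signal, dtype=float)
    n_kernel = int(np.ceil(kernel_duration_s / dt)) + 1
    kernel = hrf_curve(params, np.arange(n_kernel) * dt)
    return np.convolve(signal, kernel)[: signal.shape[0]]
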