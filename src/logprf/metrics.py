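"""Reliability and summary statistics.

Session-to-session reliability of pRF estimates uses Spearman rank
correlation for linear parameters (eccentricity, size, variance explained)
and a circular correlation for polar angle, each mapped through the Fisher z
(atanh) transform.  The circular coefficient defaults to the Fisher-Lee
statistic; the Jammalamadaka-SenGupta variant is available via
``method="js"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ReliabilityResult",
    "BehavioralCounts",
    "variance_explained",
    "reliability",
    "fisher_z",
    "circular_correlation",
    "behavioral_performance",
    "bin_by_eccentricity",
]


@dataclass(frozen=True)
class ReliabilityResult:
    """Correlation between paired parameter estimates plus its Fisher z."""

    parameter: str
    r: float
    fisher_z: float
    n_units: int
    valid: bool = True


@dataclass(frozen=True)
class BehavioralCounts:
    """Hit / false-alarm / total counts of the fixation color-change task."""

    n_hit: int
    n_false_alarms: int
    n_total: int

    def __post_init__(self) -> None:
        if min(self.n_hit, self.n_false_alarms, self.n_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_hit > self.n_total:
            raise ValueError("n_hit cannot exceed n_total")


def variance_explained(data, prediction) -> float:
    """Squared Pearson correlation, in [0, 1]; NaN for zero-variance input."""
    a = np.asarray(getattr(data, "values", data), dtype=float)
    b = np.asarray(getattr(prediction, "values", prediction), dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def fisher_z(r: float) -> float:
    """Fisher z transform Z = 0.5*ln((1+r)/(1-r)) = atanh(r); |r|>=1 -> ±inf."""
    r = float(r)
    if abs(r) > 1:
        raise ValueError(f"correlation must be in [-1, 1], got {r}")
    if abs(r) == 1:
        return float(np.sign(r) * np.inf)
    return float(np.arctanh(r))


def circular_correlation(a: np.ndarray, b: np.ndarray, method: str = "fisher-lee") -> float:
    """Circular correlation of two paired angle samples (radians).

    ``fisher-lee``: pairwise statistic
    sum_{i<j} sin(a_i - a_j) sin(b_i - b_j) normalized by the sample's own
    sine-difference energies; ``js``: the Jammalamadaka-SenGupta form around
    the circular means.  Both are invariant to common rotation of either set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("angle samples must be paired")
    if method == "fisher-lee":
        da = np.sin(a[:, None] - a[None, :])
        db = np.sin(b[:, None] - b[None, :])
        iu = np.triu_indices(a.size, k=1)
        num = float((da[iu] * db[iu]).sum())
        den = float(np.sqrt((da[iu] ** 2).sum() * (db[iu] ** 2).sum()))
    elif method == "js":
        abar = np.angle(np.exp(1j * a).mean())
        bbar = np.angle(np.exp(1j * b).mean())
        sa, sb = np.sin(a - abar), np.sin(b - bbar)
        num = float((sa * sb).sum())
        den = float(np.sqrt((sa**2).sum() * (sb**2).sum()))
    else:
        raise ValueError(f"unknown method {method!r}")
    if den == 0:
        return float("nan")
    return num / den


def reliability(
    est_a: np.ndarray,
    est_b: np.ndarray,
    kind: str = "linear",
    parameter: str = "",
    method: str = "fisher-lee",
) -> ReliabilityResult:
    """Paired reliability: Spearman (linear) or circular correlation (angles).

    Fewer than 3 pairs yields an invalid (NaN) result rather than an error.
    r = ±1 maps to Fisher z of ±inf with ``valid`` still True — callers see
    the flag through the infinite value rather than silent clipping.
    """
    est_a = np.asarray(est_a, dtype=float)
    est_b = np.asarray(est_b, dtype=float)
    if est_a.shape != est_b.shape:
        raise ValueError("sessions must have paired units")
    n = est_a.size
    if n < 3:
        return ReliabilityResult(parameter, float("nan"), float("nan"), n, valid=False)
    if kind == "linear":
        r = float(stats.spearmanr(est_a, est_b).statistic)
    elif kind == "circular":
        r = circular_correlation(est_a, est_b, method=method)
    else:
        raise ValueError(f"kind must be 'linear' or 'circular', got {kind!r}")
    if np.isnan(r):
        return ReliabilityResult(parameter, r, float("nan"), n, valid=False)
    return ReliabilityResult(parameter, r, fisher_z(r), n, valid=True)


def behavioral_performance(counts: BehavioralCounts) -> float:
    """(n_hit - n_false_alarms) / n_total * 100."""
    if counts.n_total == 0:
        raise ValueError("n_total must be positive")
    return (counts.n_hit - counts.n_false_alarms) / counts.n_total * 100.0


def bin_by_eccentricity(
    values: np.ndarray,
    eccentricities: np.ndarray,
    bins: np.ndarray,
) -> "pd.DataFrame":
    """Per-bin mean ± SEM of ``values`` grouped by eccentricity.

    ``bins`` are edges (length n_bins+1). Empty bins are reported with NaN.
    """
    import pandas as pd

    values = np.asarray(values, dtype=float)
    ecc = np.asarray(eccentricities, dtype=float)
    if values.shape != ecc.shape:
        raise ValueError("values and eccentricities must align")
    edges = np.asarray(bins, dtype=float)
    idx = np.clip(np.searchsorted(edges, ecc, side="right") - 1, 0, len(edges) - 2)
    in_range = (ecc >= edges[0]) & (ecc <= edges[-1])
    rows = []
    for b in range(len(edges) - 1):
        sel = in_range & (idx == b)
        n = int(sel.sum())
        if n:
            mean = float(values[sel].mean())
            sem = float(values[sel].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        else:
            mean, sem = float("nan"), float("nan")
        rows.append({"bin": b, "ecc_lo": edges[b], "ecc_hi": edges[b + 1],
                     "n": n, "mean": mean, "sem": sem})
    return pd.DataFrame(rows)
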