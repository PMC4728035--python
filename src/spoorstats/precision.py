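"""Bootstrap precision analysis of inter-spoor intervals.

For growing sample sizes n, resample n intervals with replacement many
times; the spread of the resample means shows how survey precision (mean
spoor frequency, its 95% CI, and its coefficient of variation) improves
with effort. A window/tolerance rule locates the sample size at which the
CV curve stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .survey_data import InsufficientDataError


@dataclass(frozen=True)
class PrecisionCurve:
    """Bootstrap summary of mean spoor frequency per sample size."""

    sample_sizes: np.ndarray
    means: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    cv: np.ndarray
    n_bootstrap: int
    seed: int

    def __post_init__(self) -> None:
        n = len(self.sample_sizes)
        if not (len(self.means) == len(self.ci_low) == len(self.ci_high) == len(self.cv) == n):
            raise ValueError("curve arrays must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_size": self.sample_sizes,
                "mean": self.means,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "cv": self.cv,
            }
        )


def bootstrap_curve(
    intervals: Sequence[float],
    n_bootstrap: int = 1000,
    seed: int = 0,
    max_n: int | None = None,
    stride: int = 1,
    sample_sizes: Sequence[int] | None = None,
) -> PrecisionCurve:
    """Bootstrap the mean interval at every sample size from 2 upward.

    For each n (default grid: every integer from 2 to ``max_n``, default
    the number of intervals; ``stride`` thins the grid, or pass
    ``sample_sizes`` explicitly) draw ``n_bootstrap`` resamples of size n
    with replacement and record the mean of resample means, their
    2.5th/97.5th percentiles, and their coefficient of variation
    (SD of replicate means / their mean). Deterministic for a fixed seed.
    """
    values = np.asarray(list(intervals), dtype=float)
    if len(values) < 2:
        raise InsufficientDataError(
            f"need at least 2 inter-spoor intervals, got {len(values)}"
        )
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be positive")
    if sample_sizes is None:
        top = len(values) if max_n is None else max_n
        grid = np.arange(2, top + 1, stride, dtype=int)
    else:
        grid = np.asarray(list(sample_sizes), dtype=int)
    if len(grid) == 0 or grid.min() < 1:
        raise ValueError("sample-size grid must be nonempty and positive")

    rng = np.random.default_rng(seed)
    means = np.empty(len(grid))
    lo = np.empty(len(grid))
    hi = np.empty(len(grid))
    cv = np.empty(len(grid))
    for i, n in enumerate(grid):
        idx = rng.integers(0, len(values), size=(n_bootstrap, int(n)))
        rep = values[idx].mean(axis=1)
        m = rep.mean()
        means[i] = m
        lo[i], hi[i] = np.percentile(rep, [2.5, 97.5])
        sd = rep.std(ddof=1) if n_bootstrap > 1 else 0.0
        cv[i] = sd / m if m != 0 else 0.0
    return PrecisionCurve(
        sample_sizes=grid,
        means=means,
        ci_low=lo,
        ci_high=hi,
        cv=cv,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def stabilization_point(
    curve: PrecisionCurve, window: int = 10, tolerance: float = 0.15
) -> int | None:
    """Smallest sample size after which the CV curve has settled.

    Returns the first grid point n such that over the next ``window`` grid
    points the CV never moves by more than ``tolerance * cv(n)`` in
    absolute value; ``None`` if no point qualifies.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if window >= len(curve.sample_sizes):
        raise ValueError(
            f"window {window} exceeds curve length {len(curve.sample_sizes)}"
        )
    cv = curve.cv
    for i in range(len(cv) - window):
        ahead = cv[i + 1 : i + 1 + window]
        if np.all(np.abs(ahead - cv[i]) <= tolerance * cv[i]):
            return int(curve.sample_sizes[i])
    return None


def spoor_frequency_summary(
    intervals: Sequence[float], n_bootstrap: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Bootstrap mean spoor frequency and 95% CI at the full sample size."""
    values = np.asarray(list(intervals), dtype=float)
    if len(values) < 2:
        raise InsufficientDataError(
            f"need at least 2 inter-spoor intervals, got {len(values)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_bootstrap, len(values)))
    rep = values[idx].mean(axis=1)
    lo, hi = np.percentile(rep, [2.5, 97.5])
    return float(rep.mean()), (float(lo), float(hi))


def plot_curve(curve: PrecisionCurve, kind: str = "ci", ax=None):
    """Plot mean +/- CI ("ci") or the CV curve ("cv") against sample size."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    n = curve.sample_sizes
    if kind == "ci":
        ax.plot(n, curve.means, "o", ms=3, color="k")
        ax.vlines(n, curve.ci_low, curve.ci_high, color="k", lw=0.6)
        ax.set_ylabel("spoor frequency (km/spoor)")
    elif kind == "cv":
        ax.plot(n, curve.cv, "-", color="k")
        ax.set_ylabel("coefficient of variation")
    else:
        raise ValueError(f"unknown plot kind {kind!r}")
    ax.set_xlabel("sample size (number of intervals)")
    return ax
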