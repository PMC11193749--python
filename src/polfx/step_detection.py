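"""Noise estimation, smoothing, change-point step fitting and binarization.

Shared by the fluorescence-intensity pipeline (binarize bound/unbound) and
the base-pair activity pipeline (piecewise-constant rate plateaus).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "StepFit",
    "BinaryTrace",
    "sg_smooth",
    "mad_sigma",
    "fit_steps",
    "binarize",
    "min_run_filter",
]


@dataclass
class StepFit:
    """Piecewise-constant fit: interior change points and plateau levels.

    ``change_points`` are sample indices where a new plateau begins
    (sorted, unique, excluding 0 and n). Plateau ``k`` spans
    ``[boundaries[k], boundaries[k+1])`` where boundaries = [0, *cps, n].
    """

    change_points: np.ndarray
    levels: np.ndarray
    residual_sd: float
    n_samples: int

    @property
    def boundaries(self) -> np.ndarray:
        return np.concatenate(([0], self.change_points, [self.n_samples]))

    def fitted(self) -> np.ndarray:
        """The fitted piecewise-constant series."""
        out = np.empty(self.n_samples)
        b = self.boundaries
        for k, level in enumerate(self.levels):
            out[b[k] : b[k + 1]] = level
        return out

    def plateau_at(self, index: int) -> int:
        """Index of the plateau containing sample `index`."""
        b = self.boundaries
        return int(np.searchsorted(b, index, side="right") - 1)


@dataclass
class BinaryTrace:
    """0/1 state series with the threshold that produced it."""

    time: np.ndarray
    state: np.ndarray
    threshold_used: float
    k_sigma: float

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=int)
        if not np.isin(self.state, (0, 1)).all():
            raise ValueError("state must contain only 0 and 1")


def sg_smooth(series, window: int = 15, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing with polynomial endpoint extension."""
    y = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if y.size <= window:
        raise ValueError(f"series length {y.size} must exceed window {window}")
    return savgol_filter(y, window_length=window, polyorder=polyorder, mode="interp")


def sg_derivative(series, dt: float, window: int = 15, polyorder: int = 2) -> np.ndarray:
    """Smoothed first derivative (units of series per second)."""
    y = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if y.size <= window:
        raise ValueError(f"series length {y.size} must exceed window {window}")
    return savgol_filter(
        y, window_length=window, polyorder=polyorder, deriv=1, delta=dt, mode="interp"
    )


def mad_sigma(series) -> float:
    """Robust noise-SD estimate from sequential differences.

    ``1.4826 * median(|diff - median(diff)|) / sqrt(2)`` — the 1.4826 factor
    calibrates the MAD to a Gaussian SD and the sqrt(2) removes the variance
    doubling introduced by differencing, so the estimate targets the sample
    SD of the underlying noise and is insensitive to slow trends and steps.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise ValueError("mad_sigma needs at least 2 samples")
    d = np.diff(y)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _best_split(y: np.ndarray, csum: np.ndarray, csq: np.ndarray, lo: int, hi: int):
    """Best single split of y[lo:hi] minimizing residual sum of squares.

    Returns (gain, split_index) where gain is the RSS reduction; split must
    leave at least one sample on each side. O(n) via prefix sums.
    """
    n = hi - lo
    if n < 2:
        return 0.0, -1
    total_sum = csum[hi] - csum[lo]
    rss0 = (csq[hi] - csq[lo]) - total_sum**2 / n
    ks = np.arange(lo + 1, hi)
    left_n = ks - lo
    right_n = hi - ks
    left_sum = csum[ks] - csum[lo]
    right_sum = total_sum - left_sum
    rss = (
        (csq[hi] - csq[lo])
        - left_sum**2 / left_n
        - right_sum**2 / right_n
    )
    i = int(np.argmin(rss))
    gain = float(rss0 - rss[i])
    return gain, int(ks[i])


def fit_steps(series, sensitivity: float = 3.0, sigma: float | None = None) -> StepFit:
    """Greedy binary-split change-point fit of a piecewise-constant signal.

    Repeatedly splits the plateau whose best split most reduces the residual
    sum of squares, stopping when the best remaining gain falls below
    ``sensitivity * sigma^2 * log(n)`` (sigma defaults to :func:`mad_sigma`
    of the input). Deterministic for fixed input.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("fit_steps needs at least 4 samples")
    if sigma is None:
        sigma = mad_sigma(y)
    threshold = sensitivity * sigma**2 * np.log(n)
    csum = np.concatenate(([0.0], np.cumsum(y)))
    csq = np.concatenate(([0.0], np.cumsum(y**2)))

    boundaries = [0, n]
    # candidate best split per plateau, keyed by (lo, hi)
    candidates = {(0, n): _best_split(y, csum, csq, 0, n)}
    while True:
        (lo, hi), (gain, split) = max(
            candidates.items(), key=lambda kv: (kv[1][0], -kv[0][0])
        )
        if split < 0 or gain <= threshold:
            break
        del candidates[(lo, hi)]
        boundaries.append(split)
        candidates[(lo, split)] = _best_split(y, csum, csq, lo, split)
        candidates[(split, hi)] = _best_split(y, csum, csq, split, hi)

    boundaries = np.array(sorted(boundaries))
    cps = boundaries[1:-1]
    levels = np.array(
        [y[boundaries[k] : boundaries[k + 1]].mean() for k in range(len(boundaries) - 1)]
    )
    fit = StepFit(change_points=cps, levels=levels, residual_sd=0.0, n_samples=n)
    fit.residual_sd = float(np.std(y - fit.fitted()))
    return fit


def binarize(
    series,
    time=None,
    k_sigma: float = 4.0,
    sigma_source: Literal["background_region", "mad"] = "mad",
    background_region: slice | None = None,
) -> BinaryTrace:
    """Threshold a series at ``k_sigma`` noise SDs above background.

    ``sigma_source='background_region'`` estimates background level (median)
    and noise SD from a declared off-signal region; ``'mad'`` uses the full
    series median and the robust :func:`mad_sigma` estimate.
    """
    y = np.asarray(series, dtype=float)
    if not 3.0 <= k_sigma <= 5.0:
        raise ValueError("k_sigma must lie in [3, 5]")
    if sigma_source == "background_region":
        if background_region is None:
            raise ValueError("background_region slice required for this sigma_source")
        bg = y[background_region]
        if bg.size < 2:
            raise ValueError("background region too small")
        level = float(np.median(bg))
        sigma = float(np.std(bg))
    elif sigma_source == "mad":
        level = float(np.median(y))
        sigma = mad_sigma(y)
    else:
        raise ValueError(f"unknown sigma_source {sigma_source!r}")
    threshold = level + k_sigma * sigma
    t = np.arange(y.size, dtype=float) if time is None else np.asarray(time, dtype=float)
    return BinaryTrace(
        time=t,
        state=(y > threshold).astype(int),
        threshold_used=threshold,
        k_sigma=k_sigma,
    )


def runs_of_ones(state: Sequence[int]) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of maximal runs of 1."""
    s = np.asarray(state, dtype=int)
    if s.size == 0:
        return []
    padded = np.concatenate(([0], s, [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def min_run_filter(binary: BinaryTrace, min_len: int = 3) -> BinaryTrace:
    """Suppress runs of 1 shorter than `min_len` samples; runs of 0 untouched."""
    state = binary.state.copy()
    for start, stop in runs_of_ones(state):
        if stop - start < min_len:
            state[start:stop] = 0
    return BinaryTrace(
        time=binary.time.copy(),
        state=state,
        threshold_used=binary.threshold_used,
        k_sigma=binary.k_sigma,
    )
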