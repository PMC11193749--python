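"""Burst-segment extraction, pause detection and the memory-effect statistic.

Activity is read from the base-pair trace: the smoothed first derivative is
step-fitted into piecewise-constant rate plateaus, each classified as exo
(bp decreasing), pol (bp increasing) or pause (|rate| below the
force-regime cutoff).  Fluorescent burst segments are maximal runs of the
binarized junction intensity; their sub-interval labels decide single- vs
transitional-type.  The memory statistic counts (pre, during, post)
enzymatic/pause triplets over the eight possible configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from polfx.step_detection import (
    BinaryTrace,
    StepFit,
    fit_steps,
    mad_sigma,
    runs_of_ones,
    sg_derivative,
)

__all__ = [
    "PauseThresholds",
    "BurstSegment",
    "MemoryConfigCounts",
    "simplify_label",
    "segment_type_from_labels",
    "single_type_fraction",
    "classify_rate",
    "rate_trace",
    "detect_pauses",
    "extract_segments",
    "flanking_states",
    "memory_configuration_counts",
    "independence_null",
]

TRIPLETS = [
    (a, b, c) for a in "EP" for b in "EP" for c in "EP"
]  # (pre, during, post) in a fixed order


@dataclass(frozen=True)
class PauseThresholds:
    """Force-regime pause cutoffs (bp/s): ten-fold below the working rates."""

    high_force_cutoff: float = 10.0  # |rate| below this is a pause at F >= 40 pN
    low_force_cutoff: float = 20.0  # ... at F <= 20 pN
    high_force_min: float = 40.0
    low_force_max: float = 20.0

    def __post_init__(self) -> None:
        if self.high_force_cutoff <= 0 or self.low_force_cutoff <= 0:
            raise ValueError("pause cutoffs must be positive")

    def cutoff_for(self, force: float) -> float | None:
        """Regime cutoff, or None in the undeclared middle force band."""
        if force >= self.high_force_min:
            return self.high_force_cutoff
        if force <= self.low_force_max:
            return self.low_force_cutoff
        return None


@dataclass
class BurstSegment:
    """One contiguous fluorescent binding event with step-fitted activity."""

    t_start: float
    t_end: float
    sub_intervals: list[tuple[float, float, float, str]]  # (t0, t1, rate, label)
    mean_rate: float
    segment_type: Literal["single", "transitional"]
    pre_state: str | None = None  # 'E' / 'P' / None when unavailable
    post_state: str | None = None
    start_index: int = 0
    stop_index: int = 0

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def labels(self) -> list[str]:
        return [s[3] for s in self.sub_intervals]


@dataclass
class MemoryConfigCounts:
    """Counts of the eight (pre, during, post) ∈ {E,P}³ configurations."""

    counts: dict[tuple[str, str, str], int]
    n_total: int

    def fraction(self, triplet: tuple[str, str, str]) -> float:
        if self.n_total == 0:
            return 0.0
        return self.counts.get(triplet, 0) / self.n_total

    def fractions(self) -> dict[tuple[str, str, str], float]:
        return {t: self.fraction(t) for t in TRIPLETS}

    def errors(self) -> dict[tuple[str, str, str], float]:
        """Square-root-of-count error bars, expressed as fractions."""
        if self.n_total == 0:
            return {t: 0.0 for t in TRIPLETS}
        return {t: math.sqrt(self.counts.get(t, 0)) / self.n_total for t in TRIPLETS}


def segment_type_from_labels(labels: Sequence[str]) -> Literal["single", "transitional"]:
    """'single' iff at most one distinct activity label (ignoring unclassified)."""
    distinct = {lab for lab in labels if lab != "unclassified"}
    return "single" if len(distinct) <= 1 else "transitional"


def single_type_fraction(segments: Sequence[BurstSegment]) -> float:
    """Fraction of burst segments classified single-type."""
    if not segments:
        raise ValueError("no segments")
    return sum(1 for s in segments if s.segment_type == "single") / len(segments)


def simplify_label(label: str) -> str:
    """Collapse exo/pol to enzymatic 'E'; pause to 'P'."""
    if label in ("exo", "pol"):
        return "E"
    if label == "pause":
        return "P"
    raise ValueError(f"cannot simplify label {label!r}")


def classify_rate(
    rate: float, force: float, thresholds: PauseThresholds = PauseThresholds()
) -> str:
    """Label a plateau rate: 'exo', 'pol', 'pause' or 'unclassified'.

    Below the regime cutoff the plateau is a pause; otherwise the sign of
    the base-pair rate decides (negative = bp removal = exo).  Forces in the
    undeclared middle band are flagged 'unclassified'.
    """
    cutoff = thresholds.cutoff_for(force)
    if cutoff is None:
        return "unclassified"
    if abs(rate) < cutoff:
        return "pause"
    return "exo" if rate < 0 else "pol"


def rate_trace(
    bp: np.ndarray, dt: float, sg_window: int = 15, polyorder: int = 2
) -> np.ndarray:
    """Smoothed base-pair rate (bp/s) via the Savitzky-Golay derivative."""
    return sg_derivative(bp, dt=dt, window=sg_window, polyorder=polyorder)


def _merge_plateaus(
    fit: StepFit, time: np.ndarray, labels: list[str]
) -> list[tuple[int, int, float, str]]:
    """Merge consecutive equally-labeled plateaus; returns (i0, i1, rate, label)."""
    b = fit.boundaries
    merged: list[tuple[int, int, float, str]] = []
    for k, label in enumerate(labels):
        i0, i1 = int(b[k]), int(b[k + 1])
        if merged and merged[-1][3] == label:
            p0, p1, prate, _ = merged[-1]
            w0, w1 = p1 - p0, i1 - i0
            merged[-1] = (p0, i1, (prate * w0 + fit.levels[k] * w1) / (w0 + w1), label)
        else:
            merged.append((i0, i1, float(fit.levels[k]), label))
    return merged


def detect_pauses(
    bp: np.ndarray,
    time: np.ndarray,
    force: np.ndarray,
    thresholds: PauseThresholds = PauseThresholds(),
    min_pause_duration: float | None = None,
    sg_window: int = 15,
    sensitivity: float = 3.0,
) -> list[tuple[float, float]]:
    """Pause intervals: step-fit rate plateaus below the regime cutoff.

    The default minimum duration is ten times the single-cutoff traversal
    time, ``10 / cutoff`` seconds, evaluated per interval's force regime.
    """
    dt = float(time[1] - time[0])
    rates = rate_trace(bp, dt, sg_window=sg_window)
    fit = fit_steps(rates, sensitivity=sensitivity)
    b = fit.boundaries
    labels = []
    for k, level in enumerate(fit.levels):
        mid = (int(b[k]) + int(b[k + 1])) // 2
        labels.append(classify_rate(level, float(force[mid]), thresholds))
    out: list[tuple[float, float]] = []
    for i0, i1, _rate, label in _merge_plateaus(fit, time, labels):
        if label != "pause":
            continue
        t0, t1 = float(time[i0]), float(time[i1 - 1]) + dt
        cutoff = thresholds.cutoff_for(float(force[(i0 + i1) // 2]))
        min_dur = (10.0 / cutoff) if min_pause_duration is None else min_pause_duration
        if t1 - t0 >= min_dur:
            out.append((t0, t1))
    return out


def extract_segments(
    binary_fluor: BinaryTrace,
    bp: np.ndarray,
    time: np.ndarray,
    force: np.ndarray,
    thresholds: PauseThresholds = PauseThresholds(),
    sg_window: int = 15,
    sensitivity: float = 3.0,
) -> list[BurstSegment]:
    """One burst segment per maximal run of binarized fluorescence.

    Within each run the step-fitted rate trace defines labeled
    sub-intervals; a segment is 'single' iff one distinct label remains
    after merging, 'transitional' otherwise.
    """
    if binary_fluor.state.size != bp.size:
        raise ValueError("fluorescence and base-pair traces must share a time base")
    dt = float(time[1] - time[0])
    rates = rate_trace(bp, dt, sg_window=sg_window)
    global_sigma = mad_sigma(rates)
    segments: list[BurstSegment] = []
    for start, stop in runs_of_ones(binary_fluor.state):
        seg_rates = rates[start:stop]
        if seg_rates.size >= 4:
            fit = fit_steps(seg_rates, sensitivity=sensitivity, sigma=global_sigma)
        else:
            fit = StepFit(
                change_points=np.array([], dtype=int),
                levels=np.array([float(np.mean(seg_rates))]),
                residual_sd=0.0,
                n_samples=seg_rates.size,
            )
        b = fit.boundaries
        labels = []
        for k, level in enumerate(fit.levels):
            mid = start + (int(b[k]) + int(b[k + 1])) // 2
            labels.append(classify_rate(level, float(force[mid]), thresholds))
        merged = _merge_plateaus(fit, time[start:stop], labels)
        subs = [
            (float(time[start + i0]), float(time[start + i1 - 1]) + dt, r, lab)
            for i0, i1, r, lab in merged
        ]
        seg_type = segment_type_from_labels([lab for _, _, _, lab in subs])
        durations = np.array([t1 - t0 for t0, t1, _, _ in subs])
        seg_rates_w = np.array([r for _, _, r, _ in subs])
        mean_rate = float(np.average(seg_rates_w, weights=durations))
        segments.append(
            BurstSegment(
                t_start=float(time[start]),
                t_end=float(time[stop - 1]) + dt,
                sub_intervals=subs,
                mean_rate=mean_rate,
                segment_type=seg_type,
                start_index=start,
                stop_index=stop,
            )
        )
    return segments


def flanking_states(
    segment: BurstSegment,
    bp: np.ndarray,
    time: np.ndarray,
    force: np.ndarray,
    thresholds: PauseThresholds = PauseThresholds(),
    flank_window: float = 0.5,
    sg_window: int = 15,
    sensitivity: float = 3.0,
    fitted_rates: np.ndarray | None = None,
) -> tuple[str | None, str | None]:
    """Simplified E/P state immediately before and after a segment.

    The mean step-fitted rate over the ``flank_window`` adjacent to each
    boundary is classified; a flank closer than ``flank_window`` to the
    trace edge is unavailable (None).  ``fitted_rates`` may carry a
    precomputed step-fitted rate trace to avoid refitting per segment.

    A guard of half the smoothing window separates the flank from the
    segment boundary, since the derivative filter smears rate transitions
    over that span.
    """
    dt = float(time[1] - time[0])
    n_w = max(int(round(flank_window / dt)), 1)
    guard = sg_window // 2
    if fitted_rates is not None:
        fitted = np.asarray(fitted_rates, dtype=float)
        rates = fitted
    else:
        rates = rate_trace(bp, dt, sg_window=sg_window)
        fitted = fit_steps(rates, sensitivity=sensitivity).fitted()

    def _state(lo: int, hi: int) -> str | None:
        if lo < 0 or hi > rates.size or hi <= lo:
            return None
        level = float(np.mean(fitted[lo:hi]))
        mid = (lo + hi) // 2
        label = classify_rate(level, float(force[mid]), thresholds)
        return None if label == "unclassified" else simplify_label(label)

    pre = _state(segment.start_index - guard - n_w, segment.start_index - guard)
    post = _state(segment.stop_index + guard, segment.stop_index + guard + n_w)
    return pre, post


def memory_configuration_counts(segments: Sequence[BurstSegment]) -> MemoryConfigCounts:
    """Count the eight (pre, during, post) configurations of state switching.

    Only single-type segments with both flanks available contribute; the
    'during' state is the segment's own simplified label.
    """
    counts: dict[tuple[str, str, str], int] = {t: 0 for t in TRIPLETS}
    n = 0
    for seg in segments:
        if seg.segment_type != "single":
            continue
        if seg.pre_state is None or seg.post_state is None:
            continue
        label = next((lab for lab in seg.labels if lab != "unclassified"), None)
        if label is None:
            continue
        triplet = (seg.pre_state, simplify_label(label), seg.post_state)
        counts[triplet] += 1
        n += 1
    return MemoryConfigCounts(counts=counts, n_total=n)


def independence_null(counts: MemoryConfigCounts) -> tuple[float, float, np.ndarray]:
    """Chi-squared test of (pre, during, post) independence.

    Expected cell counts are the products of the three marginal E-fractions;
    returns ``(chi2, p_value, expected_counts)`` with 4 degrees of freedom
    (8 cells − 1 − 3 estimated marginals).
    """
    n = counts.n_total
    if n == 0:
        raise ValueError("no configurations counted")
    obs = np.array([counts.counts.get(t, 0) for t in TRIPLETS], dtype=float)
    marg = []
    for axis in range(3):
        pE = sum(c for t, c in counts.counts.items() if t[axis] == "E") / n
        marg.append({"E": pE, "P": 1.0 - pE})
    expected = np.array(
        [n * marg[0][t[0]] * marg[1][t[1]] * marg[2][t[2]] for t in TRIPLETS]
    )
    keep = expected > 0
    chi2 = float(np.sum((obs[keep] - expected[keep]) ** 2 / expected[keep]))
    dof = max(int(keep.sum()) - 1 - 3, 1)
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, p, expected
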