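"""Binarized activity × fluorescence correlation classes and event clusters.

Each time sample is assigned one of four classes [fluorescence, activity]:
[1,1] fluorescent active, [1,0] fluorescent pausing, [0,1] non-fluorescent
active, [0,0] non-fluorescent pausing.  Molecular events are maximal runs
of identical class at least ``min_len`` samples long.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from polfx.step_detection import BinaryTrace

__all__ = [
    "CorrelationSeries",
    "EventClusterCounts",
    "CLASSES",
    "build_correlation_series",
    "cluster_events",
    "fluorescent_event_fraction",
    "nonfluorescent_pause_fraction",
]

#: Class code order: index = 2*fluorescence + activity.
CLASSES = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class CorrelationSeries:
    """Per-sample [fluorescence, activity] class codes."""

    time: np.ndarray
    fluorescence: np.ndarray  # 0/1
    activity: np.ndarray  # 0/1

    @property
    def classes(self) -> np.ndarray:
        """Integer class code per sample: 2*fluor + activity."""
        return 2 * self.fluorescence + self.activity


@dataclass(frozen=True)
class EventClusterCounts:
    """Cluster counts per class ([1,1], [1,0], [0,1], [0,0])."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def build_correlation_series(
    binary_fluor: BinaryTrace, binary_activity: BinaryTrace
) -> CorrelationSeries:
    """Pair two binary traces sample by sample on a shared time base."""
    if binary_fluor.state.size != binary_activity.state.size:
        raise ValueError("fluorescence and activity traces differ in length")
    if not np.allclose(binary_fluor.time, binary_activity.time):
        raise ValueError("fluorescence and activity traces have mismatched time bases")
    return CorrelationSeries(
        time=binary_fluor.time.copy(),
        fluorescence=binary_fluor.state.copy(),
        activity=binary_activity.state.copy(),
    )


def cluster_events(series: CorrelationSeries, min_len: int = 3) -> EventClusterCounts:
    """Count maximal runs of identical class, discarding runs < min_len."""
    codes = series.classes
    counts = {c: 0 for c in range(4)}
    if codes.size:
        boundaries = np.flatnonzero(np.diff(codes) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [codes.size]))
        for s, e in zip(starts, stops):
            if e - s >= min_len:
                counts[int(codes[s])] += 1
    return EventClusterCounts(
        n11=counts[3], n10=counts[2], n01=counts[1], n00=counts[0]
    )


def fluorescent_event_fraction(counts: EventClusterCounts) -> float:
    """Fraction of all event clusters that are fluorescent: (n11+n10)/total."""
    if counts.total == 0:
        raise ValueError("no events counted")
    return (counts.n11 + counts.n10) / counts.total


def nonfluorescent_pause_fraction(counts: EventClusterCounts) -> float | None:
    """Fraction of pausing clusters that are non-fluorescent: n00/(n00+n10).

    Returns None (missing, per-molecule statistic) when no pausing clusters
    were observed.
    """
    denom = counts.n00 + counts.n10
    if denom == 0:
        return None
    return counts.n00 / denom
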