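"""Kymograph ↔ junction-trajectory registration and intensity extraction.

The reconstructed junction trajectory (from the trap) and the fluorescence
kymograph (from the confocal scan) are recorded on different clocks and
frames.  Coarse offsets are supplied by configuration; refinement is an
exhaustive integer grid search maximizing total in-box photons within a
±5-pixel range, followed by box-summed intensity extraction along the
junction line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "Kymograph",
    "RegistrationOffsets",
    "JunctionIntensity",
    "junction_to_pixels",
    "refine_offsets",
    "extract_junction_intensity",
    "classify_binding_position",
]


@dataclass
class Kymograph:
    """2-D photon-count image: lines (time) × pixels (position)."""

    photons: np.ndarray
    line_time: float  # s
    pixel_size: float  # µm
    origin_position: float = 0.0  # µm of pixel 0 (pixel centers at origin + (i+.5)*px)
    bead_band_pixels: int = 0

    def __post_init__(self) -> None:
        self.photons = np.asarray(self.photons)
        if self.photons.ndim != 2:
            raise ValueError("photons must be a 2-D (lines × pixels) array")
        if np.any(self.photons < 0):
            raise ValueError("photon counts must be non-negative")
        if self.line_time <= 0 or self.pixel_size <= 0:
            raise ValueError("line_time and pixel_size must be positive")

    @property
    def n_lines(self) -> int:
        return self.photons.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.photons.shape[1]

    @property
    def line_times(self) -> np.ndarray:
        """Timestamp (line center) of each scan line, in s."""
        return (np.arange(self.n_lines) + 0.5) * self.line_time

    def signal_mask(self) -> np.ndarray:
        """Boolean pixel mask excluding the bead bands at both edges."""
        mask = np.ones(self.n_pixels, dtype=bool)
        if self.bead_band_pixels > 0:
            mask[: self.bead_band_pixels] = False
            mask[-self.bead_band_pixels :] = False
        return mask


@dataclass(frozen=True)
class RegistrationOffsets:
    """Integer alignment: x along time (lines), y along position (pixels)."""

    x_offset: int
    y_offset: int
    objective_value: float  # total in-box photons at the optimum


@dataclass
class JunctionIntensity:
    """Box-summed photon counts along the registered junction line.

    ``counts`` is NaN where the box lies fully outside the frame or the
    trajectory sample is missing; ``truncated`` flags partial boxes.
    """

    time: np.ndarray
    counts: np.ndarray
    truncated: np.ndarray


def junction_to_pixels(traj, kymo: Kymograph) -> tuple[np.ndarray, np.ndarray]:
    """Map the junction trajectory onto kymograph pixel coordinates.

    The trajectory is resampled to line times by nearest sample.  Returns
    ``(pixels, in_frame)``; out-of-frame or flagged lines have pixel -1 and
    ``in_frame`` False.
    """
    t_lines = kymo.line_times
    if traj.time.size == 0 or t_lines.size == 0:
        raise ValueError("empty trajectory or kymograph")
    if t_lines[-1] < traj.time[0] or t_lines[0] > traj.time[-1]:
        raise ValueError("trajectory and kymograph do not overlap in time")
    idx = np.clip(np.searchsorted(traj.time, t_lines), 0, traj.time.size - 1)
    left = np.clip(idx - 1, 0, traj.time.size - 1)
    take_left = np.abs(traj.time[left] - t_lines) <= np.abs(traj.time[idx] - t_lines)
    idx = np.where(take_left, left, idx)
    pos = traj.junction_position[idx]
    px = np.floor((pos - kymo.origin_position) / kymo.pixel_size).astype(float)
    in_frame = np.isfinite(pos) & (px >= 0) & (px < kymo.n_pixels)
    if hasattr(traj, "flagged") and traj.flagged is not None:
        in_frame &= ~np.asarray(traj.flagged)[idx]
    out = np.where(in_frame, px, -1).astype(int)
    return out, in_frame


def _box_cumsum(kymo: Kymograph) -> np.ndarray:
    """Per-line prefix sums of bead-masked photon counts (shape lines × px+1)."""
    masked = np.asarray(kymo.photons, dtype=float) * kymo.signal_mask()
    return np.concatenate(
        [np.zeros((kymo.n_lines, 1)), np.cumsum(masked, axis=1)], axis=1
    )


def _box_total(
    csum: np.ndarray,
    pixels: np.ndarray,
    valid: np.ndarray,
    dx: int,
    dy: int,
    half: int,
) -> float:
    """Total photons in boxes centered at pixels[line - dx] + dy, bead bands excluded."""
    n_lines = csum.shape[0]
    n_px = csum.shape[1] - 1
    lines = np.arange(n_lines)
    src = lines - dx
    ok = (src >= 0) & (src < n_lines)
    ok[ok] &= valid[src[ok]]
    i = lines[ok]
    c = pixels[src[ok]] + dy
    lo = np.clip(c - half, 0, n_px)
    hi = np.clip(c + half + 1, 0, n_px)
    hi = np.maximum(hi, lo)
    return float((csum[i, hi] - csum[i, lo]).sum())


def refine_offsets(
    kymo: Kymograph,
    traj,
    search_range: int = 5,
    box_width: int = 5,
    coarse: tuple[int, int] = (0, 0),
) -> RegistrationOffsets:
    """Exhaustive grid search for the offsets maximizing in-box photons.

    All integer ``(dx, dy)`` within ``coarse ± search_range`` are scored;
    ties break toward the smallest ``|dx| + |dy|``, then smallest ``dy``,
    then smallest ``dx``, making the result deterministic.
    """
    if box_width % 2 == 0 or box_width < 1:
        raise ValueError("box_width must be an odd positive integer")
    if not np.any(np.asarray(kymo.photons)[:, kymo.signal_mask()]):
        raise ValueError("no signal to register: kymograph is all zero")
    pixels, valid = junction_to_pixels(traj, kymo)
    half = box_width // 2
    csum = _box_cumsum(kymo)
    best = None
    for dx in range(coarse[0] - search_range, coarse[0] + search_range + 1):
        for dy in range(coarse[1] - search_range, coarse[1] + search_range + 1):
            obj = _box_total(csum, pixels, valid, dx, dy, half)
            key = (-obj, abs(dx) + abs(dy), dy, dx)
            if best is None or key < best[0]:
                best = (key, RegistrationOffsets(dx, dy, obj))
    return best[1]


def extract_junction_intensity(
    kymo: Kymograph,
    traj,
    offsets: RegistrationOffsets = RegistrationOffsets(0, 0, 0.0),
    box_width: int = 5,
) -> JunctionIntensity:
    """Box-summed intensity along the offset-corrected junction line.

    Boxes are truncated at frame edges (flagged); bead-band pixels never
    contribute.  Lines whose box lies fully outside the frame, or whose
    trajectory sample is missing, yield NaN.
    """
    if box_width % 2 == 0 or box_width < 1:
        raise ValueError("box_width must be an odd positive integer")
    pixels, valid = junction_to_pixels(traj, kymo)
    half = box_width // 2
    mask = kymo.signal_mask()
    n_lines, n_px = kymo.n_lines, kymo.n_pixels
    counts = np.full(n_lines, np.nan)
    truncated = np.zeros(n_lines, dtype=bool)
    for i in range(n_lines):
        j = i - offsets.x_offset
        if j < 0 or j >= n_lines or not valid[j]:
            continue
        c = pixels[j] + offsets.y_offset
        lo, hi = c - half, c + half + 1
        clo, chi = max(lo, 0), min(hi, n_px)
        if clo >= chi:
            continue
        cols = np.arange(clo, chi)
        cols = cols[mask[cols]]
        counts[i] = float(kymo.photons[i, cols].sum()) if cols.size else 0.0
        truncated[i] = (clo != lo) or (chi != hi)
    return JunctionIntensity(time=kymo.line_times, counts=counts, truncated=truncated)


def classify_binding_position(
    particle_pixels,
    junction_pixels,
    tolerance: int = 3,
    orientation: Literal["ss_top", "ds_top"] = "ss_top",
    n_pixels: int | None = None,
) -> Literal["junction", "ssDNA", "dsDNA"]:
    """Classify a particle trajectory as junction-, ssDNA- or dsDNA-bound.

    Per line the particle is 'junction' within ``±tolerance`` pixels of the
    junction line, otherwise labeled by which side it sits on (with
    ``ss_top`` the low-pixel side is ssDNA).  The majority label over the
    trajectory's lifetime wins; ties prefer 'junction'.
    """
    p = np.asarray(particle_pixels, dtype=float)
    jp = np.asarray(junction_pixels, dtype=float)
    if p.shape != jp.shape:
        raise ValueError("particle and junction pixel series must align")
    if n_pixels is not None and (np.any(p < 0) or np.any(p >= n_pixels)):
        raise ValueError("particle trajectory lies outside the frame")
    d = p - jp
    at_junction = np.abs(d) <= tolerance
    top_side = d < 0
    top_label = "ssDNA" if orientation == "ss_top" else "dsDNA"
    bottom_label = "dsDNA" if orientation == "ss_top" else "ssDNA"
    n_j = int(at_junction.sum())
    n_top = int((top_side & ~at_junction).sum())
    n_bottom = int((~top_side & ~at_junction).sum())
    best = max(n_j, n_top, n_bottom)
    if n_j == best:
        return "junction"
    return top_label if n_top == best else bottom_label
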