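"""Bound-lifetime fitting with photobleaching correction; MSD diffusion.

Lifetimes: observed fluorescence durations are the minimum of the true
bound dwell and the fluorophore's bleaching time, both exponential, so
``1/tau_obs = 1/tau_off + 1/tau_bleach`` and the bleaching contribution can
be removed exactly.  The observed scale is fitted by survival-curve maximum
likelihood (the sample mean, for an exponential).

Diffusion: particle trajectories are extracted from the kymograph by
per-line peak detection with centroid refinement and nearest-neighbour
linking; the time-averaged MSD is fitted as ``MSD = 2 D τ + b`` (1-D
convention, intercept absorbing localization noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from polfx.kymo_registration import Kymograph
from polfx.step_detection import mad_sigma

__all__ = [
    "LifetimeFit",
    "DiffusionEstimate",
    "ParticleTrack",
    "fit_lifetime",
    "track_particles",
    "msd",
    "fit_diffusion",
]


@dataclass(frozen=True)
class LifetimeFit:
    tau_observed: float  # s
    tau_corrected: float  # s
    tau_bleach_used: float  # s (inf = no bleaching)
    fit_error: float  # s, SE on the corrected scale
    n_events: int
    degenerate: bool = False  # all durations identical


@dataclass(frozen=True)
class DiffusionEstimate:
    D: float  # µm²/s, truncated at 0
    intercept: float  # µm², localization-noise term
    fit_lags: int
    n_points: int
    truncated: bool = False  # negative slope was clipped to D = 0


@dataclass
class ParticleTrack:
    """A linked emitter trajectory through the kymograph."""

    lines: np.ndarray  # line indices (may skip gap-closed lines)
    times: np.ndarray  # s
    positions: np.ndarray  # µm
    photons: np.ndarray  # box-summed counts per detection

    def __len__(self) -> int:
        return self.lines.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) > 1 else 0.0


def fit_lifetime(durations, tau_bleach: float = math.inf) -> LifetimeFit:
    """Mean bound lifetime with photobleaching correction.

    The exponential survival-curve MLE of the observed durations is the
    sample mean; the bleaching channel is removed via
    ``tau_corrected = 1 / (1/tau_observed - 1/tau_bleach)``.  The standard
    error ``tau_obs/sqrt(n)`` is propagated to the corrected scale.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 10:
        raise ValueError("need at least 10 events to fit a lifetime")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    if tau_bleach <= 0:
        raise ValueError("tau_bleach must be positive (use inf for no bleaching)")
    tau_obs = float(np.mean(d))
    degenerate = bool(np.ptp(d) == 0)
    if math.isfinite(tau_bleach):
        if tau_obs >= tau_bleach:
            raise ValueError(
                f"lifetime not identifiable: observed mean {tau_obs:.3g} s >= "
                f"bleaching time {tau_bleach:.3g} s"
            )
        tau_corr = 1.0 / (1.0 / tau_obs - 1.0 / tau_bleach)
    else:
        tau_corr = tau_obs
    se_obs = tau_obs / math.sqrt(d.size)
    se_corr = se_obs * (tau_corr / tau_obs) ** 2  # delta method
    return LifetimeFit(
        tau_observed=tau_obs,
        tau_corrected=tau_corr,
        tau_bleach_used=tau_bleach,
        fit_error=se_corr,
        n_events=d.size,
        degenerate=degenerate,
    )


def _detect_peaks(
    row: np.ndarray,
    mask: np.ndarray,
    threshold: float,
    half: int = 2,
    smooth_row: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """Local maxima above threshold with centroid refinement over ±half px.

    Maxima are found on ``smooth_row`` (Poisson noise splits a PSF into
    several raw maxima) while centroids use the raw counts.  Returns
    (subpixel position in px, box photon total) per detection.
    """
    s = row if smooth_row is None else smooth_row
    out = []
    n = row.size
    for j in range(n):
        if not mask[j] or s[j] <= threshold:
            continue
        left = s[j - 1] if j > 0 and mask[j - 1] else -np.inf
        right = s[j + 1] if j < n - 1 and mask[j + 1] else -np.inf
        if s[j] < left or s[j] < right:
            continue
        lo, hi = max(j - half, 0), min(j + half + 1, n)
        cols = np.arange(lo, hi)
        cols = cols[mask[cols]]
        w = row[cols].astype(float)
        total = float(w.sum())
        if total <= 0:
            continue
        pos = float((cols * w).sum() / total)
        out.append((pos, total))
    # merge detections closer than a PSF width (same emitter)
    out.sort()
    merged: list[tuple[float, float]] = []
    for pos, tot in out:
        if merged and pos - merged[-1][0] <= 2 * half:
            if tot > merged[-1][1]:
                merged[-1] = (pos, tot)
        else:
            merged.append((pos, tot))
    return merged


def track_particles(
    kymo: Kymograph,
    k_sigma: float = 4.0,
    max_jump: float = 2.0,
    max_gap: int = 2,
    min_length: int = 3,
) -> list[ParticleTrack]:
    """Detect-then-link particle tracking on a background-subtracted kymograph.

    Per line, local maxima above ``median + k_sigma * MAD-sigma`` (bead
    bands excluded) are localized by 5-pixel centroid; detections are linked
    nearest-neighbour within ``max_jump`` pixels, closing gaps up to
    ``max_gap`` lines.  Tracks shorter than ``min_length`` detections are
    dropped.
    """
    img = np.asarray(kymo.photons, dtype=float)
    mask = kymo.signal_mask()
    flat = img[:, mask].ravel()
    background = float(np.median(flat))
    sigma = mad_sigma(flat)
    if sigma == 0:
        sigma = max(math.sqrt(max(background, 1.0)), 1.0)  # Poisson fallback
    threshold = background + k_sigma * sigma
    times = kymo.line_times

    open_tracks: list[dict] = []
    done: list[ParticleTrack] = []

    def _close(tr: dict) -> None:
        if len(tr["lines"]) >= min_length:
            done.append(
                ParticleTrack(
                    lines=np.array(tr["lines"]),
                    times=times[np.array(tr["lines"])],
                    positions=np.array(tr["pos"]) * kymo.pixel_size
                    + kymo.origin_position,
                    photons=np.array(tr["phot"]),
                )
            )

    from scipy.ndimage import gaussian_filter1d

    # zero bead-band pixels before smoothing so their brightness cannot
    # bleed into adjacent columns and fake detections
    smooth = gaussian_filter1d(img * mask, sigma=1.0, axis=1, mode="nearest")
    for i in range(kymo.n_lines):
        detections = _detect_peaks(
            img[i] - background,
            mask,
            threshold - background,
            smooth_row=smooth[i] - background,
        )
        unmatched = list(range(len(detections)))
        # greedy nearest-neighbour matching, deterministic order by distance
        pairs = []
        for ti, tr in enumerate(open_tracks):
            for di in unmatched:
                dist = abs(detections[di][0] - tr["pos"][-1])
                if dist <= max_jump:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t, used_d = set(), set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = open_tracks[ti]
            tr["lines"].append(i)
            tr["pos"].append(detections[di][0])
            tr["phot"].append(detections[di][1])
        survivors = []
        for ti, tr in enumerate(open_tracks):
            if ti in used_t or i - tr["lines"][-1] <= max_gap:
                survivors.append(tr)
            else:
                _close(tr)
        open_tracks = survivors
        for di in range(len(detections)):
            if di not in used_d:
                open_tracks.append(
                    {
                        "lines": [i],
                        "pos": [detections[di][0]],
                        "phot": [detections[di][1]],
                    }
                )
    for tr in open_tracks:
        _close(tr)
    return done


def msd(track: ParticleTrack, max_lag_fraction: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged mean squared displacement over overlapping pairs.

    Returns ``(lags_s, msd_um2)`` for lags 1 .. floor(N * max_lag_fraction).
    Trajectories shorter than 8 points are rejected.
    """
    n = len(track)
    if n < 8:
        raise ValueError("trajectory too short for MSD (need >= 8 points)")
    dt = float(np.median(np.diff(track.times)))
    max_lag = max(int(n * max_lag_fraction), 3)
    lags = np.arange(1, max_lag + 1)
    out = np.empty(lags.size)
    x = track.positions
    for k, lag in enumerate(lags):
        d = x[lag:] - x[:-lag]
        out[k] = float(np.mean(d * d))
    return lags * dt, out


def fit_diffusion(
    lags_s: np.ndarray, msd_um2: np.ndarray, fit_lags: int = 4
) -> DiffusionEstimate:
    """Weighted linear fit ``MSD = 2 D τ + b`` over the first ``fit_lags`` lags.

    Weights fall with lag (fewer independent displacement pairs at long
    lag); a negative slope is truncated to D = 0 and flagged.
    """
    lags_s = np.asarray(lags_s, dtype=float)
    msd_um2 = np.asarray(msd_um2, dtype=float)
    if lags_s.size < 3:
        raise ValueError("need at least 3 lag points to fit diffusion")
    m = min(fit_lags, lags_s.size)
    x, y = lags_s[:m], msd_um2[:m]
    w = 1.0 / np.arange(1, m + 1)
    W = np.diag(w)
    A = np.column_stack([x, np.ones(m)])
    coef, *_ = np.linalg.lstsq(np.sqrt(W) @ A, np.sqrt(w) * y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    truncated = slope < 0
    D = max(slope / 2.0, 0.0)
    return DiffusionEstimate(
        D=D, intercept=intercept, fit_lags=m, n_points=lags_s.size, truncated=truncated
    )
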