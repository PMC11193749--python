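"""DNA elasticity models and junction-trajectory reconstruction.

Single-stranded DNA is described by an extensible freely-jointed chain (FJC),
double-stranded DNA by the extensible worm-like chain (WLC) in its high-force
(Odijk) form.  From a synchronized (force, end-to-end distance) trace the
ssDNA fraction, junction position along the tether and remaining
double-stranded base pairs are reconstructed sample by sample.

Units: forces in pN, distances in µm, model parameters in nm (converted
internally), thermal energy in pN·nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ElasticityParams",
    "ForceExtensionTrace",
    "JunctionTrajectory",
    "Orientation",
    "fjc_extension",
    "wlc_extension",
    "ss_fraction_from_eed",
    "ds_fraction",
    "junction_position",
    "basepairs_from_fraction",
    "reconstruct_junction",
]

Orientation = Literal["ss_top", "ds_top"]

#: Minimum force (pN) at which the Odijk high-force WLC form is trusted.
WLC_FORCE_MIN = 5.0


@dataclass(frozen=True)
class ElasticityParams:
    """Elastic parameters of the ssDNA (FJC) and dsDNA (WLC) models.

    Defaults are standard literature values for the 10–50 pN operating
    regime; none are fitted here and all may be overridden.
    """

    ss_contour_per_nt: float = 0.56  # nm / nucleotide
    ss_kuhn_length: float = 1.5  # nm
    ss_stretch_modulus: float = 800.0  # pN
    ds_contour_per_bp: float = 0.338  # nm / bp
    ds_persistence_length: float = 50.0  # nm
    ds_stretch_modulus: float = 1500.0  # pN
    kBT: float = 4.11  # pN·nm
    total_bp: int = 8393

    def __post_init__(self) -> None:
        for name in (
            "ss_contour_per_nt",
            "ss_kuhn_length",
            "ss_stretch_modulus",
            "ds_contour_per_bp",
            "ds_persistence_length",
            "ds_stretch_modulus",
            "kBT",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.total_bp < 1:
            raise ValueError("total_bp must be >= 1")

    @property
    def ss_contour_um(self) -> float:
        """Full ssDNA contour length of the template, in µm."""
        return self.total_bp * self.ss_contour_per_nt * 1e-3

    @property
    def ds_contour_um(self) -> float:
        """Full dsDNA contour length of the template, in µm."""
        return self.total_bp * self.ds_contour_per_bp * 1e-3


@dataclass
class ForceExtensionTrace:
    """Synchronized trap time series: time (s), force (pN), EED (µm)."""

    time: np.ndarray
    force: np.ndarray
    eed: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.eed = np.asarray(self.eed, dtype=float)
        if not (self.time.shape == self.force.shape == self.eed.shape):
            raise ValueError("time, force and eed must have equal length")
        if self.time.ndim != 1:
            raise ValueError("trace series must be one-dimensional")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.force < 0):
            raise ValueError("force must be non-negative")
        if np.any(self.eed <= 0):
            raise ValueError("eed must be strictly positive")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class JunctionTrajectory:
    """Per-sample junction state reconstructed from a force-extension trace."""

    time: np.ndarray
    ss_fraction: np.ndarray
    junction_position: np.ndarray  # µm from the declared template end
    basepairs_ds: np.ndarray  # integer bp remaining double-stranded
    orientation: Orientation = "ss_top"
    clamp_count: int = 0
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = np.zeros(len(self.time), dtype=bool)


def _as_positive_force(force, minimum: float, what: str):
    f = np.asarray(force, dtype=float)
    if np.any(f < minimum) or np.any(~np.isfinite(f)):
        raise ValueError(
            f"{what} requires force >= {minimum} pN (validity limit); got {force!r}"
        )
    return f


def fjc_extension(force, params: ElasticityParams = ElasticityParams()):
    """Extension (µm) of the full-length ssDNA template under `force` (pN).

    Extensible freely-jointed chain:
    ``Lc_ss * [coth(F b / kBT) - kBT / (F b)] * (1 + F / S_ss)``.
    Monotone increasing in force; force must be strictly positive.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f <= 0) or np.any(~np.isfinite(f)):
        raise ValueError("fjc_extension requires force > 0 pN")
    x = f * params.ss_kuhn_length / params.kBT
    langevin = 1.0 / np.tanh(x) - 1.0 / x
    out = params.ss_contour_um * langevin * (1.0 + f / params.ss_stretch_modulus)
    return out if out.ndim else float(out)


def wlc_extension(force, params: ElasticityParams = ElasticityParams()):
    """Extension (µm) of the full-length dsDNA template under `force` (pN).

    Extensible worm-like chain, Odijk high-force form:
    ``Lc_ds * [1 - 1/2 sqrt(kBT / (F Lp)) + F / S_ds]``, valid above
    ``WLC_FORCE_MIN`` (5 pN).
    """
    f = _as_positive_force(force, WLC_FORCE_MIN, "wlc_extension (Odijk form)")
    out = params.ds_contour_um * (
        1.0
        - 0.5 * np.sqrt(params.kBT / (f * params.ds_persistence_length))
        + f / params.ds_stretch_modulus
    )
    return out if out.ndim else float(out)


def ss_fraction_from_eed(eed, force, params: ElasticityParams = ElasticityParams()):
    """ssDNA fraction from the measured EED via linear mixture inversion.

    ``ss% = (EED - WLC(F)) / (FJC(F) - WLC(F))``, clamped to [0, 1].

    Returns
    -------
    (fraction, n_clamped) : value(s) in [0, 1] plus the number of samples
        that fell outside [0, 1] before clamping.
    """
    fjc = np.asarray(fjc_extension(force, params), dtype=float)
    wlc = np.asarray(wlc_extension(force, params), dtype=float)
    denom = fjc - wlc
    if np.any(denom == 0):
        raise ValueError("degenerate elasticity models: FJC(F) == WLC(F)")
    raw = (np.asarray(eed, dtype=float) - wlc) / denom
    n_clamped = int(np.count_nonzero((raw < 0) | (raw > 1)))
    clipped = np.clip(raw, 0.0, 1.0)
    return (clipped if clipped.ndim else float(clipped)), n_clamped


def ds_fraction(ss_fraction):
    """dsDNA fraction, the complement ``1 - ss_fraction``."""
    s = np.asarray(ss_fraction, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("ss_fraction must lie in [0, 1]")
    out = 1.0 - s
    return out if out.ndim else float(out)


def junction_position(
    ss_fraction,
    force,
    eed,
    orientation: Orientation = "ss_top",
    params: ElasticityParams = ElasticityParams(),
):
    """Junction position (µm) measured from the top of the kymograph frame.

    With ssDNA on top the junction sits at
    ``ss% FJC(F) / (ss% FJC(F) + ds% WLC(F)) * EED``; with dsDNA on top at
    the complement ``EED`` minus that quantity.
    """
    s = np.asarray(ss_fraction, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("ss_fraction must lie in [0, 1]")
    fjc = np.asarray(fjc_extension(force, params), dtype=float)
    wlc = np.asarray(wlc_extension(force, params), dtype=float)
    denom = s * fjc + (1.0 - s) * wlc
    if np.any(denom == 0):
        raise ValueError("zero junction denominator: ss%*FJC + ds%*WLC == 0")
    frac = s * fjc / denom
    e = np.asarray(eed, dtype=float)
    if orientation == "ss_top":
        out = frac * e
    elif orientation == "ds_top":
        out = (1.0 - frac) * e
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return out if out.ndim else float(out)


def basepairs_from_fraction(ss_fraction, params: ElasticityParams = ElasticityParams()):
    """Base pairs remaining double-stranded: ``round((1 - ss%) * total_bp)``.

    Rounding is half-up so integer examples are reproducible.
    """
    s = np.asarray(ss_fraction, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("ss_fraction must lie in [0, 1]")
    bp = np.floor((1.0 - s) * params.total_bp + 0.5).astype(int)
    return bp if bp.ndim else int(bp)


def reconstruct_junction(
    trace: ForceExtensionTrace,
    params: ElasticityParams = ElasticityParams(),
    orientation: Orientation = "ss_top",
) -> JunctionTrajectory:
    """Reconstruct the junction trajectory from a force-extension trace.

    Samples whose force lies below the WLC validity limit are flagged rather
    than aborting the run; flagged samples carry NaN positions.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    valid = trace.force >= WLC_FORCE_MIN
    n = len(trace)
    ss = np.full(n, np.nan)
    pos = np.full(n, np.nan)
    bp = np.zeros(n, dtype=int)
    clamp_count = 0
    if valid.any():
        frac, clamp_count = ss_fraction_from_eed(
            trace.eed[valid], trace.force[valid], params
        )
        ss[valid] = frac
        pos[valid] = junction_position(
            frac, trace.force[valid], trace.eed[valid], orientation, params
        )
        bp[valid] = basepairs_from_fraction(frac, params)
    return JunctionTrajectory(
        time=trace.time.copy(),
        ss_fraction=ss,
        junction_position=pos,
        basepairs_ds=bp,
        orientation=orientation,
        clamp_count=clamp_count,
        flagged=~valid,
    )
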