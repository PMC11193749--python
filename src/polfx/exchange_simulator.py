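"""Ground-truthed stochastic simulator of polymerase exchange experiments.

Generates (1) a latent kinetic record of junction binding events with
activity classes, labeling and photobleaching, plus extra static ssDNA
binders and diffusing dsDNA binders; (2) the corresponding force-extension
trace through the forward elasticity mixture; (3) a photon-count line-scan
kymograph with Poisson noise, Gaussian PSF and bright bead bands.

Reproducibility: each artifact draws from its own child stream of the master
seed (kinetics=0, trace=1, kymograph=2), so a fixed seed yields bit-identical
output and the three renders are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from polfx.polymer_models import (
    ElasticityParams,
    ForceExtensionTrace,
    fjc_extension,
    junction_position,
    wlc_extension,
)
from polfx.kymo_registration import Kymograph

__all__ = [
    "SimulationConfig",
    "BindingEvent",
    "ExtraBinder",
    "SimulationTruth",
    "simulate_kinetics",
    "render_force_trace",
    "render_kymograph",
    "simulate_dataset",
]

ActivityClass = Literal["exo", "pol", "pause"]


class SimulationConfig(BaseModel):
    """All knobs of the generative model.

    Defaults follow the experimental system where a printed value exists
    (catalytic rates, labeling ratio, bleaching time, pixel size, dwell
    means); the rest are chosen for realism.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    duration: float = Field(60.0, gt=0)  # s
    force_schedule: tuple[tuple[float, float], ...] = ((0.0, 50.0),)
    k_on: float = Field(2.0, gt=0)  # 1/s, junction binding rate
    tau_off: float = Field(1.2, gt=0)  # s, mean bound dwell
    p_labeled: float = Field(0.6, ge=0, le=1)
    tau_bleach: float = Field(13.0, gt=0)  # s
    rate_exo: float = -100.0  # bp/s (negative: bp removal)
    rate_pol: float = 200.0  # bp/s
    p_pause_given_bind: float = Field(0.3, ge=0, le=1)
    memory_strength: float = Field(0.0, ge=0, le=1)
    p_switch_within_bind: float = Field(0.0, ge=0, le=1)
    rate_jitter_sd: float = Field(10.0, ge=0)  # bp/s
    line_time: float = Field(0.1, gt=0)  # s
    pixel_size: float = Field(0.075, gt=0)  # µm
    n_pixels: int = Field(80, ge=8)
    psf_sigma: float = Field(0.15, gt=0)  # µm
    photons_per_line_bound: float = Field(50.0, ge=0)
    background_rate: float = Field(0.2, ge=0)  # counts / pixel / line
    bead_band_pixels: int = Field(3, ge=0)
    bead_band_rate: float = Field(200.0, ge=0)  # counts / pixel / line
    eed_noise_sd: float = Field(0.002, ge=0)  # µm
    p_ssdna_binder: float = Field(0.0, ge=0)  # arrivals / s, static ssDNA binders
    p_dsdna_binder: float = Field(0.0, ge=0)  # arrivals / s, diffusing dsDNA binders
    tau_ss: float = Field(6.5, gt=0)  # s, mean ssDNA-binder dwell
    tau_ds: float = Field(10.0, gt=0)  # s, mean dsDNA-diffuser dwell
    D_dsdna: float = Field(0.02, ge=0)  # µm²/s
    D_ssdna: float = Field(0.003, ge=0)  # µm²/s
    bp_init: int | None = None  # starting dsDNA bp; defaults to total template


@dataclass
class BindingEvent:
    """One junction-binding event with its activity sub-intervals."""

    t_bind: float
    t_unbind: float
    labeled: bool
    t_bleach: float  # absolute; inf if unlabeled
    sub_intervals: list[tuple[float, float, float, str]]  # (t0, t1, rate bp/s, class)

    @property
    def duration(self) -> float:
        return self.t_unbind - self.t_bind

    @property
    def classes(self) -> list[str]:
        return [s[3] for s in self.sub_intervals]

    def visible_until(self) -> float:
        """Time the event stops fluorescing (unbind or bleach)."""
        return min(self.t_unbind, self.t_bleach) if self.labeled else self.t_bind


@dataclass
class ExtraBinder:
    """Off-junction binder: static on ssDNA or diffusing on dsDNA."""

    kind: Literal["ssDNA", "dsDNA-diffusing"]
    t_bind: float
    t_unbind: float
    labeled: bool
    t_bleach: float
    positions: np.ndarray  # µm per kymograph line over its lifetime
    line_start: int  # first kymograph line covered


@dataclass
class SimulationTruth:
    """Complete latent record used to validate the analysis pipeline."""

    config: SimulationConfig
    time: np.ndarray  # line-time grid (line centers), s
    force: np.ndarray  # pN per line
    basepairs: np.ndarray  # dsDNA bp per line
    ss_fraction: np.ndarray
    junction_position_um: np.ndarray
    events: list[BindingEvent]
    extra_binders: list[ExtraBinder] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return self.time.size

    def occupancy(self, fluorescent_only: bool = True) -> np.ndarray:
        """Boolean per-line: a junction polymerase is (visibly) bound."""
        occ = np.zeros(self.n_lines, dtype=bool)
        for ev in self.events:
            t1 = ev.visible_until() if fluorescent_only else ev.t_unbind
            occ |= (self.time >= ev.t_bind) & (self.time < t1)
        return occ

    def activity_class(self) -> np.ndarray:
        """Per-line activity class ('exo'/'pol'/'pause'), '' when unbound."""
        cls = np.full(self.n_lines, "", dtype=object)
        for ev in self.events:
            for t0, t1, _rate, label in ev.sub_intervals:
                cls[(self.time >= t0) & (self.time < t1)] = label
        return cls

    def pause_intervals(
        self, min_duration: float = 0.0, rate_floor: float = 1.0
    ) -> list[tuple[float, float]]:
        """Merged intervals where the effective junction rate is ~zero.

        Uses the integrated base-pair trajectory (which respects clipping at
        the template ends), so an active binder stalled at a template
        boundary counts as paused — matching what any observer of the trace
        could see.
        """
        dt_bp = float(self.time[1] - self.time[0]) if self.n_lines > 1 else 1.0
        eff_rate = np.gradient(self.basepairs, dt_bp)
        active = np.abs(eff_rate) > rate_floor
        out = []
        dt = float(self.time[1] - self.time[0]) if self.n_lines > 1 else 0.0
        i = 0
        while i < self.n_lines:
            if not active[i]:
                j = i
                while j < self.n_lines and not active[j]:
                    j += 1
                t0, t1 = float(self.time[i]), float(self.time[j - 1]) + dt
                if t1 - t0 >= min_duration:
                    out.append((t0, t1))
                i = j
            else:
                i += 1
        return out


def _force_at(t, schedule: Sequence[tuple[float, float]]) -> np.ndarray:
    """Piecewise-constant force schedule lookup."""
    starts = np.array([s for s, _ in schedule])
    forces = np.array([f for _, f in schedule])
    order = np.argsort(starts)
    starts, forces = starts[order], forces[order]
    idx = np.clip(np.searchsorted(starts, np.asarray(t, dtype=float), side="right") - 1, 0, None)
    return forces[idx]


def _draw_class(rng: np.random.Generator, force: float, cfg: SimulationConfig) -> str:
    if rng.random() < cfg.p_pause_given_bind:
        return "pause"
    if force >= 40.0:
        return "exo"
    if force <= 20.0:
        return "pol"
    return "pause"  # middle band: no defined enzymatic regime


def _class_rate(rng: np.random.Generator, cls: str, cfg: SimulationConfig) -> float:
    if cls == "pause":
        return 0.0
    base = cfg.rate_exo if cls == "exo" else cfg.rate_pol
    return base + rng.normal(0.0, cfg.rate_jitter_sd)


def simulate_kinetics(
    config: SimulationConfig, params: ElasticityParams = ElasticityParams()
) -> SimulationTruth:
    """Draw the latent kinetic record and integrate the base-pair trajectory.

    Junction occupancy alternates exponential unbound (mean ``1/k_on``) and
    bound (mean ``tau_off``) intervals; single occupancy is enforced by
    construction.  At each binding the activity class copies the previous
    binder's class with probability ``memory_strength`` and is otherwise
    drawn afresh given the force regime.  The base-pair count integrates the
    active rate and is clipped to ``[0, total_bp]``.
    """
    rng = np.random.default_rng([config.seed, 0])
    events: list[BindingEvent] = []
    t = 0.0
    prev_class: str | None = None
    while True:
        t_bind = t + rng.exponential(1.0 / config.k_on)
        if t_bind >= config.duration:
            break
        dwell = rng.exponential(config.tau_off)
        t_unbind = min(t_bind + dwell, config.duration)
        force_here = float(_force_at(t_bind, config.force_schedule))
        if prev_class is not None and rng.random() < config.memory_strength:
            cls = prev_class
        else:
            cls = _draw_class(rng, force_here, config)
        subs: list[tuple[float, float, float, str]] = []
        if rng.random() < config.p_switch_within_bind and t_unbind - t_bind > 0.2:
            t_switch = t_bind + rng.uniform(0.25, 0.75) * (t_unbind - t_bind)
            others = [c for c in ("exo", "pol", "pause") if c != cls]
            cls2 = others[rng.integers(len(others))]
            subs.append((t_bind, t_switch, _class_rate(rng, cls, config), cls))
            subs.append((t_switch, t_unbind, _class_rate(rng, cls2, config), cls2))
            prev_class = cls2
        else:
            subs.append((t_bind, t_unbind, _class_rate(rng, cls, config), cls))
            prev_class = cls
        labeled = bool(rng.random() < config.p_labeled)
        t_bleach = t_bind + rng.exponential(config.tau_bleach) if labeled else math.inf
        events.append(
            BindingEvent(
                t_bind=t_bind,
                t_unbind=t_unbind,
                labeled=labeled,
                t_bleach=t_bleach,
                sub_intervals=subs,
            )
        )
        t = t_unbind

    # integrate bp on the line-time grid, clipping at template limits
    n_lines = int(round(config.duration / config.line_time))
    time = (np.arange(n_lines) + 0.5) * config.line_time
    force = _force_at(time, config.force_schedule).astype(float)
    rate_fn = np.zeros(n_lines)
    for ev in events:
        for t0, t1, rate, _cls in ev.sub_intervals:
            rate_fn[(time >= t0) & (time < t1)] = rate
    bp_init = config.bp_init if config.bp_init is not None else params.total_bp
    raw = bp_init + np.cumsum(rate_fn) * config.line_time
    if raw.min() >= 0.0 and raw.max() <= params.total_bp:
        bp = raw  # fast path: template limits never reached
    else:
        bp = np.empty(n_lines)
        level = float(bp_init)
        for i in range(n_lines):
            level = min(
                max(level + rate_fn[i] * config.line_time, 0.0), float(params.total_bp)
            )
            bp[i] = level
    ss = 1.0 - bp / params.total_bp

    fjc = fjc_extension(force, params)
    wlc = wlc_extension(force, params)
    eed_clean = ss * fjc + (1.0 - ss) * wlc
    jpos = junction_position(ss, force, eed_clean, "ss_top", params)

    truth = SimulationTruth(
        config=config,
        time=time,
        force=force,
        basepairs=bp,
        ss_fraction=ss,
        junction_position_um=jpos,
        events=events,
    )
    truth.extra_binders = _simulate_extra_binders(rng, truth, config, params)
    return truth


def _simulate_extra_binders(
    rng: np.random.Generator,
    truth: SimulationTruth,
    cfg: SimulationConfig,
    params: ElasticityParams,
) -> list[ExtraBinder]:
    binders: list[ExtraBinder] = []
    dt = cfg.line_time
    eed_clean = truth.ss_fraction * fjc_extension(truth.force, params) + (
        1 - truth.ss_fraction
    ) * wlc_extension(truth.force, params)

    for kind, rate, tau in (
        ("ssDNA", cfg.p_ssdna_binder, cfg.tau_ss),
        ("dsDNA-diffusing", cfg.p_dsdna_binder, cfg.tau_ds),
    ):
        n = rng.poisson(rate * cfg.duration)
        for _ in range(n):
            t0 = rng.uniform(0.0, cfg.duration)
            t1 = min(t0 + rng.exponential(tau), cfg.duration)
            i0 = int(np.searchsorted(truth.time, t0))
            i1 = int(np.searchsorted(truth.time, t1))
            if i1 <= i0:
                continue
            labeled = bool(rng.random() < cfg.p_labeled)
            t_bleach = t0 + rng.exponential(cfg.tau_bleach) if labeled else math.inf
            if kind == "ssDNA":
                # static at a uniform point on the ssDNA side (above junction)
                u = rng.random()
                pos0 = u * truth.junction_position_um[i0]
                positions = np.full(i1 - i0, pos0)
            else:
                # reflected Brownian motion on the dsDNA side
                lo = truth.junction_position_um[i0]
                hi = eed_clean[i0]
                x = rng.uniform(lo, hi)
                positions = np.empty(i1 - i0)
                for k in range(i1 - i0):
                    lo = truth.junction_position_um[i0 + k]
                    hi = eed_clean[i0 + k]
                    x += rng.normal(0.0, math.sqrt(2.0 * cfg.D_dsdna * dt))
                    # reflect into [lo, hi]
                    span = hi - lo
                    if span > 0:
                        y = (x - lo) % (2 * span)
                        x = lo + (y if y <= span else 2 * span - y)
                    positions[k] = x
            binders.append(
                ExtraBinder(
                    kind=kind,
                    t_bind=t0,
                    t_unbind=t1,
                    labeled=labeled,
                    t_bleach=t_bleach,
                    positions=positions,
                    line_start=i0,
                )
            )
    return binders


def render_force_trace(
    truth: SimulationTruth,
    config: SimulationConfig | None = None,
    params: ElasticityParams = ElasticityParams(),
) -> ForceExtensionTrace:
    """Render the measured trace: ``EED = ss%·FJC(F) + ds%·WLC(F) + noise``."""
    cfg = config or truth.config
    rng = np.random.default_rng([cfg.seed, 1])
    fjc = fjc_extension(truth.force, params)
    wlc = wlc_extension(truth.force, params)
    eed = truth.ss_fraction * fjc + (1.0 - truth.ss_fraction) * wlc
    if cfg.eed_noise_sd > 0:
        eed = eed + rng.normal(0.0, cfg.eed_noise_sd, size=eed.size)
    return ForceExtensionTrace(time=truth.time.copy(), force=truth.force.copy(), eed=eed)


def _emitter_profile(centers_um: np.ndarray, x_um: float, sigma: float) -> np.ndarray:
    w = np.exp(-0.5 * ((centers_um - x_um) / sigma) ** 2)
    s = w.sum()
    return w / s if s > 0 else w


def render_kymograph(
    truth: SimulationTruth, config: SimulationConfig | None = None
) -> Kymograph:
    """Render the photon-count kymograph from the latent record.

    Per line: Poisson background everywhere; each labeled, unbleached bound
    emitter adds Poisson photons with a Gaussian spatial profile; bright
    bead bands occupy ``bead_band_pixels`` at both frame edges.
    """
    cfg = config or truth.config
    rng = np.random.default_rng([cfg.seed, 2])
    n_lines, n_px = truth.n_lines, cfg.n_pixels
    centers = (np.arange(n_px) + 0.5) * cfg.pixel_size
    lam = np.full((n_lines, n_px), cfg.background_rate, dtype=float)

    for ev in truth.events:
        if not ev.labeled:
            continue
        t1 = ev.visible_until()
        lines = np.flatnonzero((truth.time >= ev.t_bind) & (truth.time < t1))
        for i in lines:
            lam[i] += cfg.photons_per_line_bound * _emitter_profile(
                centers, truth.junction_position_um[i], cfg.psf_sigma
            )
    for b in truth.extra_binders:
        if not b.labeled:
            continue
        for k, x in enumerate(b.positions):
            i = b.line_start + k
            if i >= n_lines or truth.time[i] >= b.t_bleach:
                break
            lam[i] += cfg.photons_per_line_bound * _emitter_profile(
                centers, x, cfg.psf_sigma
            )
    if cfg.bead_band_pixels > 0:
        nb = cfg.bead_band_pixels
        lam[:, :nb] = cfg.bead_band_rate
        lam[:, -nb:] = cfg.bead_band_rate
    photons = rng.poisson(lam)
    return Kymograph(
        photons=photons.astype(np.int64),
        line_time=cfg.line_time,
        pixel_size=cfg.pixel_size,
        origin_position=0.0,
        bead_band_pixels=cfg.bead_band_pixels,
    )


def simulate_dataset(
    config: SimulationConfig, params: ElasticityParams = ElasticityParams()
) -> tuple[SimulationTruth, ForceExtensionTrace, Kymograph]:
    """Convenience wrapper producing all three artifacts from one seed."""
    truth = simulate_kinetics(config, params)
    trace = render_force_trace(truth, config, params)
    kymo = render_kymograph(truth, config)
    return truth, trace, kymo
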