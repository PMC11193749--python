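"""End-to-end orchestration: simulate, analyze and report commands.

The analyze pipeline runs reconstruct → register → binarize → segment →
correlate → kinetics on the interchange files in a data directory and
writes a JSON run report plus CSV tables, with per-stage event counts in a
log so headline numbers stay auditable.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

import polfx
from polfx import interchange
from polfx.burst_analysis import (
    PauseThresholds,
    detect_pauses,
    extract_segments,
    flanking_states,
    independence_null,
    memory_configuration_counts,
    rate_trace,
)
from polfx.correlation_analysis import (
    build_correlation_series,
    cluster_events,
    fluorescent_event_fraction,
    nonfluorescent_pause_fraction,
)
from polfx.exchange_simulator import SimulationConfig, simulate_dataset
from polfx.kinetics import fit_diffusion, fit_lifetime, msd, track_particles
from polfx.kymo_registration import (
    extract_junction_intensity,
    junction_to_pixels,
    refine_offsets,
)
from polfx.polymer_models import ElasticityParams, reconstruct_junction
from polfx.step_detection import BinaryTrace, binarize, fit_steps, min_run_filter

__all__ = ["AnalysisConfig", "run_simulate", "run_analyze", "run_report"]


class AnalysisConfig(BaseModel):
    """Validated analysis settings; unknown keys are rejected.

    Every default is embedded into the run report so no setting is hidden.
    """

    model_config = ConfigDict(extra="forbid")

    # elasticity (defaults match ElasticityParams)
    ss_contour_per_nt: float = Field(0.56, gt=0)
    ss_kuhn_length: float = Field(1.5, gt=0)
    ss_stretch_modulus: float = Field(800.0, gt=0)
    ds_contour_per_bp: float = Field(0.338, gt=0)
    ds_persistence_length: float = Field(50.0, gt=0)
    ds_stretch_modulus: float = Field(1500.0, gt=0)
    kBT: float = Field(4.11, gt=0)
    total_bp: int = Field(8393, ge=1)

    orientation: str = "ss_top"
    k_sigma: float = Field(4.0, ge=3.0, le=5.0)
    box_width: int = Field(5, ge=1)
    search_range: int = Field(5, ge=0)
    coarse_x_offset: int = 0
    coarse_y_offset: int = 0
    background_region: tuple[int, int] | None = None  # line-index range for background
    high_force_cutoff: float = Field(10.0, gt=0)
    low_force_cutoff: float = Field(20.0, gt=0)
    min_run: int = Field(3, ge=1)
    flank_window: float = Field(0.5, gt=0)
    tau_bleach: float = Field(13.0, gt=0)
    sg_window: int = Field(15, ge=5)
    step_sensitivity: float = Field(3.0, gt=0)
    tracker_k_sigma: float = Field(4.0, ge=3.0, le=5.0)
    tracker_max_jump: float = Field(2.0, gt=0)
    tracker_max_gap: int = Field(2, ge=0)
    junction_tolerance_px: int = Field(3, ge=0)
    seed: int = 0

    def elasticity(self) -> ElasticityParams:
        return ElasticityParams(
            ss_contour_per_nt=self.ss_contour_per_nt,
            ss_kuhn_length=self.ss_kuhn_length,
            ss_stretch_modulus=self.ss_stretch_modulus,
            ds_contour_per_bp=self.ds_contour_per_bp,
            ds_persistence_length=self.ds_persistence_length,
            ds_stretch_modulus=self.ds_stretch_modulus,
            kBT=self.kBT,
            total_bp=self.total_bp,
        )

    def thresholds(self) -> PauseThresholds:
        return PauseThresholds(
            high_force_cutoff=self.high_force_cutoff,
            low_force_cutoff=self.low_force_cutoff,
        )


def _config_hash(model: BaseModel) -> str:
    blob = json.dumps(model.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_simulate(config_path, out_dir) -> dict:
    """Generate a simulated dataset (truth JSON, force CSV/HDF5, kymo HDF5/TIFF)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = json.loads(Path(config_path).read_text()) if config_path else {}
    cfg = SimulationConfig(**doc)
    params = ElasticityParams()
    truth, trace, kymo = simulate_dataset(cfg, params)
    interchange.write_truth_json(truth, out / "truth.json")
    interchange.write_force_csv(trace, out / "force_trace.csv")
    interchange.write_force_hdf5(trace, out / "force_trace.h5")
    interchange.write_kymograph_hdf5(kymo, out / "kymograph.h5")
    interchange.write_kymograph_tiff(kymo, out / "kymograph.tif")
    return {
        "n_events": len(truth.events),
        "n_lines": truth.n_lines,
        "config_hash": _config_hash(cfg),
    }


def _nearest_resample(src_time, src_values, dst_time) -> np.ndarray:
    idx = np.clip(np.searchsorted(src_time, dst_time), 0, src_time.size - 1)
    left = np.clip(idx - 1, 0, src_time.size - 1)
    take_left = np.abs(src_time[left] - dst_time) <= np.abs(src_time[idx] - dst_time)
    return np.asarray(src_values)[np.where(take_left, left, idx)]


def run_analyze(data_dir, config_path=None, out_dir=None) -> dict:
    """Run all analysis stages over one molecule's interchange files."""
    data = Path(data_dir)
    csv_path = data / "force_trace.csv"
    h5_path = data / "force_trace.h5"
    kymo_path = data / "kymograph.h5"
    if not kymo_path.exists() or not (csv_path.exists() or h5_path.exists()):
        raise FileNotFoundError(
            f"expected force_trace.csv/h5 and kymograph.h5 under {data}"
        )
    cfg = AnalysisConfig(
        **(json.loads(Path(config_path).read_text()) if config_path else {})
    )
    params = cfg.elasticity()
    thresholds = cfg.thresholds()
    trace = (
        interchange.read_force_csv(csv_path)
        if csv_path.exists()
        else interchange.read_force_hdf5(h5_path)
    )
    kymo = interchange.read_kymograph_hdf5(kymo_path)
    log: dict = {}

    # 1. reconstruct the junction trajectory
    traj = reconstruct_junction(trace, params, cfg.orientation)
    log["clamp_count"] = traj.clamp_count
    log["flagged_samples"] = int(traj.flagged.sum())

    # 2. register kymograph against the trajectory
    has_signal = bool(np.any(kymo.photons[:, kymo.signal_mask()]))
    if has_signal:
        offsets = refine_offsets(
            kymo,
            traj,
            search_range=cfg.search_range,
            box_width=cfg.box_width,
            coarse=(cfg.coarse_x_offset, cfg.coarse_y_offset),
        )
    else:
        from polfx.kymo_registration import RegistrationOffsets

        offsets = RegistrationOffsets(cfg.coarse_x_offset, cfg.coarse_y_offset, 0.0)
    intensity = extract_junction_intensity(kymo, traj, offsets, cfg.box_width)
    counts = np.nan_to_num(intensity.counts, nan=0.0)
    log["missing_intensity_lines"] = int(np.isnan(intensity.counts).sum())

    # 3. binarize fluorescence
    if cfg.background_region is not None:
        lo, hi = cfg.background_region
        fluor = binarize(
            counts,
            time=intensity.time,
            k_sigma=cfg.k_sigma,
            sigma_source="background_region",
            background_region=slice(lo, hi),
        )
    else:
        fluor = binarize(counts, time=intensity.time, k_sigma=cfg.k_sigma)
    fluor = min_run_filter(fluor, cfg.min_run)
    log["fluorescent_lines"] = int(fluor.state.sum())

    # 4. base-pair trace on the line-time base
    line_time = kymo.line_times
    bp = _nearest_resample(traj.time, traj.basepairs_ds.astype(float), line_time)
    force = _nearest_resample(trace.time, trace.force, line_time)
    dt = kymo.line_time
    rates = rate_trace(bp, dt, sg_window=cfg.sg_window)
    rate_fit = fit_steps(rates, sensitivity=cfg.step_sensitivity)
    fitted_rates = rate_fit.fitted()

    # 5. burst segments, flanks, memory configurations
    segments = extract_segments(
        fluor, bp, line_time, force, thresholds, cfg.sg_window, cfg.step_sensitivity
    )
    for seg in segments:
        seg.pre_state, seg.post_state = flanking_states(
            seg,
            bp,
            line_time,
            force,
            thresholds,
            cfg.flank_window,
            cfg.sg_window,
            cfg.step_sensitivity,
            fitted_rates=fitted_rates,
        )
    n_single = sum(1 for s in segments if s.segment_type == "single")
    memory = memory_configuration_counts(segments)
    log["segments_total"] = len(segments)
    log["segments_single"] = n_single
    log["memory_counted"] = memory.n_total

    # 6. pauses
    pauses = detect_pauses(
        bp, line_time, force, thresholds, sg_window=cfg.sg_window,
        sensitivity=cfg.step_sensitivity,
    )
    log["pauses"] = len(pauses)

    # 7. correlation classes and clusters
    cutoffs = np.array([thresholds.cutoff_for(f) or np.inf for f in force])
    activity = BinaryTrace(
        time=line_time,
        state=(np.abs(fitted_rates) > cutoffs).astype(int),
        threshold_used=float(np.nanmin(cutoffs)) if len(cutoffs) else 0.0,
        k_sigma=cfg.k_sigma,
    )
    series = build_correlation_series(fluor, activity)
    clusters = cluster_events(series, min_len=cfg.min_run)
    fluor_frac = (
        fluorescent_event_fraction(clusters) if clusters.total > 0 else None
    )
    nf_pause_frac = nonfluorescent_pause_fraction(clusters)
    log["clusters_total"] = clusters.total

    # 8. lifetimes from segment durations
    durations = [s.duration for s in segments]
    lifetime = None
    if len(durations) >= 10:
        try:
            lifetime = fit_lifetime(durations, cfg.tau_bleach)
        except ValueError as exc:
            log["lifetime_error"] = str(exc)
    log["lifetime_events"] = len(durations)

    # 9. particle tracking and diffusion per DNA side
    tracks = track_particles(
        kymo,
        k_sigma=cfg.tracker_k_sigma,
        max_jump=cfg.tracker_max_jump,
        max_gap=cfg.tracker_max_gap,
    )
    jpx, _valid = junction_to_pixels(traj, kymo)
    diffusion: dict[str, list[float]] = {"ssDNA": [], "dsDNA": [], "junction": []}
    from polfx.kymo_registration import classify_binding_position

    for tr in tracks:
        if len(tr) < 8:
            continue
        px = (tr.positions - kymo.origin_position) / kymo.pixel_size
        side = classify_binding_position(
            px, jpx[tr.lines], cfg.junction_tolerance_px, cfg.orientation
        )
        lags, curve = msd(tr)
        est = fit_diffusion(lags, curve)
        diffusion[side].append(est.D)
    log["tracks"] = len(tracks)

    report = {
        "software_version": polfx.__version__,
        "config": cfg.model_dump(),
        "config_hash": _config_hash(cfg),
        "registration": {
            "x_offset": offsets.x_offset,
            "y_offset": offsets.y_offset,
            "objective_value": offsets.objective_value,
        },
        "segments": [
            {
                "t_start": s.t_start,
                "t_end": s.t_end,
                "duration": s.duration,
                "segment_type": s.segment_type,
                "mean_rate": s.mean_rate,
                "labels": s.labels,
                "pre_state": s.pre_state,
                "post_state": s.post_state,
            }
            for s in segments
        ],
        "pauses": [{"t_start": a, "t_end": b, "duration": b - a} for a, b in pauses],
        "single_type_fraction": (n_single / len(segments)) if segments else None,
        "memory_configurations": {
            "counts": {"".join(t): c for t, c in memory.counts.items()},
            "fractions": {"".join(t): f for t, f in memory.fractions().items()},
            "errors": {"".join(t): e for t, e in memory.errors().items()},
            "n_total": memory.n_total,
        },
        "clusters": asdict(clusters),
        "fluorescent_event_fraction": fluor_frac,
        "nonfluorescent_pause_fraction": nf_pause_frac,
        "lifetime": asdict(lifetime) if lifetime else None,
        "diffusion_um2_per_s": {
            side: {
                "n": len(vals),
                "mean": float(np.mean(vals)) if vals else None,
                "median": float(np.median(vals)) if vals else None,
            }
            for side, vals in diffusion.items()
        },
        "log": log,
    }
    if report["lifetime"] and math.isinf(report["lifetime"]["tau_bleach_used"]):
        report["lifetime"]["tau_bleach_used"] = "inf"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame(report["segments"]).to_csv(out / "segments.csv", index=False)
        pd.DataFrame(report["pauses"]).to_csv(out / "pauses.csv", index=False)
    return report


def run_report(report_path, out_dir) -> list[str]:
    """Render human-readable summary text and PNG figure panels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    doc = json.loads(Path(report_path).read_text())
    if "memory_configurations" not in doc or "clusters" not in doc:
        raise ValueError("malformed report: missing required sections")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    lines = [
        f"polfx {doc.get('software_version')} run report",
        f"config hash: {doc.get('config_hash')}",
        f"segments: {len(doc.get('segments', []))} "
        f"(single-type fraction: {doc.get('single_type_fraction')})",
        f"pauses: {len(doc.get('pauses', []))}",
        f"fluorescent event fraction: {doc.get('fluorescent_event_fraction')}",
        f"non-fluorescent pause fraction: {doc.get('nonfluorescent_pause_fraction')}",
        f"lifetime: {doc.get('lifetime')}",
        f"diffusion: {doc.get('diffusion_um2_per_s')}",
    ]
    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(str(summary))

    # configuration bar chart
    fig, ax = plt.subplots(figsize=(6, 4))
    mem = doc["memory_configurations"]
    keys = sorted(mem["fractions"])
    vals = [mem["fractions"][k] for k in keys]
    errs = [mem["errors"][k] for k in keys]
    ax.bar(range(len(keys)), vals, yerr=errs, color="tab:blue")
    ax.set_xticks(range(len(keys)))
    ax.set_xticklabels(["→".join(k) for k in keys], rotation=45)
    ax.set_ylabel("fraction")
    ax.set_title("state-switching configurations")
    fig.tight_layout()
    p = out / "memory_configurations.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))

    # cluster-class bar chart
    fig, ax = plt.subplots(figsize=(4, 4))
    cl = doc["clusters"]
    names = ["n11", "n10", "n01", "n00"]
    colors = ["red", "blue", "pink", "cyan"]
    ax.bar(names, [cl[n] for n in names], color=colors)
    ax.set_ylabel("clusters")
    ax.set_title("correlation classes")
    fig.tight_layout()
    p = out / "correlation_classes.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))

    # segment-duration survival curve
    fig, ax = plt.subplots(figsize=(5, 4))
    durations = sorted(s["duration"] for s in doc.get("segments", []))
    if durations:
        n = len(durations)
        surv = 1.0 - np.arange(n) / n
        ax.step(durations, surv, where="post")
        ax.set_yscale("log")
    else:
        ax.text(0.5, 0.5, "no segments", ha="center", va="center")
    ax.set_xlabel("duration (s)")
    ax.set_ylabel("survival")
    fig.tight_layout()
    p = out / "lifetime_survival.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))
    return written
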