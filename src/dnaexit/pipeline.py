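"""End-to-end orchestration: traces -> lengths -> velocities -> pauses ->
profiles -> distribution fits, deterministic under a fixed seed."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, kinetics, pauses, pausestats
from .elasticity import ElasticParams
from .friction import DEFAULT_FORCE_KNOTS
from .simulate import Trace

log = logging.getLogger("dnaexit")


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-side knobs, all defaulted to the study conditions."""

    window: float = 0.5                 # s, velocity window
    step: float = 0.1                   # s, window step (80% overlap)
    bin_width: float = 5.0              # % filling
    bootstrap_reps: int = 1000
    detection_rate: float = 100.0       # Hz for change-point search
    min_segment: int = 3                # detection samples (0.03 s)
    n_sd: float = 2.5                   # pause threshold in control SDs
    min_pause_s: float = 0.04           # hard floor; the local rule tightens it
    resolution_margin: float = 1.5      # extra SDs for the local duration limit
    dt_grid: tuple = pauses.DEFAULT_DT_GRID
    genome_bp: float = 19300.0
    fit_range: tuple = (80.0, 100.0)
    pause_stats_filling: tuple = (90.0, 95.0)
    seed: int = 0
    elastic: ElasticParams = field(default_factory=ElasticParams)
    force_knots: tuple = DEFAULT_FORCE_KNOTS

    def __post_init__(self) -> None:
        if self.window < 3 / self.detection_rate:
            raise ValueError("window must cover at least 3 detection samples")
        if abs(100.0 / self.bin_width - round(100.0 / self.bin_width)) > 1e-9:
            raise ValueError("bin_width must divide 100")
        if self.bootstrap_reps < 100:
            raise ValueError("bootstrap_reps must be at least 100")


def analyze_event(trace: Trace, noise: pauses.NoiseModel, config: AnalysisConfig):
    """Per-event analysis.

    Returns (samples_incl, samples_excl, pause list, t, filling, exited):
    samples_incl are sliding-window velocities on the raw series (pauses
    included); samples_excl are windows on the pause-excised series, i.e.
    transient velocities of movement only.
    """
    t, x = kinetics.exited_length_series(trace, config.elastic)
    _, fill = kinetics.filling_series(t, x, config.genome_bp)
    plist = pauses.detect_pauses(
        trace, noise, config.elastic, genome_bp=config.genome_bp,
        detection_rate=config.detection_rate, min_segment=config.min_segment,
        n_sd=config.n_sd, min_pause_s=config.min_pause_s,
        resolution_margin=config.resolution_margin,
    )
    samples_incl = kinetics.window_velocities(t, x, config.window, config.step)
    samples_incl = kinetics.attach_filling(samples_incl, t, fill)
    samples_incl["paused"] = False

    samples_excl = None
    try:
        ts, xs, idx = kinetics.excise_pauses(t, x, plist)
        if ts[-1] - ts[0] >= config.window:
            samples_excl = kinetics.window_velocities(ts, xs, config.window,
                                                      config.step)
            samples_excl = kinetics.attach_filling(samples_excl, ts, fill[idx])
            samples_excl["paused"] = False
    except ValueError:
        pass
    return samples_incl, samples_excl, plist, t, fill, x


def run_pipeline(traces: list[Trace], config: AnalysisConfig,
                 applied_force: float | None = None) -> dict:
    """Analyse one ensemble of ejection + control traces.

    Returns a results bundle (plain dict of scalars, dicts and DataFrames)
    suitable for io.write_results. Raises before any analysis when the
    ensemble has no control trace or no ejection trace.
    """
    ejections = [tr for tr in traces if tr.kind == "ejection"]
    controls = [tr for tr in traces if tr.kind == "control"]
    if not controls:
        raise ValueError("ensemble has no control traces; noise calibration impossible")
    if not ejections:
        raise ValueError("ensemble has no ejection traces")
    log.info("calibrating noise on %d control traces", len(controls))
    noise = pauses.calibrate_noise(controls, config.elastic, config.dt_grid)

    profiles_excl, profiles_incl = [], []
    pauses_by_event: dict[str, list] = {}
    filling_by_event: dict[str, tuple] = {}
    total_time: dict[str, float] = {}
    catalog_rows = []
    for tr in ejections:
        samples_incl, samples_excl, plist, t, fill, x = analyze_event(
            tr, noise, config)
        pauses_by_event[tr.event_id] = plist
        filling_by_event[tr.event_id] = (t, fill)
        total_time[tr.event_id] = float(t[-1] - t[0])
        try:
            profiles_incl.append(kinetics.event_profile(
                samples_incl, exclude_paused=False, bin_width=config.bin_width))
            if samples_excl is not None:
                profiles_excl.append(kinetics.event_profile(
                    samples_excl, exclude_paused=False,
                    bin_width=config.bin_width))
        except ValueError:
            log.warning("event %s produced no velocity samples", tr.event_id)
        for p in plist:
            catalog_rows.append({
                "event_id": tr.event_id, "start_s": p.start, "end_s": p.end,
                "duration_s": p.duration, "filling_pct": p.filling_at_onset,
                "exited_bp": p.exited_length_at_onset,
            })
        log.info("event %s: %d pauses, %.1f s", tr.event_id, len(plist),
                 total_time[tr.event_id])

    profile_excl = kinetics.ensemble_profile(
        profiles_excl, config.bootstrap_reps, config.seed,
        config.bin_width, pauses_included=False)
    profile_incl = kinetics.ensemble_profile(
        profiles_incl, config.bootstrap_reps, config.seed,
        config.bin_width, pauses_included=True)
    metrics = pauses.pause_metrics_by_bin(
        pauses_by_event, filling_by_event, config.genome_bp,
        config.bin_width, config.bootstrap_reps, config.seed)
    frac_paused = pauses.fraction_time_paused(pauses_by_event, total_time)

    lo, hi = config.pause_stats_filling
    pooled = [p for ps in pauses_by_event.values() for p in ps
              if lo <= p.filling_at_onset <= hi]
    durations = np.array([p.duration for p in pooled])
    spacings = np.concatenate([
        pausestats.interpause_lengths([p for p in ps if lo <= p.filling_at_onset <= hi])
        for ps in pauses_by_event.values()
    ]) if pooled else np.array([])
    dist_fits: dict = {"filling_range_pct": [lo, hi],
                       "n_pauses": int(durations.size)}
    if spacings.size >= 2:
        efit = pausestats.fit_exponential(spacings[spacings > 0])
        dist_fits["interpause_exponential"] = {
            "rate_per_bp": efit.rate, "n": efit.n, "ks_distance": efit.ks_distance}
    if durations.size >= 50:
        pfit = pausestats.csn_powerlaw_fit(durations)
        dist_fits["duration_powerlaw"] = {
            "alpha": pfit.alpha, "xmin_s": pfit.xmin, "n_tail": pfit.n_tail,
            "ks_distance": pfit.ks_distance, "alpha_se": pfit.alpha_se,
            "ks_exponential_tail": pfit.ks_exponential_tail,
            "powerlaw_preferred": pfit.powerlaw_preferred}

    fit_excl = None
    try:
        v100, decade = kinetics.fit_exponential_profile(profile_excl, config.fit_range)
        fit_excl = {"v_at_100_bp_s": v100, "decade_filling_pct": decade,
                    "v_at_80_bp_s": v100 * 10 ** (20.0 / decade)}
    except ValueError as err:
        log.warning("exponential profile fit skipped: %s", err)

    bundle = {
        "applied_force_pN": applied_force,
        "n_events": len(ejections),
        "n_controls": len(controls),
        "fraction_time_paused": frac_paused,
        "exit_time_s_by_event": total_time,
        "velocity_profile_excl_pauses": profile_excl.as_frame(),
        "velocity_profile_incl_pauses": profile_incl.as_frame(),
        "per_event_profile_excl": profile_excl.per_event.reset_index(
            names="filling_pct"),
        "pause_catalog": pd.DataFrame(catalog_rows),
        "pause_metrics": metrics,
        "distribution_fits": dist_fits,
        "exponential_profile_fit": fit_excl,
        "noise_model": {
            "dt_s": noise.dt_grid.tolist(), "mean_bp_s": noise.mean.tolist(),
            "sd_bp_s": noise.sd.tolist(),
            "length_resolution_bp": noise.length_resolution_bp,
        },
        "frequency_unit": "pauses per kb exited",
        "config_hash": io.config_hash(config),
        "config": config,
    }
    return bundle


def run_pipeline_from_dir(traces_dir, config: AnalysisConfig,
                          out_dir=None) -> dict:
    """Load an ensemble written by io.write_ensemble and analyse it."""
    traces_dir = Path(traces_dir)
    manifest = io.read_manifest(traces_dir / "manifest.json")
    traces = [
        io.read_trace(traces_dir / rec["file"], rec["event_id"], rec["kind"])
        for rec in manifest["events"]
    ]
    bundle = run_pipeline(traces, config,
                          applied_force=manifest.get("applied_force_pN"))
    if out_dir is not None:
        io.write_results(bundle, out_dir)
    return bundle
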