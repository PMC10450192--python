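"""Forward model for force-clamp DNA-exit traces from phi29 capsids.

Generates ensembles of synthetic optical-tweezers trajectories with the
statistical structure of measured DNA ejection events: an exponentially
rising exit velocity as the capsid empties, stochastic clogging pauses
(Poisson onsets in exited length, heavy-tailed Pareto durations), broad
per-event heterogeneity, a tracking-velocity cap, and instrument noise on
the extension signal. Static control tethers for noise calibration are
generated by the same machinery.

Model summary (filling phi in %, exited length x in bp, phi = 100 - x/193):

  velocity law   v(phi) = v100 * 10^((100-phi)/decade_filling) * factors
                 where factors carry the ionic condition (Mg2+ halves the
                 velocity) and the applied-force dependence through the
                 Prandtl-Tomlinson ratio exp((F_app - 5 pN) d/kT).
  pause onsets   Poisson process in x with hazard
                 lambda(phi) = pause_rate_100 * exp(-(100-phi)/pause_rate_scale),
                 switched off below 50% filling.
  durations      Pareto(alpha, xmin(phi)),
                 xmin(phi) = pareto_xmin_100 * exp(-(100-phi)/xmin_scale).
  heterogeneity  one lognormal velocity multiplier eta per event (mean one,
                 log-SD heterogeneity_sigma); pause onsets and durations
                 are unaffected, so ensemble-mean velocities stay unbiased.
  termination    when the instantaneous velocity reaches velocity_cap.

Between pauses the motion is deterministic, so segment times are closed
form: with c = decade_filling * bp_per_percent / ln 10,
t(x0 -> x1) = (c / (eta v_anchor)) (e^{-x0/c} - e^{-x1/c}).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .elasticity import ElasticParams, fractional_extension

REFERENCE_FORCE_PN = 5.0  # applied force at which the velocity law is anchored


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated ensemble.

    Anchors follow the measured phi29 ejection phenomenology: ~200 bp/s at
    100% filling rising to ~2000 bp/s at 80% (one velocity decade per 20%
    filling), a ~12 kb/s tracking cap, 1 kHz sampling, a 19.3 kb genome,
    and a clogging-pause hazard calibrated so pauses occupy ~57% of the
    total exit time (see docs/methods.md for the derivation).
    """

    genome_bp: float = 19300.0
    sample_rate: float = 1000.0          # Hz
    applied_force: float = 5.0           # pN force-clamp setpoint (5 or 20)
    condition: str = "na"                # ionic screening: "na" or "mg"
    v100: float = 200.0                  # bp/s at 100% filling, na/5 pN
    decade_filling: float = 20.0         # % filling per 10x velocity increase
    velocity_cap: float = 12000.0        # bp/s, tracking limit
    pause_rate_100: float = 0.030        # per-bp pause hazard at 100% filling
    pause_rate_scale: float = 7.0        # % filling hazard decay scale
    pareto_alpha: float = 2.3            # duration tail exponent (>2)
    pareto_xmin_100: float = 0.09        # s, duration scale at 100% filling
    xmin_scale: float = 15.0             # % filling xmin decay scale
    heterogeneity_sigma: float = 0.6     # log-SD of per-event mobility factor
    extension_noise: float = 3.0         # nm per 1 kHz sample
    drift: float = 0.5                   # nm/s slow instrumental drift
    force_jitter: float = 0.3            # pN rms clamp jitter
    mg_velocity_factor: float = 0.5
    mg_xmin_factor: float = 1.5
    mg_rate_factor: float = 1.2
    highforce_rate_factor: float = 0.6
    highforce_xmin_factor: float = 0.7
    d_true: float = 0.34                 # nm, monomer spacing in the PT factor
    min_pause_filling: float = 50.0      # % filling below which pausing stops
    initial_tether_bp: float = 5700.0    # bp of tether outside the capsid at t0
    pauses: bool = True
    heterogeneity: bool = True
    seed: int = 0
    elastic: ElasticParams = field(default_factory=ElasticParams)

    def __post_init__(self) -> None:
        if self.condition not in ("na", "mg"):
            raise ValueError("condition must be 'na' or 'mg'")
        if self.pareto_alpha <= 2:
            raise ValueError("pareto_alpha must exceed 2 (finite mean duration)")
        positive = (
            "genome_bp", "sample_rate", "applied_force", "v100", "decade_filling",
            "velocity_cap", "pause_rate_100", "pause_rate_scale", "pareto_xmin_100",
            "xmin_scale", "heterogeneity_sigma", "mg_velocity_factor",
            "mg_xmin_factor", "mg_rate_factor", "highforce_rate_factor",
            "highforce_xmin_factor", "d_true", "initial_tether_bp",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.min_pause_filling <= 100:
            raise ValueError("min_pause_filling must lie in [0, 100]")

    @property
    def bp_per_percent(self) -> float:
        return self.genome_bp / 100.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class Trace:
    """One recorded event: time (s), clamped force (pN), extension (nm)."""

    event_id: str
    kind: str  # "ejection" or "control"
    time: np.ndarray
    force: np.ndarray
    extension: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("ejection", "control"):
            raise ValueError("kind must be 'ejection' or 'control'")
        if len(self.time) >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def _condition_force_factor(config: SimConfig) -> float:
    """Velocity multiplier relative to the na / 5 pN anchor condition."""
    factor = 1.0
    if config.condition == "mg":
        factor *= config.mg_velocity_factor
    if config.applied_force != REFERENCE_FORCE_PN:
        kT = config.elastic.kT
        factor *= math.exp(
            (config.applied_force - REFERENCE_FORCE_PN) * config.d_true / kT
        )
    return factor


def base_velocity(filling, config: SimConfig):
    """Mean (pause-free) exit velocity in bp/s at a capsid filling in %."""
    arr = np.asarray(filling, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError("filling must lie in [0, 100]")
    v = config.v100 * 10.0 ** ((100.0 - arr) / config.decade_filling)
    v = v * _condition_force_factor(config)
    return float(v) if v.ndim == 0 else v


def _pause_hazard_params(config: SimConfig) -> tuple[float, float]:
    """(hazard at x=0 per bp, hazard decay length in bp)."""
    lam0 = config.pause_rate_100
    if config.condition == "mg":
        lam0 *= config.mg_rate_factor
    if config.applied_force != REFERENCE_FORCE_PN:
        lam0 *= config.highforce_rate_factor
    return lam0, config.pause_rate_scale * config.bp_per_percent


def _xmin_at(x: float, config: SimConfig) -> float:
    """Pareto duration scale (s) at exited length x bp."""
    xmin = config.pareto_xmin_100 * math.exp(
        -x / (config.xmin_scale * config.bp_per_percent)
    )
    if config.condition == "mg":
        xmin *= config.mg_xmin_factor
    if config.applied_force != REFERENCE_FORCE_PN:
        xmin *= config.highforce_xmin_factor
    return xmin


def _draw_pause_positions(config: SimConfig, x_stop: float, rng) -> Iterator[float]:
    """Poisson pause onsets in exited length, inhomogeneous hazard."""
    lam0, ell = _pause_hazard_params(config)
    x = 0.0
    while x < x_stop:
        # Invert the integrated hazard Lambda = lam0*ell*(e^{-x/ell}-e^{-x'/ell}).
        e = rng.exponential()
        arg = math.exp(-x / ell) - e / (lam0 * ell)
        if arg <= 0:
            return
        x = -ell * math.log(arg)
        if x < x_stop:
            yield x


def _build_schedule(config: SimConfig, rng) -> tuple[list, float, float]:
    """Event schedule: list of (t_start, t_end, kind, x_start) segments.

    kind is "move" or "pause"; x within a move segment follows the closed
    form of the velocity law. Returns (segments, eta, x_cap).
    """
    eta = 1.0
    if config.heterogeneity:
        sigma = config.heterogeneity_sigma
        eta = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
    v_anchor = config.v100 * _condition_force_factor(config)
    c = config.decade_filling * config.bp_per_percent / math.log(10.0)
    if eta * v_anchor >= config.velocity_cap:
        return [], eta, 0.0
    x_cap = c * math.log(config.velocity_cap / (eta * v_anchor))
    x_cap = min(x_cap, config.genome_bp)

    x_pause_max = (100.0 - config.min_pause_filling) * config.bp_per_percent
    onsets: list[float] = []
    if config.pauses:
        onsets = [x for x in _draw_pause_positions(config, min(x_cap, x_pause_max), rng)]
    durations = [
        _xmin_at(x, config) * rng.uniform() ** (-1.0 / (config.pareto_alpha - 1.0))
        for x in onsets
    ]

    def move_time(x0: float, x1: float) -> float:
        return (c / (eta * v_anchor)) * (math.exp(-x0 / c) - math.exp(-x1 / c))

    segments = []
    t = 0.0
    x = 0.0
    for xp, dur in zip(onsets, durations):
        dt = move_time(x, xp)
        segments.append((t, t + dt, "move", x))
        t += dt
        segments.append((t, t + dur, "pause", xp))
        t += dur
        x = xp
    dt = move_time(x, x_cap)
    segments.append((t, t + dt, "move", x))
    return segments, eta, x_cap


def _sample_exited_length(times: np.ndarray, segments: list, config: SimConfig,
                          eta: float) -> np.ndarray:
    """Exited length x(t) in bp on the sample grid."""
    v_anchor = config.v100 * _condition_force_factor(config)
    c = config.decade_filling * config.bp_per_percent / math.log(10.0)
    starts = np.array([s[0] for s in segments])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(segments) - 1)
    x = np.empty_like(times)
    for i, (t0, t1, kind, x0) in enumerate(segments):
        sel = idx == i
        if not np.any(sel):
            continue
        if kind == "pause":
            x[sel] = x0
        else:
            u = np.exp(-x0 / c) - eta * v_anchor * (times[sel] - t0) / c
            x[sel] = -c * np.log(np.maximum(u, 1e-300))
    return x


def _instrument_channels(times: np.ndarray, tether_bp: np.ndarray,
                         config: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """(force, extension) with clamp jitter, extension noise and drift.

    Extension is computed from the jittered per-sample force through the
    WLC, mimicking a force-clamp whose recorded force and extension are
    consistent sample by sample.
    """
    force = config.applied_force + config.force_jitter * rng.standard_normal(times.size)
    force = np.maximum(force, 0.1)
    frac = fractional_extension(force, config.elastic)
    extension = (
        tether_bp * config.elastic.rise_per_bp * frac
        + config.extension_noise * rng.standard_normal(times.size)
        + config.drift * times
    )
    return force, np.maximum(extension, 0.0)


def simulate_event(config: SimConfig, rng=None, event_id: str = "event") -> Trace:
    """Simulate one DNA-exit event, starting at 100% filling.

    The event terminates when the instantaneous velocity reaches the
    tracking cap. Ground truth (pause schedule, eta, exited length at each
    sample) is stored in metadata for testing against detection output.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    segments, eta, x_cap = _build_schedule(config, rng)
    t_end = segments[-1][1] if segments else 0.0
    n = max(int(math.floor(t_end * config.sample_rate)) + 1, 2)
    times = np.arange(n) / config.sample_rate
    x = _sample_exited_length(times, segments, config, eta)
    tether = config.initial_tether_bp + x
    force, extension = _instrument_channels(times, tether, config, rng)
    truth_pauses = [
        {"start": t0, "end": t1, "x": x0}
        for (t0, t1, kind, x0) in segments if kind == "pause"
    ]
    meta = {
        "config": config.to_dict(),
        "eta": eta,
        "x_cap_bp": x_cap,
        "true_pauses": truth_pauses,
        "true_exited_bp": x,
    }
    return Trace(event_id, "ejection", times, force, extension, meta)


def simulate_control(config: SimConfig, duration: float, rng=None,
                     event_id: str = "control") -> Trace:
    """Static tether held in the force clamp for noise/drift calibration."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = int(round(duration * config.sample_rate))
    times = np.arange(n) / config.sample_rate
    tether = np.full(n, config.initial_tether_bp)
    force, extension = _instrument_channels(times, tether, config, rng)
    meta = {"config": config.to_dict(), "tether_bp": config.initial_tether_bp}
    return Trace(event_id, "control", times, force, extension, meta)


def _event_rng(seed: int, index: int):
    """Counter-based sub-stream: stable under insertion/removal of events."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_ensemble(config: SimConfig, n_events: int, n_controls: int = 3,
                      control_duration: float = 60.0) -> tuple[list[Trace], dict]:
    """Independent events plus control tethers, with a full manifest.

    Every event gets a deterministic sub-seed derived from config.seed and
    its index, so the ensemble is byte-reproducible and unaffected by
    changing n_events for other indices.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    traces: list[Trace] = []
    records = []
    for i in range(n_events):
        eid = f"ej{i:03d}"
        tr = simulate_event(config, rng=_event_rng(config.seed, i), event_id=eid)
        traces.append(tr)
        records.append({
            "event_id": eid, "kind": "ejection", "file": f"{eid}.tsv",
            "sub_seed_index": i, "eta": tr.metadata["eta"],
        })
    for j in range(n_controls):
        eid = f"ctrl{j:03d}"
        tr = simulate_control(config, control_duration,
                              rng=_event_rng(config.seed, 10_000 + j), event_id=eid)
        traces.append(tr)
        records.append({
            "event_id": eid, "kind": "control", "file": f"{eid}.tsv",
            "sub_seed_index": 10_000 + j, "eta": None,
        })
    manifest = {
        "condition": config.condition,
        "applied_force_pN": config.applied_force,
        "genome_bp": config.genome_bp,
        "config": config.to_dict(),
        "events": records,
    }
    # Validate the manifest is JSON-serialisable up front.
    json.dumps(manifest)
    return traces, manifest
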