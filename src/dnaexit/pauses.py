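"""Pause detection by BIC change-point segmentation and noise calibration.

Change points are found with the Kalafut--Visscher scheme: the tether-length
series is modelled as piecewise-constant with shared Gaussian noise, and
change points are added greedily, each step choosing the placement that most
lowers the Schwarz/Bayesian information criterion

    BIC = 2(k + 1) ln N + N ln(SSE / N)

for k change points (each change point contributes a location and a new
segment mean; the global variance is profiled out through SSE). Addition
stops when no placement lowers the BIC. Detection runs on the series block-
averaged to 100 Hz; boundaries are then refined on the full-rate data.

Segments are classified against static-tether controls: the control
distribution of OLS velocities over intervals of duration dt gives a
noise model (mean, SD versus dt), and a segment of duration dt is a pause
when its velocity lies within n_sd control SDs of the control mean.
Adjacent pause segments at the same tether level (one plateau split by the
greedy search) are re-joined; pauses separated by a net advance below the
length resolution are merged; and candidate pauses shorter than the
minimum resolvable duration are dropped. The duration resolution is
velocity dependent: an arrest of duration dt only counts where the local
moving velocity exceeds the control noise at dt, so the floor tightens
automatically in slow stretches. Smooth movement is approximated
by the piecewise-constant model as a staircase of short treads; the level
guard on merging keeps those treads from coalescing into false pauses, and
a local duration-resolution rule removes treads slower than the
classification can resolve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elasticity import ElasticParams
from .kinetics import (bin_edges_for, exited_length_series, filling_series,
                       _rolling_ols_slopes)
from .simulate import Trace


# ---------------------------------------------------------------------------
# Kalafut--Visscher change points
# ---------------------------------------------------------------------------

def _best_split(c1: np.ndarray, c2: np.ndarray, a: int, b: int,
                min_segment: int) -> tuple[float, int]:
    """Largest SSE reduction from one split of segment [a, b)."""
    n = b - a
    if n < 2 * min_segment:
        return -np.inf, -1
    s = np.arange(a + min_segment, b - min_segment + 1)
    tot_sum = c1[b] - c1[a]
    cost_ab = (c2[b] - c2[a]) - tot_sum**2 / n
    left_sum = c1[s] - c1[a]
    nl = (s - a).astype(float)
    nr = (b - s).astype(float)
    cost_split = ((c2[b] - c2[a])
                  - left_sum**2 / nl
                  - (tot_sum - left_sum)**2 / nr)
    k = int(np.argmax(cost_ab - cost_split))
    return float(cost_ab - cost_split[k]), int(s[k])


def kv_changepoints(y: np.ndarray, min_segment: int = 3,
                    sigma: float | None = None) -> list[int]:
    """Greedy BIC change-point indices for a piecewise-constant mean model.

    With sigma=None the global noise variance is profiled out and
    re-estimated from the residual SSE at every greedy step (the classic
    scheme). When the measurement noise is known -- here it is calibrated
    from static control tethers or a robust differenced estimate -- passing
    `sigma` switches to the known-variance criterion: a change point is
    added while the best split reduces the SSE by more than 2 sigma^2 ln N.
    The profiled form is unreliable on strongly accelerating traces, where
    residual ramp curvature inflates the variance estimate and masks pause
    steps; detection therefore always supplies sigma.

    Returns sorted indices i (segments y[..:i], y[i:..]); every segment has
    at least min_segment samples. Raises if the series is shorter than two
    minimal segments.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2 * min_segment:
        raise ValueError("series too short for change-point search")
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost(a: int, b: int) -> float:
        s = c1[b] - c1[a]
        return float((c2[b] - c2[a]) - s * s / (b - a))

    sse = seg_cost(0, n)
    log_n = math.log(n)
    bounds = [0, n]
    best_cache: dict[tuple[int, int], tuple[float, int]] = {}

    def best_of(a: int, b: int) -> tuple[float, int]:
        key = (a, b)
        if key not in best_cache:
            best_cache[key] = _best_split(c1, c2, a, b, min_segment)
        return best_cache[key]

    tiny = max(sse, 1.0) * 1e-15
    while True:
        gains = [best_of(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
        k = int(np.argmax([g for g, _ in gains]))
        gain, split = gains[k]
        if split < 0:
            break
        new_sse = max(sse - gain, tiny)
        # One extra change point costs 2 ln N (a location and a new mean).
        if sigma is None:
            reject = 2.0 * log_n + n * math.log(new_sse / sse) >= 0
        else:
            reject = gain <= 2.0 * sigma * sigma * log_n
        if reject:
            break
        bounds.insert(k + 1, split)
        sse = new_sse
        # Relocation sweep: re-optimise each interior boundary between its
        # fixed neighbours until stable, so greedy placements that landed
        # slightly off a true step get pulled onto it.
        for _ in range(10):
            moved = False
            for i in range(1, len(bounds) - 1):
                a, b = bounds[i - 1], bounds[i + 1]
                old = bounds[i]
                _, s = best_of(a, b)
                if s >= 0 and s != old:
                    delta = (seg_cost(a, old) + seg_cost(old, b)
                             - seg_cost(a, s) - seg_cost(s, b))
                    if delta > 1e-12:
                        bounds[i] = s
                        sse = max(sse - delta, tiny)
                        moved = True
            if not moved:
                break
    return bounds[1:-1]


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise SD of a series from the median absolute first difference.

    Steps and slow ramps barely move the median, so this tracks the
    sample-to-sample measurement noise even on trending data.
    """
    d = np.abs(np.diff(np.asarray(y, dtype=float)))
    # median(|N(0, sqrt(2) sigma)|) = sqrt(2) * 0.674490 * sigma
    return float(np.median(d) / 0.95387)


def _refine_boundary(t: np.ndarray, y: np.ndarray, i: int, lo: int,
                     hi: int) -> int:
    """Re-locate one boundary on full-rate data by a continuous hinge fit.

    A two-mean split is biased into the moving side at a movement/pause
    junction (the ramp's mean differs from the plateau level), so the kink
    is located instead by a piecewise-linear model with free slopes on
    either side, continuous at the boundary.
    """
    lo = max(lo, 1)
    hi = min(hi, y.size - 1)
    if hi - lo < 8:
        return i
    tt = t[lo:hi]
    yy = y[lo:hi]
    best = (np.inf, i)
    ones = np.ones_like(tt)
    for j in range(3, tt.size - 3):
        dt_ = tt - tt[j]
        a_mat = np.stack([ones, np.minimum(dt_, 0.0), np.maximum(dt_, 0.0)], 1)
        coef, res, _, _ = np.linalg.lstsq(a_mat, yy, rcond=None)
        sse = float(res[0]) if res.size else float(
            np.sum((yy - a_mat @ coef) ** 2))
        if sse < best[0]:
            best = (sse, lo + j)
    return best[1]


# ---------------------------------------------------------------------------
# Noise calibration
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Control-tether velocity statistics versus averaging interval.

    dt_grid : interval durations (s)
    mean    : mean control velocity per dt (bp/s; carries the drift)
    sd      : SD of control velocities per dt (bp/s)
    length_resolution_bp : 1 SD of the net length change at the smallest dt
    """

    dt_grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    length_resolution_bp: float

    def sd_at(self, duration: float) -> float:
        """SD interpolated in log-log within the grid.

        Below the smallest calibrated interval the white-noise OLS slope
        scaling SD ~ dt^-3/2 extrapolates (clamping would understate the
        noise of very short intervals); above the grid the last value is
        held, which is conservative.
        """
        if duration < self.dt_grid[0]:
            return float(self.sd[0] * (self.dt_grid[0] / max(duration, 1e-6))
                         ** 1.5)
        d = float(min(duration, self.dt_grid[-1]))
        return float(np.exp(np.interp(math.log(d), np.log(self.dt_grid),
                                      np.log(self.sd))))

    def mean_at(self, duration: float) -> float:
        d = float(np.clip(duration, self.dt_grid[0], self.dt_grid[-1]))
        return float(np.interp(d, self.dt_grid, self.mean))


DEFAULT_DT_GRID = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0)


def calibrate_noise(controls: list[Trace], params: ElasticParams | None = None,
                    dt_grid=DEFAULT_DT_GRID) -> NoiseModel:
    """Velocity noise model from static control tethers.

    For each dt, OLS velocities are computed over non-overlapping intervals
    pooled across controls. Requires total control duration at least
    10 x max(dt).
    """
    if not controls:
        raise ValueError("need at least one control trace")
    params = params or ElasticParams()
    dt_grid = np.asarray(sorted(dt_grid), dtype=float)
    total = sum(tr.time[-1] - tr.time[0] for tr in controls)
    if total < 10 * dt_grid[-1]:
        raise ValueError("insufficient control data for the requested dt grid")
    series = [exited_length_series(tr, params) for tr in controls]
    means, sds = [], []
    net_changes = []
    for dt in dt_grid:
        vels = []
        for t, y in series:
            fs = 1.0 / np.median(np.diff(t))
            n = int(round(dt * fs))
            n_int = y.size // n
            if n_int == 0:
                continue
            starts = np.arange(n_int) * n
            stops = starts + n
            vels.append(_rolling_ols_slopes(t, y, starts, stops))
            if dt == dt_grid[0]:
                half = n // 2
                for a in starts:
                    net_changes.append(y[a + half:a + n].mean() - y[a:a + half].mean())
        vels = np.concatenate(vels)
        means.append(float(vels.mean()))
        sds.append(float(vels.std(ddof=1)))
    sds = np.maximum(sds, 1e-12)
    res = float(np.std(net_changes, ddof=1)) if len(net_changes) > 1 else 0.0
    return NoiseModel(dt_grid, np.asarray(means), np.asarray(sds), res)


# ---------------------------------------------------------------------------
# Pause classification
# ---------------------------------------------------------------------------

@dataclass
class Pause:
    """A detected zero-velocity (clogged) interval."""

    start: float                 # s
    end: float                   # s
    filling_at_onset: float      # %
    exited_length_at_onset: float  # bp

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("pause end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def classify_pauses(time: np.ndarray, length_bp: np.ndarray,
                    changepoints: list[int], noise: NoiseModel,
                    filling: np.ndarray | None = None,
                    n_sd: float = 2.5, min_pause_s: float = 0.04,
                    resolution_margin: float = 1.5) -> list[Pause]:
    """Label segments as pauses against the control noise model.

    A segment of duration dt is a pause when its OLS velocity lies within
    n_sd control SDs of the control mean at that dt. Adjacent pauses at the
    same tether level (one plateau split by the greedy search) are
    re-joined; pauses separated by an intervening net advance of at most
    the length resolution are merged; pauses shorter than min_pause_s are
    discarded.

    Finally, the duration resolution limit is applied locally: a candidate
    pause of duration dt only counts when the surrounding moving velocity
    exceeds (n_sd + resolution_margin) control SDs at dt -- otherwise a
    slice of slow movement of that duration would be indistinguishable from
    a genuine arrest, and neither can be claimed.
    """
    time = np.asarray(time, float)
    length_bp = np.asarray(length_bp, float)
    bounds = [0, *sorted(changepoints), time.size]
    raw = [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b - a >= 2]

    dt0 = float(np.median(np.diff(time)))
    segments = []
    for a, b in raw:
        total = float(length_bp[a:b].sum())
        dur = time[b - 1] - time[a]
        # Guarded interior: segment boundaries can overhang into adjacent
        # movement by a sample or two of the detection grid, and that
        # contamination dominates the (tight) slope threshold. The slope is
        # therefore measured on the interior — trimming 20% of the duration
        # per side, between 0.01 and 0.05 s — with the threshold taken at
        # the interior duration.
        g = int(round(min(0.05, max(0.2 * dur, 0.01)) / dt0))
        a2, b2 = a + g, b - g
        if b2 - a2 < 3:
            a2, b2 = a, b
        dur_eff = time[b2 - 1] - time[a2]
        slope = _rolling_ols_slopes(time, length_bp,
                                    np.array([a2]), np.array([b2]))[0]
        is_pause = (abs(slope - noise.mean_at(dur_eff))
                    <= n_sd * noise.sd_at(dur_eff))
        segments.append({"a": a, "b": b, "pause": bool(is_pause),
                         "level": total / (b - a), "slope": float(slope)})

    # Merge pause / tiny-movement / pause sandwiches into one pause.
    merged: list[dict] = []
    for seg in segments:
        if (seg["pause"] and len(merged) >= 2 and not merged[-1]["pause"]
                and merged[-2]["pause"]
                and abs(seg["level"] - merged[-2]["level"])
                <= noise.length_resolution_bp):
            merged.pop()
            prev = merged.pop()
            merged.append({"a": prev["a"], "b": seg["b"], "pause": True,
                           "level": (prev["level"] + seg["level"]) / 2.0,
                           "slope": 0.0})
        elif (seg["pause"] and merged and merged[-1]["pause"]
                and abs(seg["level"] - merged[-1]["level"])
                <= noise.length_resolution_bp):
            prev = merged.pop()
            merged.append({"a": prev["a"], "b": seg["b"], "pause": True,
                           "level": (prev["level"] + seg["level"]) / 2.0,
                           "slope": 0.0})
        else:
            merged.append(dict(seg))

    # Moving-time bookkeeping for the local resolution rule. Only long,
    # confidently classified arrests are excluded: short ambiguous
    # candidates may be unresolved movement, and counting them as paused
    # would inflate the apparent local velocity.
    dt_sample = float(np.median(np.diff(time)))
    paused_mask = np.zeros(time.size, dtype=bool)
    for seg in merged:
        if seg["pause"] and (seg["b"] - seg["a"]) * dt_sample >= 0.3:
            paused_mask[seg["a"]:seg["b"]] = True

    def local_moving_velocity(a: int, b: int) -> float:
        """Net advance per unit un-paused time around segment [a, b)."""
        for w in (1.0, 3.0):
            half = int(round(w / dt_sample))
            lo, hi = max(a - half, 0), min(b + half, time.size)
            moving = (~paused_mask[lo:hi]).sum() * dt_sample
            if moving >= 0.2:
                k = max(min((hi - lo) // 20, 50), 1)
                adv = length_bp[hi - k:hi].mean() - length_bp[lo:lo + k].mean()
                return abs(adv) / moving
        return math.inf  # no resolvable movement nearby; keep the pause

    def adjacent_moving_slope(i: int) -> float:
        """Moving velocity of the nearest non-pause neighbours.

        Where pausing is dense, the windowed staircase rate (advance over
        un-paused time) underestimates the true moving velocity because
        short unexcluded arrests pad its denominator. The slopes of the
        flanking movement segments measure it directly: a genuine short
        arrest sits between fast segments, whereas an unresolvable slice of
        slow movement sits between equally slow ones.
        """
        slopes = []
        for j in (range(i - 1, -1, -1), range(i + 1, len(merged))):
            for k in j:
                if not merged[k]["pause"]:
                    slopes.append(abs(merged[k]["slope"]))
                    break
        return min(slopes) if slopes else 0.0

    pauses: list[Pause] = []
    for i, seg in enumerate(merged):
        if not seg["pause"]:
            continue
        a, b = seg["a"], seg["b"]
        start, end = float(time[a]), float(time[min(b, time.size - 1)])
        dur = end - start
        if dur < min_pause_s:
            continue
        # Resolution at the same guarded duration the classifier used: the
        # local movement must be distinguishable from a static tether over
        # that interval, else the candidate cannot be claimed as an arrest.
        g_s = min(0.05, max(0.2 * dur, 0.01))
        dur_eff = max(dur - 2 * g_s, dt_sample)
        v_local = max(local_moving_velocity(a, b), adjacent_moving_slope(i))
        if v_local < (n_sd + resolution_margin) * noise.sd_at(dur_eff):
            continue  # below the local duration-resolution limit
        fill = float(filling[a]) if filling is not None else float("nan")
        pauses.append(Pause(start, end, fill, float(length_bp[a])))
    return pauses


def _block_average(time: np.ndarray, y: np.ndarray, factor: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    n = (y.size // factor) * factor
    tb = time[:n].reshape(-1, factor).mean(axis=1)
    yb = y[:n].reshape(-1, factor).mean(axis=1)
    return tb, yb


def detect_pauses(trace: Trace, noise: NoiseModel,
                  params: ElasticParams | None = None,
                  genome_bp: float = 19300.0,
                  detection_rate: float = 100.0,
                  min_segment: int = 3, n_sd: float = 2.5,
                  min_pause_s: float = 0.04, resolution_margin: float = 1.5,
                  refine: bool = True) -> list[Pause]:
    """Full pause detection for one ejection trace.

    Length conversion -> block-average to the detection rate -> KV change
    points -> boundary refinement at full rate -> classification against
    the control noise model.
    """
    params = params or ElasticParams()
    t, x = exited_length_series(trace, params)
    _, fill = filling_series(t, x, genome_bp)
    fs = 1.0 / np.median(np.diff(t))
    factor = max(int(round(fs / detection_rate)), 1)
    tb, xb = _block_average(t, x, factor)
    if xb.size < 2 * min_segment:
        return []
    cps_b = kv_changepoints(xb, min_segment=min_segment,
                            sigma=robust_noise_sd(xb))
    cps = [min(c * factor, x.size - 1) for c in cps_b]
    if refine and factor > 1:
        cps = [_refine_boundary(t, x, c, c - 5 * factor, c + 5 * factor)
               for c in cps]
        cps = sorted(set(int(c) for c in cps))
    return classify_pauses(t, x, cps, noise, filling=fill, n_sd=n_sd,
                           min_pause_s=min_pause_s,
                           resolution_margin=resolution_margin)


# ---------------------------------------------------------------------------
# Per-bin pause metrics
# ---------------------------------------------------------------------------

def fraction_time_paused(pauses_by_event: dict[str, list[Pause]],
                         total_time_by_event: dict[str, float]) -> float:
    """Pooled fraction of total exit time spent paused."""
    paused = sum(p.duration for ps in pauses_by_event.values() for p in ps)
    total = sum(total_time_by_event.values())
    if total <= 0:
        raise ValueError("total exit time must be positive")
    return paused / total


def pause_metrics_by_bin(pauses_by_event: dict[str, list[Pause]],
                         filling_by_event: dict[str, tuple[np.ndarray, np.ndarray]],
                         genome_bp: float = 19300.0, bin_width: float = 5.0,
                         bootstrap_reps: int = 1000, seed: int | None = 0
                         ) -> pd.DataFrame:
    """Pause frequency, mean duration and paused-time fraction per bin.

    Pauses are assigned to bins by filling at onset. Frequency is pauses
    per kb exited within the bin, computed per event and averaged across
    events with bootstrap SEs; fraction is pooled paused time over total
    time in the bin.
    """
    edges = bin_edges_for(bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    per_event: dict[str, dict] = {}
    for eid, (t, fill) in filling_by_event.items():
        dt = np.median(np.diff(t))
        idx = np.clip(np.searchsorted(edges, fill, side="right") - 1, 0, len(edges) - 2)
        time_in_bin = np.bincount(idx, minlength=len(centers)) * dt
        kb_in_bin = np.zeros(len(centers))
        for b in range(len(centers)):
            sel = idx == b
            if sel.any():
                kb_in_bin[b] = (fill[sel].max() - fill[sel].min()) * genome_bp / 100 / 1000
        counts = np.zeros(len(centers))
        paused = np.zeros(len(centers))
        durs: dict[int, list[float]] = {}
        for p in pauses_by_event.get(eid, []):
            b = int(np.clip(np.searchsorted(edges, p.filling_at_onset, side="right") - 1,
                            0, len(centers) - 1))
            counts[b] += 1
            paused[b] += p.duration
            durs.setdefault(b, []).append(p.duration)
        per_event[eid] = {"time": time_in_bin, "kb": kb_in_bin,
                          "counts": counts, "paused": paused, "durs": durs}

    rows = []
    eids = list(per_event)
    rng = np.random.default_rng(seed)
    for b, center in enumerate(centers):
        covering = [e for e in eids if per_event[e]["kb"][b] > 0]
        if not covering:
            continue
        freqs = np.array([per_event[e]["counts"][b] / max(per_event[e]["kb"][b], 1e-12)
                          for e in covering])
        total_t = sum(per_event[e]["time"][b] for e in covering)
        paused_t = sum(per_event[e]["paused"][b] for e in covering)
        all_durs = [d for e in covering for d in per_event[e]["durs"].get(b, [])]
        boot = np.empty(bootstrap_reps)
        for r in range(bootstrap_reps):
            boot[r] = freqs[rng.integers(0, len(freqs), len(freqs))].mean()
        rows.append({
            "filling_pct": center,
            "frequency_per_kb": float(freqs.mean()),
            "frequency_se": float(boot.std(ddof=0)),
            "mean_duration_s": float(np.mean(all_durs)) if all_durs else np.nan,
            "fraction_paused": paused_t / total_t if total_t > 0 else np.nan,
            "n_events": len(covering),
            "n_pauses": int(sum(per_event[e]["counts"][b] for e in covering)),
        })
    return pd.DataFrame(rows).sort_values("filling_pct").reset_index(drop=True)
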