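"""Trajectory kinetics: exited length, filling, windowed velocities, profiles.

The measured observables are (time, clamped force, extension). Each sample
is converted to a DNA tether contour length through the extensible WLC
using the per-sample measured force; the exited length is the tether-length
increase since the start of the record, and the capsid filling follows from
the genome length (193 bp per percent for the 19.3 kb phi29 genome).

Velocities are ordinary least-squares slopes of tether length versus time
in a 0.5 s sliding window (0.1 s step), each window assigned the filling at
its midpoint. Per-event profiles are means in 5% filling bins (an event
must traverse at least half a bin to populate it), and the ensemble profile
averages per-event bin means across complexes with bootstrap standard
errors from resampling whole events.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elasticity import ElasticParams, contour_length_bp
from .simulate import Trace


def exited_length_series(trace: Trace, params: ElasticParams | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """(time, exited length in bp) with exited(t0) = 0.

    Raises ValueError if the trace contains non-positive forces.
    """
    if len(trace.time) < 2:
        raise ValueError("trace must have at least 2 samples")
    params = params or ElasticParams()
    if np.any(trace.force <= 0):
        raise ValueError("trace contains non-positive forces")
    length = contour_length_bp(trace.extension, trace.force, params)
    return trace.time, length - length[0]


def filling_series(time: np.ndarray, exited_bp: np.ndarray, genome_bp: float,
                   initial_filling: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
    """Capsid filling (%) versus time, clipped at zero."""
    if not 0 < initial_filling <= 100:
        raise ValueError("initial_filling must lie in (0, 100]")
    filling = initial_filling - 100.0 * np.asarray(exited_bp) / genome_bp
    return time, np.maximum(filling, 0.0)


def _rolling_ols_slopes(t: np.ndarray, y: np.ndarray, starts: np.ndarray,
                        stops: np.ndarray) -> np.ndarray:
    """OLS slope of y on t for index windows [starts[k], stops[k])."""
    c1 = np.concatenate([[0.0], np.cumsum(t)])
    c2 = np.concatenate([[0.0], np.cumsum(t * t)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    n = (stops - starts).astype(float)
    st = c1[stops] - c1[starts]
    stt = c2[stops] - c2[starts]
    sy = cy[stops] - cy[starts]
    sty = cty[stops] - cty[starts]
    denom = n * stt - st * st
    return (n * sty - st * sy) / denom


def window_velocities(time: np.ndarray, length_bp: np.ndarray,
                      window: float = 0.5, step: float = 0.1) -> pd.DataFrame:
    """Sliding-window OLS velocities (bp/s).

    Returns a DataFrame with columns time (window midpoint), t_start, t_end
    and velocity. Raises if the series is shorter than one window or a
    window would hold fewer than 3 samples.
    """
    time = np.asarray(time, float)
    length_bp = np.asarray(length_bp, float)
    duration = time[-1] - time[0]
    if duration < window:
        raise ValueError("series shorter than one window")
    t_starts = time[0] + step * np.arange(int(math.floor((duration - window) / step)) + 1)
    starts = np.searchsorted(time, t_starts, side="left")
    stops = np.searchsorted(time, t_starts + window, side="right")
    if np.any(stops - starts < 3):
        raise ValueError("window holds fewer than 3 samples")
    slopes = _rolling_ols_slopes(time, length_bp, starts, stops)
    return pd.DataFrame({
        "time": t_starts + window / 2.0,
        "t_start": t_starts,
        "t_end": t_starts + window,
        "velocity": slopes,
    })


def attach_filling(samples: pd.DataFrame, time: np.ndarray,
                   filling: np.ndarray) -> pd.DataFrame:
    """Add the filling at each window midpoint (linear interpolation)."""
    out = samples.copy()
    out["filling"] = np.interp(out["time"].to_numpy(), time, filling)
    return out


def excise_pauses(time: np.ndarray, length_bp: np.ndarray, pauses
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove pause intervals and stitch the movement onto a pause-free clock.

    Because the tether does not advance during a pause, deleting the paused
    samples and re-indexing time at the sample spacing leaves a continuous
    length series whose local slope is the pause-free exit velocity. This
    is how pause-excluded velocities stay measurable even when pauses are
    more closely spaced than one analysis window. Returns (stitched time,
    stitched length, original-sample indices kept).
    """
    time = np.asarray(time, float)
    keep = np.ones(time.size, dtype=bool)
    for p in pauses:
        keep &= ~((time >= p.start) & (time < p.end))
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        raise ValueError("no unpaused samples left after excision")
    dt = float(np.median(np.diff(time)))
    stitched_t = np.arange(idx.size) * dt
    return stitched_t, np.asarray(length_bp, float)[idx], idx


def flag_paused_windows(samples: pd.DataFrame, pauses) -> pd.DataFrame:
    """Mark windows overlapping any detected pause.

    Pause-excluded statistics use only windows wholly outside pauses, so a
    window straddling a pause boundary is flagged (and later dropped).
    """
    out = samples.copy()
    flag = np.zeros(len(out), dtype=bool)
    t0 = out["t_start"].to_numpy()
    t1 = out["t_end"].to_numpy()
    for p in pauses:
        flag |= (t0 < p.end) & (t1 > p.start)
    out["paused"] = flag
    return out


def bin_edges_for(bin_width: float) -> np.ndarray:
    if not (0 < bin_width <= 100) or abs(100.0 / bin_width - round(100.0 / bin_width)) > 1e-9:
        raise ValueError("bin_width must divide 100")
    return np.arange(0.0, 100.0 + bin_width / 2, bin_width)


def _bin_index(filling: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [low, high), top bin closed at 100."""
    idx = np.searchsorted(edges, filling, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def event_profile(samples: pd.DataFrame, exclude_paused: bool = True,
                  bin_width: float = 5.0, min_coverage: float = 0.5) -> pd.Series:
    """Per-event mean velocity in filling bins.

    A bin is populated only when the event's traversed filling span covers
    at least `min_coverage` of the bin; bins without (non-paused) samples
    are absent rather than zero. Index: bin centers (%).
    """
    if samples.empty:
        raise ValueError("no velocity samples")
    edges = bin_edges_for(bin_width)
    f_lo = float(samples["filling"].min())
    f_hi = float(samples["filling"].max())
    use = samples
    if exclude_paused and "paused" in samples:
        use = samples[~samples["paused"]]
    idx = _bin_index(use["filling"].to_numpy(), edges)
    means: dict[float, float] = {}
    for b in np.unique(idx):
        lo, hi = edges[b], edges[b + 1]
        covered = min(f_hi, hi) - max(f_lo, lo)
        if covered < min_coverage * bin_width:
            continue
        means[(lo + hi) / 2.0] = float(use["velocity"].to_numpy()[idx == b].mean())
    return pd.Series(means, dtype=float).sort_index()


@dataclass
class VelocityProfile:
    """Ensemble mean velocity versus filling bin with bootstrap SEs."""

    bin_centers: np.ndarray          # %
    mean_velocity: np.ndarray        # bp/s
    se: np.ndarray                   # bp/s, bootstrap over events
    n_events: np.ndarray             # events contributing per bin
    bin_width: float = 5.0
    pauses_included: bool = False
    per_event: pd.DataFrame | None = field(default=None, repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "filling_pct": self.bin_centers,
            "velocity_bp_s": self.mean_velocity,
            "se_bp_s": self.se,
            "n_events": self.n_events,
        })


def ensemble_profile(event_profiles: list[pd.Series], bootstrap_reps: int = 1000,
                     seed: int | None = 0, bin_width: float = 5.0,
                     pauses_included: bool = False) -> VelocityProfile:
    """Average per-event bin means across complexes.

    SEs are the SD of per-bin means over bootstrap resamples of whole
    events (with replacement), matching averaging "across complexes".
    """
    if not event_profiles:
        raise ValueError("need at least one event profile")
    table = pd.DataFrame(event_profiles).T  # rows: bin centers, cols: events
    table = table.sort_index()
    mean = table.mean(axis=1, skipna=True)
    n_ev = table.notna().sum(axis=1)
    rng = np.random.default_rng(seed)
    m = table.shape[1]
    arr = table.to_numpy()
    boots = np.full((bootstrap_reps, len(table)), np.nan)
    with warnings.catch_warnings():
        # a resample may miss every event covering some bin: all-NaN slice
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for r in range(bootstrap_reps):
            cols = rng.integers(0, m, size=m)
            boots[r] = np.nanmean(arr[:, cols], axis=1)
        se = np.nanstd(boots, axis=0, ddof=0)
    return VelocityProfile(
        bin_centers=table.index.to_numpy(float),
        mean_velocity=mean.to_numpy(float),
        se=se,
        n_events=n_ev.to_numpy(),
        bin_width=bin_width,
        pauses_included=pauses_included,
        per_event=table,
    )


def fit_exponential_profile(profile: VelocityProfile,
                            fit_range: tuple[float, float] = (80.0, 100.0)
                            ) -> tuple[float, float]:
    """Log-linear fit of the binned profile: v = v100 * 10^((100-phi)/decade).

    Returns (velocity extrapolated to 100% filling, decade_filling in %).
    A flat profile returns decade_filling = inf. Raises on non-positive bin
    means or fewer than 3 populated bins in range.
    """
    lo, hi = fit_range
    sel = (profile.bin_centers >= lo) & (profile.bin_centers <= hi)
    sel &= np.isfinite(profile.mean_velocity)
    phi = profile.bin_centers[sel]
    v = profile.mean_velocity[sel]
    if len(phi) < 3:
        raise ValueError("need at least 3 populated bins in fit range")
    if np.any(v <= 0):
        raise ValueError("non-positive bin mean; cannot fit log-linear profile")
    slope, intercept = np.polyfit(phi, np.log10(v), 1)
    v_100 = 10.0 ** (intercept + slope * 100.0)
    decade = math.inf if abs(slope) < 1e-12 else -1.0 / slope
    return float(v_100), float(decade)
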