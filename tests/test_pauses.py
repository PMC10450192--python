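"""Change-point search, noise calibration and pause classification."""

import itertools
import math

import numpy as np
import pytest

import dnaexit as d
from dnaexit import pauses as P


# ---------------------------------------------------------------------------
# Kalafut--Visscher change points
# ---------------------------------------------------------------------------

def exhaustive_bic(y: np.ndarray, max_cps: int = 2, min_segment: int = 3):
    """Brute-force global BIC minimiser over all <=max_cps placements.

    BIC = 2(k+1) ln n + n ln(SSE/n), the same criterion the greedy search
    uses, evaluated by direct enumeration.
    """
    n = y.size

    def sse_of(bounds):
        tot = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = y[a:b]
            tot += float(np.sum((seg - seg.mean()) ** 2))
        return tot

    best = (2 * math.log(n) + n * math.log(max(sse_of([0, n]), 1e-300) / n), [])
    positions = range(min_segment, n - min_segment + 1)
    for k in range(1, max_cps + 1):
        for cps in itertools.combinations(positions, k):
            bounds = [0, *cps, n]
            if any(b - a < min_segment for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            bic = (2 * (k + 1) * math.log(n)
                   + n * math.log(max(sse_of(bounds), 1e-300) / n))
            if bic < best[0] - 1e-12:
                best = (bic, list(cps))
    return best[1]


def test_kv_clean_step():
    y = np.concatenate([np.zeros(50), np.full(50, 100.0)])
    assert d.kv_changepoints(y, min_segment=3) == [50]


def test_kv_pure_noise_rarely_splits():
    """BIC penalty dominates on structureless data: >=95% of seeded pure
    Gaussian series of n=500 yield zero change points."""
    hits = 0
    for seed in range(100):
        y = np.random.default_rng(seed).normal(0, 1, 500)
        hits += bool(d.kv_changepoints(y, min_segment=3))
    assert hits <= 5


@pytest.mark.parametrize("seed", range(12))
def test_kv_matches_exhaustive_search(seed):
    """Greedy addition reaches the global BIC optimum on small instances
    with at most two true steps (exhaustive-enumeration oracle, which
    searches one extra change point beyond the truth so that occasional
    BIC-favoured noise splits are scored identically for both)."""
    rng = np.random.default_rng(seed)
    k_true = seed % 3
    n = 40
    y = rng.normal(0, 1.0, n)
    if k_true >= 1:
        y[15:] += 6.0
    if k_true == 2:
        y[28:] += 6.0
    greedy = d.kv_changepoints(y, min_segment=3)
    assert greedy == exhaustive_bic(y, max_cps=3, min_segment=3)


def test_kv_respects_min_segment_and_length():
    y = np.concatenate([np.zeros(4), np.full(4, 50.0)])
    cps = d.kv_changepoints(y, min_segment=4)
    assert cps == [4]
    with pytest.raises(ValueError):
        d.kv_changepoints(np.zeros(5), min_segment=3)


def test_kv_known_variance_resolves_steps_on_ramp():
    """With the calibrated-noise acceptance rule, a step riding on a strong
    ramp is still found (the profiled-variance form is masked by ramp SSE)."""
    rng = np.random.default_rng(2)
    t = np.arange(600, dtype=float)
    y = 5.0 * t + rng.normal(0, 3.0, 600)
    y[200:260] = y[200]  # a 60-sample plateau (pause) in the ramp
    y[260:] -= y[260] - y[259]
    cps = d.kv_changepoints(y, min_segment=3, sigma=3.0)
    assert any(abs(c - 200) <= 5 for c in cps)
    assert any(abs(c - 260) <= 5 for c in cps)


def test_robust_noise_sd():
    rng = np.random.default_rng(0)
    y = np.cumsum(np.zeros(5000)) + rng.normal(0, 2.5, 5000)
    assert P.robust_noise_sd(y) == pytest.approx(2.5, rel=0.1)


# ---------------------------------------------------------------------------
# Noise calibration
# ---------------------------------------------------------------------------

def test_calibrate_noise_matches_analytic_sd(noise_model, elastic):
    """Control SD at dt=0.5 s equals the closed-form OLS slope SD
    propagated through the WLC at the 5 pN clamp."""
    nm_per_bp = elastic.rise_per_bp * d.fractional_extension(5.0, elastic)
    n = 500
    expected = 3.0 * math.sqrt(12 / n) / 0.5 / nm_per_bp
    i = list(noise_model.dt_grid).index(0.5)
    assert noise_model.sd[i] == pytest.approx(expected, rel=0.3)


def test_noise_sd_decreases_with_dt(noise_model):
    assert noise_model.sd[-1] <= noise_model.sd[0]
    assert noise_model.sd_at(2.0) <= noise_model.sd_at(0.5) <= noise_model.sd_at(0.05)


def test_zero_noise_control_gives_zero_resolution(elastic):
    cfg = d.SimConfig(extension_noise=1e-12, drift=0.0, force_jitter=1e-12, seed=0)
    tr = d.simulate_control(cfg, 30.0, rng=np.random.default_rng(0))
    nm = d.calibrate_noise([tr], elastic)
    assert nm.length_resolution_bp < 1e-6
    assert np.all(nm.sd < 1e-6)


def test_calibrate_noise_requires_enough_data(elastic):
    cfg = d.SimConfig(seed=0)
    tr = d.simulate_control(cfg, 5.0, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        d.calibrate_noise([tr], elastic)  # 5 s < 10 x max dt
    with pytest.raises(ValueError):
        d.calibrate_noise([], elastic)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _trace_from_length(length_bp, cfg, seed=0):
    """Build a synthetic trace with a prescribed exited-length schedule."""
    rng = np.random.default_rng(seed)
    t = np.arange(length_bp.size) / cfg.sample_rate
    tether = cfg.initial_tether_bp + length_bp
    from dnaexit.simulate import _instrument_channels
    force, ext = _instrument_channels(t, tether, cfg, rng)
    return d.Trace("synthetic", "ejection", t, force, ext)


def test_single_inserted_pause_recovered(noise_model):
    """One 1.0 s arrest inside steady 300 bp/s movement is found with the
    right duration."""
    cfg = d.SimConfig(seed=0)
    t = np.arange(0, 6, 1e-3)
    v = 300.0
    x = np.where(t < 2.5, v * t,
                 np.where(t < 3.5, v * 2.5, v * (t - 1.0)))
    tr = _trace_from_length(x, cfg, seed=3)
    pl = d.detect_pauses(tr, noise_model)
    assert len(pl) == 1
    assert pl[0].duration == pytest.approx(1.0, abs=0.1)
    assert pl[0].start == pytest.approx(2.5, abs=0.05)


def test_pause_free_event_yields_no_resolvable_pauses(noise_model):
    """A pause-free event produces no substantial detected pause; brief
    marginal fragments near the duration-resolution limit are possible on
    noisy data and must stay below 3% of the event duration."""
    cfg = d.SimConfig(pauses=False, heterogeneity=False, seed=5)
    tr = d.simulate_event(cfg, rng=np.random.default_rng(5))
    pl = d.detect_pauses(tr, noise_model)
    assert all(p.duration < 0.3 for p in pl)
    assert sum(p.duration for p in pl) < 0.03 * (tr.time[-1] - tr.time[0])


def test_unresolvable_gap_merges_pauses():
    """Two 0.5 s pauses separated by a 2 bp advance (below the length
    resolution) merge into one; a resolvable 30 bp advance keeps them
    separate. Noiseless series with exact change points isolates the rule."""
    t = np.arange(0, 3, 1e-3)
    nm = d.NoiseModel(np.array([0.05, 0.5, 2.0]), np.zeros(3),
                      np.array([90.0, 3.0, 0.4]), length_resolution_bp=3.0)

    def series(gap_bp):
        v = 300.0
        x = np.piecewise(
            t,
            [t < 1.0, (t >= 1.0) & (t < 1.5), (t >= 1.5) & (t < 1.52),
             (t >= 1.52) & (t < 2.02), t >= 2.02],
            [lambda u: v * u, v, lambda u: v + gap_bp * (u - 1.5) / 0.02,
             v + gap_bp, lambda u: v + gap_bp + v * (u - 2.02)],
        )
        cps = [np.searchsorted(t, s) for s in (1.0, 1.5, 1.52, 2.02)]
        return d.classify_pauses(t, x, cps, nm)

    merged = series(gap_bp=2.0)
    assert len(merged) == 1
    assert merged[0].duration == pytest.approx(1.02, abs=0.03)
    separate = series(gap_bp=30.0)
    assert len(separate) == 2


def test_detection_sensitivity_on_inserted_pauses(noise_model):
    """Inserted pauses of >=4x the minimum resolvable duration are found
    with >=95% sensitivity at default noise."""
    cfg = d.SimConfig(seed=0)
    v = 250.0
    found = 0
    for seed in range(40):
        t = np.arange(0, 5, 1e-3)
        x = np.where(t < 2.0, v * t, np.where(t < 2.4, 2.0 * v, v * (t - 0.4)))
        tr = _trace_from_length(x, cfg, seed=100 + seed)
        pl = d.detect_pauses(tr, noise_model)
        found += bool([p for p in pl if abs(p.start - 2.0) < 0.2])
    assert found >= 38  # >= 95%


def test_false_pause_time_on_default_simulations(noise_model):
    """On default-condition simulations, falsely claimed pause time is
    <=5% of the detected pause time (ground-truth schedule comparison)."""
    cfg = d.SimConfig(seed=21)
    traces, _ = d.simulate_ensemble(cfg, 8, n_controls=0)
    false_time = 0.0
    det_time = 0.0
    for tr in traces:
        pl = d.detect_pauses(tr, noise_model)
        true_iv = [(p["start"], p["end"]) for p in tr.metadata["true_pauses"]]
        for p in pl:
            overlap = sum(max(0.0, min(p.end, b) - max(p.start, a))
                          for a, b in true_iv)
            if overlap == 0.0:  # no corresponding true arrest at all
                false_time += p.duration
            det_time += p.duration
    assert det_time > 0
    assert false_time / det_time < 0.05


def test_time_conservation_exact(default_ensemble_bundle):
    """Paused + unpaused time equals total event time exactly."""
    bundle = default_ensemble_bundle
    cat = bundle["pause_catalog"]
    for eid, total in bundle["exit_time_s_by_event"].items():
        sel = cat[cat.event_id == eid]
        paused = sel["duration_s"].sum()
        unpaused = total - paused
        assert paused + unpaused == pytest.approx(total, abs=1e-12)
        assert 0 <= paused <= total


def test_pause_metrics_by_bin_basics():
    # 100 -> 98% over 1 s, pause 6 s at 98%, then 98 -> 92% over 3 s
    t = np.arange(0, 10, 1e-3)
    fill = np.piecewise(
        t, [t < 1.0, (t >= 1.0) & (t < 7.0), t >= 7.0],
        [lambda u: 100 - 2 * u, 98.0, lambda u: 98 - 2 * (u - 7.0)])
    pauses = [d.Pause(1.0, 7.0, 98.0, 386.0)]
    metrics = d.pause_metrics_by_bin({"e": pauses}, {"e": (t, fill)},
                                     bootstrap_reps=100)
    top = metrics[metrics.filling_pct == 97.5].iloc[0]
    # 6 s paused of 8.5 s spent in the 95-100% bin
    assert top["fraction_paused"] == pytest.approx(6.0 / 8.5, rel=0.01)
    assert top["mean_duration_s"] == pytest.approx(6.0)
    assert top["n_pauses"] == 1
    # one pause over the 5% x 193 bp/% exited in the bin
    assert top["frequency_per_kb"] == pytest.approx(1.0 / 0.965, rel=0.02)
    # no pauses: zero frequency, absent duration
    m0 = d.pause_metrics_by_bin({"e": []}, {"e": (t, fill)}, bootstrap_reps=100)
    assert (m0["frequency_per_kb"] == 0).all()
    assert m0["mean_duration_s"].isna().all()


def test_pause_frequency_and_duration_decrease_with_exit(default_ensemble_bundle):
    """Ensemble trend: pause frequency and mean duration both fall from the
    95-100% bin to the 80-85% bin."""
    m = default_ensemble_bundle["pause_metrics"]
    m = m[(m.filling_pct >= 80) & (m.filling_pct <= 100)].sort_values("filling_pct")
    freq = m["frequency_per_kb"].to_numpy()
    dur = m["mean_duration_s"].to_numpy()
    assert freq[-1] > freq[0]
    assert dur[-1] > dur[0]
    frac = m["fraction_paused"].to_numpy()
    assert frac[-1] > frac[0]
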