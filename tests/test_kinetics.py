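"""Windowed velocities, filling conversion, binned profiles, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest

import dnaexit as d
from dnaexit import kinetics as K


def _samples(filling, velocity, paused=None):
    n = len(filling)
    return pd.DataFrame({
        "time": np.arange(n, dtype=float),
        "t_start": np.arange(n, dtype=float),
        "t_end": np.arange(n, dtype=float) + 0.5,
        "velocity": velocity,
        "filling": filling,
        "paused": paused if paused is not None else [False] * n,
    })


def test_filling_series_conversions():
    t = np.arange(3, dtype=float)
    _, f = d.filling_series(t, np.array([0.0, 3860.0, 19300.0]), 19300.0)
    assert f == pytest.approx([100.0, 80.0, 0.0])
    _, f2 = d.filling_series(t, np.array([0.0, 1930.0, 0.0]), 19300.0)
    assert f2[1] == pytest.approx(90.0)  # 1930 bp exited = 10% of genome
    with pytest.raises(ValueError):
        d.filling_series(t, np.zeros(3), 19300.0, initial_filling=0.0)


def test_exited_length_zero_for_static_trace(elastic):
    cfg = d.SimConfig(extension_noise=1e-12, drift=0.0, force_jitter=1e-12, seed=0)
    tr = d.simulate_control(cfg, 2.0, rng=np.random.default_rng(0))
    _, x = d.exited_length_series(tr, elastic)
    assert np.max(np.abs(x)) < 1e-6


def test_exited_length_matches_ground_truth(elastic):
    cfg = d.SimConfig(seed=4)
    tr = d.simulate_event(cfg, rng=np.random.default_rng(4))
    t, x = d.exited_length_series(tr, elastic)
    truth = tr.metadata["true_exited_bp"]
    rms = np.sqrt(np.mean((x - x[0] - (truth - truth[0])) ** 2))
    # per-sample noise ~3 nm / 0.32 nm/bp ~ 9.4 bp plus the uncorrected
    # 0.5 nm/s drift accumulating over the event
    nm_per_bp = elastic.rise_per_bp * d.fractional_extension(5.0, elastic)
    drift_rms = cfg.drift / nm_per_bp * t[-1] / math.sqrt(3)
    noise_rms = cfg.extension_noise / nm_per_bp
    assert rms < 2 * math.sqrt(noise_rms**2 + drift_rms**2)
    assert rms > 0.3 * noise_rms


def test_exited_length_rejects_bad_force(elastic):
    tr = d.Trace("x", "ejection", np.arange(3) / 1e3,
                 np.array([5.0, -1.0, 5.0]), np.ones(3))
    with pytest.raises(ValueError):
        d.exited_length_series(tr, elastic)


def test_window_velocity_exact_line():
    t = np.arange(0, 5, 1e-3)
    w = d.window_velocities(t, 100.0 + 300.0 * t)
    assert np.allclose(w["velocity"], 300.0, atol=1e-8)
    w0 = d.window_velocities(t, np.full_like(t, 7.0))
    assert np.allclose(w0["velocity"], 0.0, atol=1e-10)


def test_window_velocity_noise_matches_ols_formula():
    """White noise sigma=10 bp at 1 kHz in 0.5 s windows: slope SD ~ 3.1 bp/s."""
    rng = np.random.default_rng(8)
    t = np.arange(0, 300, 1e-3)
    y = rng.normal(0, 10, t.size)
    w = d.window_velocities(t, y, window=0.5, step=0.5)
    expected = 10 * math.sqrt(12 / 500) / 0.5
    assert w["velocity"].std() == pytest.approx(expected, rel=0.15)


def test_window_velocity_errors():
    t = np.arange(0, 0.3, 1e-3)
    with pytest.raises(ValueError):
        d.window_velocities(t, t)  # shorter than one window
    t2 = np.array([0.0, 0.4, 0.8])
    with pytest.raises(ValueError):
        d.window_velocities(t2, t2, window=0.5, step=0.5)  # <3 samples


def test_time_integral_consistency():
    """Sum of window velocity x step ~ total exited length (step=window)."""
    cfg = d.SimConfig(pauses=False, seed=6)
    tr = d.simulate_event(cfg, rng=np.random.default_rng(6))
    t, x = d.exited_length_series(tr)
    w = d.window_velocities(t, x, window=0.5, step=0.5)
    total = (w["velocity"] * 0.5).sum()
    spanned = x[np.searchsorted(t, w["t_end"].iloc[-1])] - x[0]
    assert total == pytest.approx(spanned, rel=0.05)


def test_event_profile_binning_rules():
    # all samples in one bin, spanning the full bin
    s = _samples([96.0, 97.5, 99.9], [100.0, 200.0, 300.0])
    prof = K.event_profile(s, exclude_paused=False)
    assert prof.loc[97.5] == pytest.approx(200.0)
    # event covering only 40% of a bin: bin absent
    s2 = _samples([92.0, 93.0, 94.0], [100.0, 100.0, 100.0])
    assert 92.5 not in K.event_profile(s2, exclude_paused=False).index
    # all samples paused in a bin and excluded: bin absent
    s3 = _samples([96.0, 99.9], [100.0, 100.0], paused=[True, True])
    assert len(K.event_profile(s3, exclude_paused=True)) == 0
    with pytest.raises(ValueError):
        K.event_profile(s3.iloc[:0], exclude_paused=False)


def test_ensemble_profile_bootstrap_enumeration():
    """Two events {100}, {300}: mean 200; bootstrap SE equals the SD over
    the 4 equally likely resamples: {100,100},{100,300}x2,{300,300} -> 70.7."""
    e1 = pd.Series({92.5: 100.0})
    e2 = pd.Series({92.5: 300.0})
    prof = d.ensemble_profile([e1, e2], bootstrap_reps=4000, seed=0)
    assert prof.mean_velocity[0] == pytest.approx(200.0)
    exact = np.std([100.0, 200.0, 200.0, 300.0])  # exhaustive enumeration
    assert prof.se[0] == pytest.approx(exact, rel=0.05)
    # identical events: SE exactly zero
    prof0 = d.ensemble_profile([e1, e1.copy()], bootstrap_reps=200, seed=0)
    assert prof0.se[0] == 0.0


def test_fit_exponential_profile_exact_recovery():
    centers = np.arange(82.5, 100, 5.0)
    v = 200.0 * 10 ** ((100 - centers) / 20.0)
    prof = d.VelocityProfile(centers, v, np.zeros_like(v), np.ones_like(v))
    v100, decade = d.fit_exponential_profile(prof)
    assert v100 == pytest.approx(200.0, rel=1e-9)
    assert decade == pytest.approx(20.0, rel=1e-9)
    assert v100 * 10 ** (20 / decade) == pytest.approx(2000.0, rel=1e-9)


def test_fit_exponential_profile_flat_and_errors():
    centers = np.arange(82.5, 100, 5.0)
    flat = d.VelocityProfile(centers, np.full(4, 50.0), np.zeros(4), np.ones(4))
    _, decade = d.fit_exponential_profile(flat)
    assert math.isinf(decade)
    bad = d.VelocityProfile(centers, np.array([1.0, -2.0, 3.0, 4.0]),
                            np.zeros(4), np.ones(4))
    with pytest.raises(ValueError):
        d.fit_exponential_profile(bad)
    with pytest.raises(ValueError):
        d.fit_exponential_profile(flat, fit_range=(95.0, 100.0))


def test_pause_free_simulation_recovers_law():
    """Parameter recovery: noiseless, pause-free ensemble returns the
    generator anchors through the full windowing/binning/fit chain."""
    cfg = d.SimConfig(pauses=False, heterogeneity=False, extension_noise=1e-6,
                      drift=0.0, force_jitter=1e-6, seed=10)
    profs = []
    for i in range(3):
        tr = d.simulate_event(cfg, rng=np.random.default_rng(i), event_id=f"e{i}")
        t, x = d.exited_length_series(tr)
        _, fill = d.filling_series(t, x, cfg.genome_bp)
        w = K.attach_filling(d.window_velocities(t, x), t, fill)
        w["paused"] = False
        profs.append(K.event_profile(w, exclude_paused=False))
    prof = d.ensemble_profile(profs, bootstrap_reps=100, seed=0)
    v100, decade = d.fit_exponential_profile(prof)
    assert v100 == pytest.approx(200.0, rel=0.03)
    assert decade == pytest.approx(20.0, rel=0.03)


def test_excise_pauses_recovers_movement_velocity():
    """Stitching out pauses leaves a continuous series whose slope is the
    pause-free velocity."""
    t = np.arange(0, 3, 1e-3)
    v = 250.0
    # movement 0-1 s, pause 1-2 s, movement 2-3 s
    x = np.where(t < 1, v * t, np.where(t < 2, v * 1.0, v * (t - 1)))
    class P:  # minimal pause stub
        start, end = 1.0, 2.0
    ts, xs, idx = K.excise_pauses(t, x, [P])
    assert ts.size == idx.size == 2000
    w = d.window_velocities(ts, xs)
    assert np.allclose(w["velocity"], v, atol=1e-6)
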