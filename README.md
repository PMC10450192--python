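# dnaexit

Trajectory analysis for single-molecule measurements of DNA exiting a
bacteriophage phi29 capsid under a force clamp, plus a calibrated synthetic
generator of such measurements.

When the packaging motor of phi29 releases its grip, the tightly packed
19.3 kb genome is pushed back out of the capsid by internal confinement
force. In an optical-tweezers force clamp the exiting DNA lengthens the
tether between two trapped beads, and because the motion is overdamped the
friction opposing exit equals the total driving force (internal plus
applied) at every instant. The package implements the full analysis chain
for such recordings:

* **Length conversion** — extensible worm-like-chain (Marko–Siggia with a
  self-consistent enthalpic term) from per-sample force and extension to
  DNA contour length and capsid filling.
* **Velocity profiling** — 0.5 s sliding-window velocities, 5% filling
  bins, per-complex profiles averaged across complexes with bootstrap
  standard errors, and log-linear (exponential-law) profile fits.
* **Pause detection** — Kalafut–Visscher-style BIC change points on the
  100 Hz length series, boundaries refined by hinge fits at 1 kHz,
  segments classified against static-control noise with explicit
  duration- and length-resolution rules; per-bin pause frequency,
  duration and paused-time fraction.
* **Clogging statistics** — exponential fits to inter-pause exited
  lengths, duration survival curves, and Clauset–Shalizi–Newman power-law
  tail fits (KS-minimal cutoff, continuous MLE exponent).
* **Friction-model inference** — per-bin Prandtl–Tomlinson fits
  d = kT·ln(v_hi/v_lo)/(F_hi−F_lo) from paired 5/20 pN profiles, the
  linear-mobility (hydrodynamic) ratio test, and predicted sliding
  friction at motor-driven packaging velocities,
  F = (kT/d)·ln(v/μ) clamped at zero for v ≤ μ.
* **Synthetic data** — force-clamp ejection events with an exponentially
  rising velocity law (one decade per 20% filling, 200 bp/s at full
  capsid), Poisson clogging pauses in exited length with heavy-tailed
  (α = 2.3) durations, per-event mobility heterogeneity, instrument noise
  and drift, a 12 kb/s tracking cap, and static control tethers — all
  byte-reproducible under a seed.

See `docs/methods.md` for the models, estimators, calibration derivations
and known resolution limits.

## Worked example

```python
import dnaexit as d

cfg = d.SimConfig(applied_force=5.0, condition="na", seed=7)
traces, manifest = d.simulate_ensemble(cfg, n_events=12)
bundle = d.run_pipeline(traces, d.AnalysisConfig(seed=7), applied_force=5.0)

fit = bundle["exponential_profile_fit"]
print(f"paused fraction      : {bundle['fraction_time_paused']:.2f}")
print(f"v at 100% filling    : {fit['v_at_100_bp_s']:.0f} bp/s")
print(f"v at  80% filling    : {fit['v_at_80_bp_s']:.0f} bp/s")
print(f"decade per filling   : {fit['decade_filling_pct']:.1f} %")
```

prints

```
paused fraction      : 0.46
v at 100% filling    : 202 bp/s
v at  80% filling    : 1832 bp/s
decade per filling   : 20.9 %
```

Almost half of the total exit time is spent in stochastic clogging pauses,
and the pause-excluded exit velocity rises exponentially as the capsid
empties — about one decade per 21% of filling, from ~200 bp/s at a full
capsid toward ~2 kb/s at 80% — recovering the generator's velocity law
through the complete measurement chain. The same bundle carries the binned
profile with bootstrap errors, the pause catalogue and per-bin pause
metrics, and the distribution fits (the pooled 90–95% duration tail here
gives a power-law exponent near 2.3).

The same stages are scriptable from the shell:

```sh
dnaexit simulate --n-events 39 --applied-force 5 --seed 1 --out ens5/
dnaexit analyze  --traces ens5/ --out res5/
dnaexit simulate --n-events 42 --applied-force 20 --seed 2 --out ens20/
dnaexit analyze  --traces ens20/ --out res20/
dnaexit fit-friction --lo res5/ --hi res20/ --out ptfit/
dnaexit pause-stats --pauses res5/pause_catalog.tsv --filling-range 90 95 --out fits/
```

`fit-friction` prints the overall monomer spacing d with its bootstrap
error and writes the per-bin d/μ table plus the velocity-ratio versus
force-ratio test that discriminates activated sliding friction from
hydrodynamic drag (PT-generated data give a velocity ratio ≈ 3.5 against
a force ratio ≈ 1.5 at full capsid).

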