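# Methods

`dnaexit` analyses force-clamp optical-tweezers recordings of DNA leaving a
bacteriophage phi29 capsid, and ships a calibrated forward model of such
recordings so that every analysis stage can be validated against known
ground truth. This note documents the models, the estimators, the numerical
choices, and what the synthetic data do and do not capture.

## Physical setting

After packaging, the phi29 capsid holds its 19.3 kb genome at near-crystalline
density. When the packaging motor releases its grip, internal confinement
force drives the DNA back out through the portal channel. In the measurement
a constant pulling force (5 or 20 pN) is clamped on the tether between two
trapped microspheres while the tether length grows as DNA exits; because
the motion is overdamped, the friction force opposing exit equals the total
driving force (internal force plus the applied clamp force) at all times.
The central physics question is the nature of that friction: hydrodynamic
drag predicts velocity proportional to force (v = μF), whereas thermally
activated sliding over a periodic potential of period d — the
Prandtl–Tomlinson picture of nanoscale friction — predicts

    F = (kT / d) · ln(v / μ),

with μ the mobility factor (the velocity at which activated friction
vanishes) and d expected near the 0.34 nm base-pair spacing for DNA–DNA
sliding. "ln" is the natural logarithm, the thermal-activation convention;
kT is computed from the CODATA Boltzmann constant at 296.15 K
(4.0888 pN·nm).

## Worm-like-chain length conversion (`elasticity`)

Tether contour length is inferred from extension and per-sample measured
force via the extensible Marko–Siggia interpolation with a self-consistent
enthalpic term, F = (kT/P)[1/(4(1−z)²) − ¼ + z], z = x/L − F/K. Defaults
are the literature-standard dsDNA constants P = 50 nm, K = 1200 pN,
rise 0.34 nm/bp; all exposed in `ElasticParams`. Inversions use bracketed
root finding (Brent for scalars, 80-step bisection for arrays — bisection
is branch-free and exactly vectorisable); forward and inverse agree to
better than 1e−6 pN over 0.1–60 pN. Above ~30 pN the measured fractional
extension legitimately exceeds 1 (enthalpic stretching past the B-form
contour); the entropic fraction z always stays in [0, 1).

## Synthetic force-clamp traces (`simulate`)

The generator's defaults are the study conditions; they are not free knobs.

* Velocity law: v(φ) = v100 · 10^((100−φ)/20) bp/s with v100 = 200 — one
  velocity decade per 20% of filling, anchoring ~200 bp/s at 100% filling
  and ~2000 bp/s at 80%. The 20 pN condition multiplies by the
  Prandtl–Tomlinson ratio exp(ΔF·d/kT) with d = 0.34 nm (×3.48); the high
  ionic-screening (Mg²⁺) condition halves velocities.
* Pause onsets: a Poisson process in exited length with hazard
  0.030/bp at 100% filling decaying with scale 7% filling, switched off
  below 50% filling. Mean onset spacing near a full capsid is ~33 bp.
* Pause durations: Pareto (density exponent α = 2.3) above a cutoff
  x_min(φ) = 0.09 s · exp(−(100−φ)/15%). The hazard 0.030/bp was derived
  analytically so that expected paused time (∫λ·⟨dur⟩ dx ≈ 10.8 s) over
  expected moving time (8.2 s, the closed-form integral of the velocity
  law to the tracking cap) puts the paused fraction near 0.57; the test
  suite keeps this derivation as an executable oracle.
* Heterogeneity: one lognormal velocity multiplier per event, mean one,
  log-SD 0.6, reproducing the order-of-magnitude spread of exit times
  without biasing ensemble-mean velocities.
* Instrumentation: 1 kHz sampling; 0.3 pN rms clamp jitter (extension and
  force are generated consistently sample by sample, as a feedback clamp
  records them); 3 nm rms extension noise; 0.5 nm/s drift; a 12 kb/s
  tracking cap terminating each event.
* Reproducibility: each event draws from a counter-based substream
  (`SeedSequence(seed, spawn_key=(index,))`), so ensembles are
  byte-identical under a fixed seed and stable under resizing.

Between pauses the motion is deterministic, so segment times use the
closed form t = (c/ηv)(e^(−x₀/c) − e^(−x₁/c)), c = 3860/ln 10 bp.

What the generator does **not** emulate: motor chemistry, bead/trap
dynamics beyond Gaussian noise, slow non-linear drift, the rare transient
re-friction events at low filling, or any correlation between pauses and
local DNA conformation. Passing tests therefore validate the estimators
against this statistical model of the data, not against every artefact of
a real instrument.

### Two quantitative caveats the generator makes explicit

1. With the mean-one velocity multiplier η, pooled moving time across an
   ensemble scales with E[1/η] = e^{0.36} ≈ 1.43, so the *pooled* paused
   fraction is ≈ 0.47 rather than the per-event calibration value 0.57.
   In addition, α = 2.3 durations have infinite variance: at ~1500 pauses
   per ensemble the sample mean of durations sits ≈ 12% below its
   expectation at the median seed. Both effects are inherent to the stated
   conditions; the measured paused fraction of a 39-event ensemble is
   therefore typically 40–45%, and the package reports it as measured.
2. Pauses shorter than the duration resolution (below) remain embedded in
   the "movement" data, so measured pause-excluded velocities sit ~5–15%
   below the generator law, more at fillings where x_min has decayed and
   in the 20 pN condition (whose pauses are shorter, ×0.7, and whose
   movement is faster, ×3.48). This is a property of any finite-resolution
   measurement of this process, not of a particular estimator: analyses
   repeated with the generator's ground-truth pause schedule in place of
   the detector recover the law without bias.

## Velocities and profiles (`kinetics`)

Exited length is tether length minus its value at the start of the record;
filling is 100% minus exited length over the genome length (193 bp per
percent). Velocities are OLS slopes in 0.5 s sliding windows stepped by
0.1 s, each assigned the filling at its midpoint. Per-event profiles are
means in 5% filling bins ([low, high), top bin closed), a bin requiring
the event to traverse at least half of it; ensemble profiles average
per-event bin means across complexes, with standard errors from
bootstrapping whole events (1000 resamples).

Pause-excluded velocities are computed on the pause-excised series: the
detected pause intervals are deleted and the remaining samples stitched
onto a uniform clock. Because the tether does not advance during an
arrest, the stitched series is continuous and its windowed slopes measure
pure movement. (The alternative — keeping only windows wholly outside
pauses — returns nothing at high filling, where inter-pause movement lasts
~0.1–0.2 s against a 0.5 s window.)

The profile's exponential character is summarised by a log-linear fit of
log₁₀(bin mean) against bin-centre filling over 80–100%, reported as the
velocity extrapolated to 100% filling and the filling decrease per
velocity decade; a flat profile reports an infinite decade scale.

## Pause detection (`pauses`)

Change points are found on the length series block-averaged to 100 Hz with
a greedy Kalafut–Visscher-style BIC search for a piecewise-constant
Gaussian model: each step adds the split with the largest SSE reduction,
then re-optimises every boundary between its neighbours (relocation
sweep), and stops when the best addition no longer lowers
BIC = 2(k+1)·ln N + N·ln(SSE/N). Two acceptance rules are available:

* profiled variance (classic): the variance is re-estimated from the
  residual SSE each step. This is the default of `kv_changepoints` and the
  form checked against exhaustive BIC enumeration in the tests. On
  strongly accelerating traces it fails structurally: the exponential
  velocity rise leaves within-segment ramp SSE that inflates the variance
  estimate ~8-fold and masks 30 bp pause steps.
* known variance: with the noise SD σ supplied (robust median-absolute
  first-difference estimate, consistent with the control tethers), a split
  is accepted while its gain exceeds 2σ²ln N. Detection always uses this
  form.

Boundaries are then refined on the 1 kHz data by a continuous
piecewise-linear hinge fit (a two-mean split is biased into the moving
side at a ramp/plateau junction); refined boundary medians are within
~5 ms of truth on simulated events.

Classification compares each segment's velocity with static-control
statistics: a noise model built from control tethers gives the mean and SD
of OLS velocities over non-overlapping intervals for a grid of durations
(0.05–2 s; log-log interpolated, extrapolated below the grid with the
white-noise dt^−3/2 law). A segment is a pause when its slope lies within
n_sd = 2.5 control SDs of the control mean at its duration. The slope is
measured on a guarded interior (20% of the duration per side, 0.01–0.05 s)
with the threshold taken at the interior duration, which keeps a few
samples of boundary overhang from dominating. The multiplier 2.5 keeps
98.8% of true arrests; a literal 1-SD band would by construction reject
31.7% of them, since a true pause is statistically identical to a control
tether.

Post-processing applies the resolution rules: adjacent pauses at the same
tether level (within the length resolution, the 1-SD net-change noise at
the smallest calibrated interval) re-join — one plateau split by the
search stays one plateau; pauses separated by a net advance below the
length resolution merge; candidates shorter than 0.04 s are dropped; and a
candidate of duration dt only counts where the local moving velocity
(the larger of the windowed advance rate over un-paused time and the slope
of the nearest flanking movement segments) exceeds (n_sd + 1.5) control
SDs at the guarded duration. The last rule is the velocity-dependent
duration-resolution limit: where movement is slow, a short flat slice
cannot be told from a genuine arrest, and neither is claimed. Sensitivity
for inserted pauses of four times the minimum resolvable duration is
≥ 97%, falsely claimed pause time on default ensembles is below 1% of
detected pause time, and pooled detected pause time tracks the generator's
schedule to a few percent.

Per-bin metrics assign each pause to the bin of its onset filling:
frequency is pauses per kb exited within the bin (per event, averaged
across events with bootstrap SEs — the kb-normalised unit is recorded in
the results metadata), the paused-time fraction is pooled within the bin,
and mean durations are pooled over pauses. Mean detected duration at low
filling is censored upward (only long arrests remain resolvable there), so
the duration trend is reliable only above ~85% filling.

## Pause statistics (`pausestats`)

Inter-pause exited lengths are fit by a maximum-likelihood exponential
(rate = 1/mean) with the Kolmogorov–Smirnov distance reported. Durations
pooled over a filling window (default 90–95%) are fit by the standard
power-law tail procedure: candidate cutoffs are the unique observed values
(ties toward the smaller cutoff), the exponent above each candidate comes
from the continuous MLE α = 1 + n/Σln(xᵢ/x_min), and the selected cutoff
minimises the KS distance between tail data and fitted law;
SE(α) = (α−1)/√n_tail. An exponential fit of the same (shifted) tail is
reported alongside for model comparison, and a semiparametric bootstrap
goodness-of-fit p-value is available behind a flag (off by default; it
refits the tail per surrogate and costs reps × the fit time).

## Friction analysis (`friction`)

The internal-force curve is a monotone piecewise-linear interpolation of
(filling, force) knots; the defaults anchor 25 pN at 100% filling and
15 pN at 93% (so that the total driving force at 93% with the 5 pN clamp
is the measured ~20 pN), reach zero at 50%, and are fully exposed in
configuration and recorded in every output. Per shared filling bin,
d = kT·ln(v_hi/v_lo)/(F_hi − F_lo); the overall d is the unweighted mean
over bins in 80–100% (noise-inverted bins with d < 0 are kept in the
per-bin table but excluded from the mean, with the count reported);
uncertainty comes from bootstrapping events within each profile; and
μ = v_lo·exp(−F_lo·d/kT) per bin. The linear-mobility (hydrodynamic) test
reports per-bin velocity and total-force ratios and flags bins where the
velocity ratio exceeds the force ratio beyond its propagated bootstrap
error. Packaging friction is max(0, (kT/d)·ln(v_pack/μ)), clamped at zero
in the thermally assisted regime v_pack ≤ μ.

## Numerical and interface choices

* Analysis knobs live in `AnalysisConfig` (window 0.5 s, step 0.1 s, 5%
  bins, 1000 bootstrap resamples, 100 Hz detection, Δt grid 0.05–2 s,
  n_sd 2.5, 0.04 s pause floor, resolution margin 1.5); generator knobs in
  `SimConfig`. Every pipeline output carries a configuration hash.
* Traces are TSV (time_s, force_pN, extension_nm; gzip transparent);
  ensembles carry a JSON manifest; results are one JSON bundle per
  ensemble with TSV sidecars for tables. Malformed inputs fail with the
  file, line and offense named.
* The CLI (`dnaexit simulate|analyze|fit-friction|pause-stats`) is a thin
  layer over the library; exit codes are 0/2/3 for success/validation
  error/runtime error.
* Default problem sizes (39-event ensembles, 60 s controls, 1000
  bootstrap resamples) run the full pipeline in well under a minute.

## Known limitations

* The paused-time fraction and the short-duration end of the pause
  catalogue are resolution-limited, as quantified above; comparisons of
  headline numbers across conditions are reliable, absolute pause counts
  below ~0.1 s are not.
* The 20 pN condition sits closer to the resolution limit everywhere
  (faster movement, shorter pauses), so the end-to-end recovered monomer
  spacing is biased a few hundredths of a nanometre low; the noiseless
  round-trip fit is exact.
* The internal-force knots between the two anchored values are calibrated
  stand-ins, not measured values; any analysis sensitive to the absolute
  force scale should substitute a measured force–filling table.
* No drift correction beyond the control calibration; no Savitzky–Golay
  or state-space velocity estimation; no truncated-power-law or lognormal
  alternatives in the tail fits.
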