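"""Prandtl--Tomlinson sliding-friction analysis of paired force conditions.

During overdamped DNA exit the friction force equals the total driving
force F (internal capsid force plus the applied optical-trap force). The
Prandtl--Tomlinson (Frenkel--Kontorova) relationship for thermally
activated sliding over a periodic potential of period d reads

    F = (kT / d) ln(v / mu),

with mu the mobility factor (the velocity scale at which friction
vanishes) and the natural-log convention of the thermal-activation model.
Two velocity profiles at different applied forces give, per filling bin,

    d = kT ln(v_hi / v_lo) / (F_hi - F_lo),

and the overall d is the unweighted mean over bins; mu follows per bin as
mu = v_lo exp(-F_lo d / kT). The same relation predicts friction during
motor-driven packaging, which proceeds ~10-100x slower than ejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elasticity import thermal_energy
from .kinetics import VelocityProfile

#: Internal-force knots (filling %, force pN). Anchors: ~25 pN at the end
#: of packaging and ~15 pN internal at 93% (20 pN total friction minus the
#: 5 pN applied force); intermediate knots are smooth calibrated defaults.
DEFAULT_FORCE_KNOTS = (
    (0.0, 0.0), (50.0, 0.0), (70.0, 3.0), (80.0, 10.0),
    (90.0, 14.0), (93.0, 15.0), (97.0, 20.0), (100.0, 25.0),
)


@dataclass(frozen=True)
class ForceFillingCurve:
    """Monotone piecewise-linear internal force versus capsid filling."""

    knots: tuple = DEFAULT_FORCE_KNOTS

    def __post_init__(self) -> None:
        fill = [k[0] for k in self.knots]
        force = [k[1] for k in self.knots]
        if any(b <= a for a, b in zip(fill, fill[1:])):
            raise ValueError("knot fillings must be strictly increasing")
        if any(b < a for a, b in zip(force, force[1:])):
            raise ValueError("internal force must be non-decreasing in filling")

    @property
    def _xy(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.knots, dtype=float)
        return arr[:, 0], arr[:, 1]


def internal_force(filling, curve: ForceFillingCurve | None = None):
    """Internal (confinement) force in pN at a filling in % by interpolation."""
    curve = curve or ForceFillingCurve()
    x, y = curve._xy
    arr = np.asarray(filling, dtype=float)
    if np.any(arr < x[0]) or np.any(arr > x[-1]):
        raise ValueError("filling outside the force-curve knot range")
    out = np.interp(arr, x, y)
    return float(out) if out.ndim == 0 else out


def total_driving_force(filling, applied: float,
                        curve: ForceFillingCurve | None = None):
    """Internal force plus the applied pulling force (pN)."""
    if applied < 0:
        raise ValueError("applied force must be >= 0")
    out = np.asarray(internal_force(filling, curve)) + applied
    return float(out) if out.ndim == 0 else out


def pt_predicted_ratio(delta_force: float, d: float,
                       temperature: float = 296.15) -> float:
    """Velocity ratio exp(dF * d / kT) predicted for a force increase dF."""
    if d <= 0:
        raise ValueError("monomer spacing d must be positive")
    return math.exp(delta_force * d / thermal_energy(temperature))


@dataclass
class PTFitResult:
    """Per-bin and overall Prandtl--Tomlinson parameters."""

    bin_centers: np.ndarray
    d_per_bin: np.ndarray            # nm (may contain negatives in noise)
    d_overall: float                 # nm, unweighted mean of non-negative bins
    d_se: float                      # nm, bootstrap over events (nan if absent)
    mu_per_bin: np.ndarray           # bp/s
    temperature: float
    force_lo: np.ndarray = field(default=None, repr=False)
    force_hi: np.ndarray = field(default=None, repr=False)
    n_negative_bins: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "filling_pct": self.bin_centers,
            "d_nm": self.d_per_bin,
            "mu_bp_s": self.mu_per_bin,
            "force_lo_pN": self.force_lo,
            "force_hi_pN": self.force_hi,
        })


def _shared_bins(profile_lo: VelocityProfile, profile_hi: VelocityProfile,
                 fit_range: tuple[float, float]):
    lo_idx = {c: i for i, c in enumerate(profile_lo.bin_centers)}
    hi_idx = {c: i for i, c in enumerate(profile_hi.bin_centers)}
    shared = sorted(set(lo_idx) & set(hi_idx))
    shared = [c for c in shared if fit_range[0] <= c <= fit_range[1]
              and np.isfinite(profile_lo.mean_velocity[lo_idx[c]])
              and np.isfinite(profile_hi.mean_velocity[hi_idx[c]])]
    if not shared:
        raise ValueError("profiles share no populated bins in the fit range")
    return shared, lo_idx, hi_idx


def _d_from_bins(v_lo, v_hi, f_lo, f_hi, kT):
    if np.any(v_lo <= 0) or np.any(v_hi <= 0):
        raise ValueError("velocities must be positive for the PT fit")
    if np.any(f_hi == f_lo):
        raise ValueError("equal total forces; d is undefined")
    return kT * np.log(v_hi / v_lo) / (f_hi - f_lo)


def fit_d_per_bin(profile_lo: VelocityProfile, applied_lo: float,
                  profile_hi: VelocityProfile, applied_hi: float,
                  curve: ForceFillingCurve | None = None,
                  temperature: float = 296.15,
                  fit_range: tuple[float, float] = (80.0, 100.0),
                  bootstrap_reps: int = 1000,
                  seed: int | None = 0) -> PTFitResult:
    """Fit the PT relationship per shared filling bin.

    d_overall is the unweighted mean over bins; bins with a negative fitted
    d (velocity ratio inverted by noise) are retained in d_per_bin but
    excluded from the mean. The SE comes from bootstrapping events within
    each profile when per-event tables are attached, otherwise it is NaN.
    mu per bin uses d_overall and the low-force total driving force.
    """
    curve = curve or ForceFillingCurve()
    kT = thermal_energy(temperature)
    shared, lo_idx, hi_idx = _shared_bins(profile_lo, profile_hi, fit_range)
    centers = np.asarray(shared, dtype=float)
    v_lo = np.array([profile_lo.mean_velocity[lo_idx[c]] for c in shared])
    v_hi = np.array([profile_hi.mean_velocity[hi_idx[c]] for c in shared])
    f_lo = total_driving_force(centers, applied_lo, curve)
    f_hi = total_driving_force(centers, applied_hi, curve)
    d_bins = _d_from_bins(v_lo, v_hi, f_lo, f_hi, kT)
    keep = d_bins >= 0
    d_overall = float(d_bins[keep].mean()) if keep.any() else float("nan")
    mu = v_lo * np.exp(-f_lo * d_overall / kT)

    d_se = float("nan")
    if profile_lo.per_event is not None and profile_hi.per_event is not None:
        rng = np.random.default_rng(seed)
        tab_lo = profile_lo.per_event.reindex(centers)
        tab_hi = profile_hi.per_event.reindex(centers)
        n_lo, n_hi = tab_lo.shape[1], tab_hi.shape[1]
        boots = []
        for _ in range(bootstrap_reps):
            m_lo = np.nanmean(tab_lo.to_numpy()[:, rng.integers(0, n_lo, n_lo)], axis=1)
            m_hi = np.nanmean(tab_hi.to_numpy()[:, rng.integers(0, n_hi, n_hi)], axis=1)
            ok = (m_lo > 0) & (m_hi > 0) & np.isfinite(m_lo) & np.isfinite(m_hi)
            if not ok.any():
                continue
            db = kT * np.log(m_hi[ok] / m_lo[ok]) / (f_hi[ok] - f_lo[ok])
            db = db[db >= 0]
            if db.size:
                boots.append(db.mean())
        if len(boots) > 1:
            d_se = float(np.std(boots, ddof=0))

    return PTFitResult(
        bin_centers=centers, d_per_bin=d_bins, d_overall=d_overall, d_se=d_se,
        mu_per_bin=mu, temperature=temperature, force_lo=f_lo, force_hi=f_hi,
        n_negative_bins=int((~keep).sum()),
    )


def linear_mobility_test(profile_lo: VelocityProfile, applied_lo: float,
                         profile_hi: VelocityProfile, applied_hi: float,
                         curve: ForceFillingCurve | None = None,
                         fit_range: tuple[float, float] = (80.0, 100.0)
                         ) -> pd.DataFrame:
    """Velocity ratio versus total-force ratio per shared bin.

    Under the hydrodynamic-drag (linear mobility) model v = mu F, the two
    ratios are equal; the linear model is rejected in a bin when the
    velocity ratio exceeds the force ratio by more than the propagated
    bootstrap error of the velocity ratio.
    """
    curve = curve or ForceFillingCurve()
    shared, lo_idx, hi_idx = _shared_bins(profile_lo, profile_hi, fit_range)
    centers = np.asarray(shared, dtype=float)
    v_lo = np.array([profile_lo.mean_velocity[lo_idx[c]] for c in shared])
    v_hi = np.array([profile_hi.mean_velocity[hi_idx[c]] for c in shared])
    if np.any(v_lo == 0):
        raise ValueError("zero low-force velocity; ratio undefined")
    se_lo = np.array([profile_lo.se[lo_idx[c]] for c in shared])
    se_hi = np.array([profile_hi.se[hi_idx[c]] for c in shared])
    f_lo = total_driving_force(centers, applied_lo, curve)
    f_hi = total_driving_force(centers, applied_hi, curve)
    if np.any(f_lo == 0):
        raise ValueError("zero total driving force; ratio undefined")
    v_ratio = v_hi / v_lo
    ratio_se = v_ratio * np.sqrt((se_lo / v_lo) ** 2 + (se_hi / v_hi) ** 2)
    f_ratio = f_hi / f_lo
    return pd.DataFrame({
        "filling_pct": centers,
        "velocity_ratio": v_ratio,
        "velocity_ratio_se": ratio_se,
        "force_ratio": f_ratio,
        "linear_model_rejected": v_ratio - ratio_se > f_ratio,
    })


def mobility_from_velocity_law(filling, velocity, applied: float,
                               d: float = 0.34,
                               curve: ForceFillingCurve | None = None,
                               temperature: float = 296.15):
    """PT mobility mu implied by a velocity law at a given applied force."""
    kT = thermal_energy(temperature)
    f_tot = np.asarray(total_driving_force(filling, applied, curve))
    out = np.asarray(velocity, dtype=float) * np.exp(-f_tot * d / kT)
    return float(out) if out.ndim == 0 else out


def packaging_friction(v_pack: float, mu: float, d: float = 0.34,
                       temperature: float = 296.15) -> float:
    """PT friction force (pN) at packaging velocity v_pack given mobility mu.

    Clamped at zero for v_pack <= mu (thermally assisted sliding regime).
    """
    if v_pack <= 0 or mu <= 0:
        raise ValueError("v_pack and mu must be positive")
    kT = thermal_energy(temperature)
    return max(0.0, (kT / d) * math.log(v_pack / mu))


def packaging_friction_profile(fit: PTFitResult, v_pack: float,
                               filling: float, d: float | None = None) -> float:
    """Friction at packaging velocity using the fitted mu of the bin
    containing `filling`. Raises if no fitted bin covers it."""
    half = np.min(np.diff(fit.bin_centers)) / 2 if len(fit.bin_centers) > 1 else 2.5
    sel = np.abs(fit.bin_centers - filling) <= half + 1e-9
    if not sel.any():
        raise ValueError(f"no fitted mobility for filling {filling}%")
    mu = float(fit.mu_per_bin[sel][np.argmin(np.abs(fit.bin_centers[sel] - filling))])
    return packaging_friction(v_pack, mu, d or fit_d_default(fit), fit.temperature)


def fit_d_default(fit: PTFitResult) -> float:
    return fit.d_overall if np.isfinite(fit.d_overall) else 0.34
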