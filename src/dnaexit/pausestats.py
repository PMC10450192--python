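"""Distributional analysis of clogging pauses.

Inter-pause exited lengths are tested against an exponential law (Poisson
onset process), and pause durations against a heavy power-law tail using
the Clauset--Shalizi--Newman procedure: the tail cutoff xmin is chosen to
minimise the Kolmogorov--Smirnov distance between the tail data and the
fitted power law, and the exponent follows from the continuous maximum-
likelihood estimator

    alpha = 1 + n_tail / sum(ln(x_i / xmin)),  x_i >= xmin,

with standard error (alpha - 1)/sqrt(n_tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ExponentialFit:
    """MLE exponential fit: rate = 1/mean."""

    rate: float
    n: int
    ks_distance: float


@dataclass
class PowerLawFit:
    """CSN power-law tail fit of a positive sample."""

    alpha: float
    xmin: float
    n_tail: int
    ks_distance: float
    alpha_se: float
    ks_exponential_tail: float = float("nan")
    powerlaw_preferred: bool = True


def _validate_positive(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("values must be positive finite reals")
    return arr


def fit_exponential(values) -> ExponentialFit:
    """Maximum-likelihood exponential fit with KS distance."""
    arr = _validate_positive(values)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    rate = 1.0 / arr.mean()
    x = np.sort(arr)
    cdf = 1.0 - np.exp(-rate * x)
    n = x.size
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    ks = float(np.max(np.maximum(np.abs(emp_hi - cdf), np.abs(emp_lo - cdf))))
    return ExponentialFit(rate=float(rate), n=int(n), ks_distance=ks)


def ccdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical survival function P(T > t) at the sorted sample points.

    Right-continuous; the largest observation is reported at 1/n (the
    just-below-max convention) so the curve is usable on log axes.
    """
    arr = np.sort(_validate_positive(values))
    n = arr.size
    surv = 1.0 - np.arange(1, n + 1) / n
    surv[-1] = 1.0 / n
    return arr, surv


def alpha_mle(values, xmin: float) -> float:
    """Continuous power-law exponent MLE for the tail x >= xmin."""
    arr = _validate_positive(values)
    tail = arr[arr >= xmin]
    if tail.size < 10:
        raise ValueError("need at least 10 tail values at xmin")
    log_sum = float(np.sum(np.log(tail / xmin)))
    if log_sum <= 0:
        raise ValueError("all tail values equal xmin; exponent diverges")
    return 1.0 + tail.size / log_sum


def _ks_powerlaw(tail: np.ndarray, xmin: float, alpha: float) -> float:
    x = np.sort(tail)
    cdf = 1.0 - (x / xmin) ** (1.0 - alpha)
    n = x.size
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(np.max(np.maximum(np.abs(emp_hi - cdf), np.abs(emp_lo - cdf))))


def csn_powerlaw_fit(values, min_tail: int = 10) -> PowerLawFit:
    """Power-law tail fit with xmin selected by KS minimisation.

    Candidate xmin values are the unique observations (ties broken toward
    the smaller xmin, i.e. the larger tail). Also fits an exponential to
    the selected tail (shifted to xmin) and flags which model has the
    smaller KS distance.
    """
    arr = _validate_positive(values)
    if arr.size < 50:
        raise ValueError("need at least 50 values for a tail fit")
    xs = np.sort(arr)
    candidates = np.unique(xs)
    # Drop candidates leaving fewer than min_tail points in the tail.
    n_tail_at = xs.size - np.searchsorted(xs, candidates, side="left")
    candidates = candidates[n_tail_at >= min_tail]
    if candidates.size == 0:
        raise ValueError("no candidate xmin leaves enough tail points")
    best = None
    for xmin in candidates:
        tail = xs[xs >= xmin]
        log_sum = float(np.sum(np.log(tail / xmin)))
        if log_sum <= 0:
            continue
        alpha = 1.0 + tail.size / log_sum
        ks = _ks_powerlaw(tail, xmin, alpha)
        if best is None or ks < best[0] - 1e-15:
            best = (ks, float(xmin), float(alpha), tail.size)
    if best is None:
        raise ValueError("degenerate sample; no power-law fit possible")
    ks, xmin, alpha, n_tail = best
    tail = xs[xs >= xmin]
    # Exponential comparison on the same tail (shifted support at xmin).
    shifted = tail - xmin + 1e-300
    rate = 1.0 / max(shifted.mean(), 1e-300)
    cdf = 1.0 - np.exp(-rate * np.sort(shifted))
    n = tail.size
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    ks_exp = float(np.max(np.maximum(np.abs(emp_hi - cdf), np.abs(emp_lo - cdf))))
    return PowerLawFit(
        alpha=alpha, xmin=xmin, n_tail=int(n_tail), ks_distance=ks,
        alpha_se=(alpha - 1.0) / np.sqrt(n_tail),
        ks_exponential_tail=ks_exp,
        powerlaw_preferred=bool(ks < ks_exp),
    )


def bootstrap_pvalue(values, fit: PowerLawFit, reps: int = 100,
                     seed: int | None = 0) -> float:
    """Semiparametric goodness-of-fit p-value (CSN bootstrap).

    Costly; off by default in the pipeline. Surrogates keep the sub-xmin
    body (resampled empirically) and draw the tail from the fitted law.
    """
    arr = _validate_positive(values)
    rng = np.random.default_rng(seed)
    body = arr[arr < fit.xmin]
    p_tail = fit.n_tail / arr.size
    worse = 0
    for _ in range(reps):
        n_t = rng.binomial(arr.size, p_tail)
        tail = fit.xmin * rng.uniform(size=n_t) ** (-1.0 / (fit.alpha - 1.0))
        if body.size and arr.size - n_t > 0:
            synth = np.concatenate([rng.choice(body, size=arr.size - n_t), tail])
        else:
            synth = tail
        try:
            refit = csn_powerlaw_fit(synth)
        except ValueError:
            continue
        if refit.ks_distance >= fit.ks_distance:
            worse += 1
    return worse / reps


def interpause_lengths(pauses) -> np.ndarray:
    """Exited lengths of DNA released between consecutive pauses (bp)."""
    xs = sorted(p.exited_length_at_onset for p in pauses)
    return np.diff(np.asarray(xs, dtype=float))
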