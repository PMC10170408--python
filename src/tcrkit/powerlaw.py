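"""Discrete power-law fitting and bootstrap goodness-of-fit for degree data.

Implements the standard maximum-likelihood recipe for a discrete power law

    P(X = k) = k^(-alpha) / zeta(alpha, xmin),    k = xmin, xmin+1, ...

with the lower cutoff xmin chosen to minimise the Kolmogorov-Smirnov
distance between the fitted model and the empirical tail, and a
semiparametric bootstrap goodness-of-fit test: synthetic samples are drawn
from the fitted model above xmin (and resampled from the empirical data
below it), each is refitted from scratch, and the p-value is the fraction of
synthetic KS distances at least as large as the observed one.  A p-value
above 0.1 is conventionally taken as "plausibly power law".

Zero degrees are excluded from the fit sample (the discrete power law has
support k >= 1); callers should still count isolated nodes when reporting
network-level quantities.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

PLAUSIBILITY_THRESHOLD = 0.1
MIN_TAIL = 10          # smallest tail size an xmin candidate may leave
MIN_SAMPLE = 50        # smallest usable fit sample (positive degrees)
MAX_XMIN_CANDIDATES = 30

_ALPHA_BOUNDS = (1.01, 8.0)


class DegenerateDistributionError(ValueError):
    """All values identical: no distribution to fit."""


class InsufficientDataError(ValueError):
    """Too few positive values to fit."""


@dataclass(frozen=True)
class PowerLawFit:
    """A fitted discrete power law with its bootstrap goodness of fit."""

    xmin: int
    alpha: float
    ks: float
    gof_p: float
    n_boot: int
    n_tail: int
    plausible: bool


def _prepare(values) -> np.ndarray:
    x = np.asarray(values)
    x = x[x >= 1].astype(np.int64)
    if x.size < MIN_SAMPLE:
        raise InsufficientDataError(
            f"need at least {MIN_SAMPLE} positive values, got {x.size}"
        )
    if np.unique(x).size == 1:
        raise DegenerateDistributionError("all positive values identical")
    return x


def _alpha_mle(tail: np.ndarray, xmin: int) -> float:
    """Maximise the discrete power-law log-likelihood over alpha.

    The closed-form continuous approximation
    alpha ~ 1 + n / sum(log(x / (xmin - 1/2))) brackets the search; the exact
    discrete MLE is then found numerically within that bracket.
    """
    n = tail.size
    slogx = np.log(tail).sum()
    approx = 1.0 + n / max(slogx - n * np.log(xmin - 0.5), 1e-9)
    lo = max(_ALPHA_BOUNDS[0], approx - 1.5)
    hi = min(_ALPHA_BOUNDS[1], approx + 1.5)
    if hi <= lo:
        lo, hi = _ALPHA_BOUNDS

    def nll(alpha: float) -> float:
        return n * np.log(zeta(alpha, xmin)) + alpha * slogx

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4})
    # guard against a bracket that clipped the optimum
    if res.x > hi - 1e-3 or res.x < lo + 1e-3:
        res = minimize_scalar(nll, bounds=_ALPHA_BOUNDS, method="bounded", options={"xatol": 1e-4})
    return float(res.x)


def _model_cdf(k: np.ndarray, alpha: float, xmin: int) -> np.ndarray:
    """P(X <= k) for the discrete power law with support starting at xmin."""
    return 1.0 - zeta(alpha, np.asarray(k, dtype=float) + 1.0) / zeta(alpha, xmin)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    # both CDFs are right-continuous step functions jumping at the same
    # integer atoms, so the supremum is attained at an observed value
    vals, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / tail.size
    model = _model_cdf(vals, alpha, xmin)
    return float(np.max(np.abs(ecdf - model)))


def fit_discrete_powerlaw(values, xmin: int | None = None) -> tuple[float, int, float]:
    """MLE fit; returns (alpha, xmin, ks).

    When ``xmin`` is None it is scanned over the unique observed values
    (smallest :data:`MAX_XMIN_CANDIDATES` of them, each leaving a tail of at
    least :data:`MIN_TAIL` points) and the KS-minimising cutoff is kept.
    """
    x = _prepare(values)
    if xmin is not None:
        tail = x[x >= xmin]
        if tail.size < MIN_TAIL:
            raise InsufficientDataError(f"tail above xmin={xmin} has {tail.size} points")
        alpha = _alpha_mle(tail, xmin)
        return alpha, int(xmin), _ks_distance(tail, alpha, xmin)
    candidates = np.unique(x)
    candidates = candidates[candidates <= np.sort(x)[-MIN_TAIL]]
    if candidates.size > MAX_XMIN_CANDIDATES:
        # quantile-spaced subset of the sorted unique values (always keeping
        # the smallest); applied identically to observed and bootstrap fits
        idx = np.unique(
            np.linspace(0, candidates.size - 1, MAX_XMIN_CANDIDATES).astype(int)
        )
        candidates = candidates[idx]
    best: tuple[float, int, float] | None = None
    for xm in candidates:
        tail = x[x >= xm]
        if tail.size < MIN_TAIL or np.unique(tail).size == 1:
            continue
        alpha = _alpha_mle(tail, int(xm))
        ks = _ks_distance(tail, alpha, int(xm))
        if best is None or ks < best[2]:
            best = (alpha, int(xm), ks)
    if best is None:
        raise InsufficientDataError("no viable xmin candidate")
    return best


def sample_discrete_powerlaw(
    alpha: float, xmin: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sampling.

    The support is tabulated up to the point where the remaining tail mass
    falls below 1e-9 (hard cap 4e6); the negligible residual mass is lumped
    into the last tabulated value.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    cdf = _cdf_table(round(float(alpha), 9), int(xmin))
    u = rng.random(size)
    idx = np.searchsorted(cdf, u, side="right")
    return (xmin + np.minimum(idx, cdf.size - 1)).astype(np.int64)


@lru_cache(maxsize=16)
def _cdf_table(alpha: float, xmin: int) -> np.ndarray:
    hi = xmin + 1000
    z = zeta(alpha, xmin)
    while zeta(alpha, hi) / z > 1e-9 and hi < 4 * 10**6:
        hi *= 4
    ks = np.arange(xmin, hi, dtype=float)
    return np.cumsum(ks ** (-alpha) / z)


def powerlaw_gof(
    degrees,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    xmin: int | None = None,
) -> PowerLawFit:
    """Fit a discrete power law to positive degrees and bootstrap its GOF.

    Parameters
    ----------
    degrees
        Node degrees; zeros are dropped before fitting.
    n_boot
        Bootstrap replicates; 1000 gives p-value resolution 0.001, 200 is
        adequate for screening.
    seed
        Seed or Generator for the bootstrap.
    xmin
        Fix the cutoff instead of scanning (the scan is the default).
    """
    x = _prepare(degrees)
    alpha, xm, ks_obs = fit_discrete_powerlaw(x, xmin=xmin)
    rng = np.random.default_rng(seed)
    below = x[x < xm]
    n_tail = int((x >= xm).sum())
    p_tail = n_tail / x.size
    exceed = 0
    for _ in range(n_boot):
        take_tail = rng.random(x.size) < p_tail
        n_t = x.size if below.size == 0 else int(take_tail.sum())
        parts = []
        if n_t:
            parts.append(sample_discrete_powerlaw(alpha, xm, n_t, rng))
        if x.size - n_t:
            parts.append(rng.choice(below, size=x.size - n_t, replace=True))
        synth = np.concatenate(parts)
        try:
            _, _, ks_i = fit_discrete_powerlaw(synth, xmin=xmin)
        except (InsufficientDataError, DegenerateDistributionError):
            continue
        if ks_i >= ks_obs:
            exceed += 1
    gof_p = exceed / n_boot if n_boot > 0 else float("nan")
    return PowerLawFit(
        xmin=xm,
        alpha=alpha,
        ks=ks_obs,
        gof_p=gof_p,
        n_boot=n_boot,
        n_tail=n_tail,
        plausible=gof_p > PLAUSIBILITY_THRESHOLD,
    )
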