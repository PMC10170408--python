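"""Hill diversity and evenness profiles and the evenness-AUC clonality index.

The Hill diversity of order q of a clone frequency vector p is

    D(q) = (sum_i p_i^q)^(1/(1-q)),     D(1) = exp(-sum_i p_i ln p_i),

the "effective number" of equally abundant clones.  q = 0 gives observed
richness (SR), q = 1 the exponential Shannon entropy and q = 2 the inverse
Simpson index; increasing q weights abundant clones more heavily.  The
evenness profile E(q) = D(q)/SR removes the sampling-depth dependence of
richness, and the clonality index

    clonality = 10 - AUC(E(q), q in [0, 10])

(composite Simpson's rule on an even q-grid) summarises how far the
repertoire departs from perfect evenness: 0 for a uniform repertoire,
approaching 10 for an extremely oligoclonal one.

A strictly monoclonal repertoire (SR = 1) has E == 1 and therefore
clonality 0, indistinguishable from a perfectly even repertoire under the
richness normalisation; such samples are flagged with a warning.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

#: default diversity-order grid: q = 0 to 10 in steps of 0.2 (51 points)
DEFAULT_Q_GRID = np.round(np.arange(0.0, 10.0 + 1e-9, 0.2), 10)

_Q_ONE_TOL = 1e-12


class DiversityError(ValueError):
    pass


@dataclass(frozen=True)
class DiversityProfile:
    """Hill diversity/evenness on a q-grid plus the clonality index."""

    q_grid: np.ndarray
    D: np.ndarray
    E: np.ndarray
    SR: float
    clonality: float


def _validate_frequencies(frequencies) -> np.ndarray:
    p = np.asarray(frequencies, dtype=float)
    if p.size == 0:
        raise DiversityError("frequency vector is empty")
    if np.any(p <= 0):
        raise DiversityError("all frequencies must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DiversityError(f"frequencies must sum to 1, got {p.sum()!r}")
    return p


def hill_diversity(frequencies, q_grid=DEFAULT_Q_GRID) -> np.ndarray:
    """D(q) for every q on the grid.

    Evaluated in log space for numerical stability; q within 1e-12 of 1 is
    computed as the Shannon limit exp(H).
    """
    p = _validate_frequencies(frequencies)
    q = np.asarray(q_grid, dtype=float)
    logp = np.log(p)
    shannon = -np.sum(p * logp)
    D = np.empty_like(q)
    near_one = np.abs(q - 1.0) < _Q_ONE_TOL
    D[near_one] = np.exp(shannon)
    for i in np.flatnonzero(~near_one):
        # log sum_i p^q via logsumexp to survive tiny p at large q
        lse = _logsumexp(q[i] * logp)
        D[i] = np.exp(lse / (1.0 - q[i]))
    return D


def _logsumexp(a: np.ndarray) -> float:
    m = a.max()
    return m + np.log(np.exp(a - m).sum())


def evenness_profile(D: np.ndarray, SR: float) -> np.ndarray:
    """E(q) = D(q)/SR; E(0) is exactly 1 by construction."""
    if SR <= 0:
        raise DiversityError("SR must be positive")
    E = np.asarray(D, dtype=float) / SR
    E[0] = 1.0
    return E


def clonality_index(E: np.ndarray, q_grid=DEFAULT_Q_GRID) -> float:
    """10 minus the Simpson's-rule area under the evenness profile.

    Requires an evenly spaced grid with at least 3 points (an even number of
    intervals for composite Simpson).
    """
    q = np.asarray(q_grid, dtype=float)
    if q.size < 3:
        raise DiversityError("q_grid must have at least 3 points")
    steps = np.diff(q)
    if not np.allclose(steps, steps[0]):
        raise DiversityError("q_grid must be evenly spaced")
    auc = simpson(np.asarray(E, dtype=float), x=q)
    return float(q[-1] - auc)


def diversity_profile(counts, q_grid=DEFAULT_Q_GRID) -> DiversityProfile:
    """Full profile from raw (template) counts of one repertoire.

    Frequencies are template proportions of productive clonotypes; the
    profile is scale-invariant in the counts.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise DiversityError("empty count vector")
    if np.any(c <= 0):
        raise DiversityError("counts must be positive")
    if c.size == 1:
        warnings.warn(
            "monoclonal repertoire (SR = 1): clonality is 0 by definition "
            "and not comparable with polyclonal samples",
            stacklevel=2,
        )
    p = c / c.sum()
    q = np.asarray(q_grid, dtype=float)
    D = hill_diversity(p, q)
    SR = float(D[0])
    E = evenness_profile(D, SR)
    return DiversityProfile(q_grid=q, D=D, E=E, SR=SR, clonality=clonality_index(E, q))
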