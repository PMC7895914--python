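"""Dichotomizing the information system and the stability of the coarse policy.

Coarsening replaces the continuous signal ``p ~ f(p)`` by a two-valued signal:
"high" when ``p >= T`` and "low" otherwise.  By Bayes' rule the two signals
appear with probabilities ``q_H = 1 - F(T)`` and ``q_L = F(T)`` and induce
posteriors

    p_H = PE(T) / q_H        (mean posterior above the threshold)
    p_L = (E(p) - PE(T)) / q_L

The central stability result: under the coarse information system, the
symmetric policy "treat only high-signal patients at every effectiveness
state" is a Markov perfect equilibrium of the prescription game if and only if

    h(T) = p_H - p_L >= E(p),

i.e. the spread between the two induced posteriors is at least the prevalence
of bacterial infection.  Remarkably this involves only the information system,
not the utilities, the depletion rate or the horizon.  ``stability_gap``
returns ``h(T) - E(p)``; ``min_stable_threshold`` locates the infimum of the
stable set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_models import SignalDistribution

__all__ = [
    "CoarseSignal",
    "coarsen",
    "stability_gap",
    "min_stable_threshold",
    "threshold_profile",
]

#: Grid step for the coarse scan in ``min_stable_threshold``.
_SCAN_STEP = 1e-3


class DegenerateThresholdError(ValueError):
    """Raised when F(T) in {0, 1}: one of the two signals never occurs."""


@dataclass(frozen=True)
class CoarseSignal:
    """The dichotomous information system induced by threshold ``T``.

    Satisfies ``q_H + q_L = 1`` and the total-expectation identity
    ``q_H p_H + q_L p_L = E(p)``; also ``p_L <= T <= p_H``.
    """

    T: float
    q_H: float
    q_L: float
    p_H: float
    p_L: float

    @property
    def h(self) -> float:
        """Posterior spread p_H - p_L."""
        return self.p_H - self.p_L


def coarsen(dist: SignalDistribution, T: float) -> CoarseSignal:
    """Dichotomize ``dist`` at threshold ``T`` (requires 0 < F(T) < 1)."""
    F = float(dist.cdf(T))
    sf = float(dist.sf(T))
    if F <= 0.0 or sf <= 0.0:
        raise DegenerateThresholdError(
            f"F({T}) = {F}: both signals must occur with positive probability")
    pe = float(dist.partial_mean(T))
    lpe = float(dist.lower_partial_mean(T))
    return CoarseSignal(T=float(T), q_H=sf, q_L=F, p_H=pe / sf, p_L=lpe / F)


def stability_gap(dist: SignalDistribution, T: float) -> float:
    """h(T) - E(p); nonnegative iff 'treat high-signal only' is an MPE."""
    cs = coarsen(dist, T)
    return cs.h - dist.mean


def _gap_vector(dist: SignalDistribution, T: np.ndarray) -> np.ndarray:
    """Vectorized stability gap on an interior grid.

    Degenerate points (F in {0, 1} to machine precision) come out NaN and
    thus compare as unstable.
    """
    F = np.asarray(dist.cdf(T), dtype=float)
    sf = np.asarray(dist.sf(T), dtype=float)
    pe = np.asarray(dist.partial_mean(T), dtype=float)
    lpe = np.asarray(dist.lower_partial_mean(T), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_H = np.where(sf > 0.0, pe / sf, np.nan)
        p_L = np.where(F > 0.0, lpe / F, np.nan)
    return p_H - p_L - dist.mean


def min_stable_threshold(dist: SignalDistribution, tol: float = 1e-6):
    """Infimum of thresholds satisfying the stability condition, or ``None``.

    Scans a grid of step 1e-3 over (0, support_max) for ``gap(T) >= -tol``,
    then refines the left edge of the stable set by bisection to ``tol``.
    Returns ``None`` when no grid point is stable.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    hi = dist.support_max
    grid = np.arange(_SCAN_STEP, hi, _SCAN_STEP)
    grid = grid[(np.asarray(dist.cdf(grid)) > 0.0) & (np.asarray(dist.sf(grid)) > 0.0)]
    if grid.size == 0:
        return None
    stable = _gap_vector(dist, grid) >= -tol
    if not stable.any():
        return None
    first = int(np.argmax(stable))
    t_hi = grid[first]
    t_lo = grid[first - 1] if first > 0 else 0.0
    # bisect the left boundary of the stable set down to tol
    while t_hi - t_lo > tol:
        mid = 0.5 * (t_lo + t_hi)
        if float(dist.cdf(mid)) > 0.0 and float(dist.sf(mid)) > 0.0 \
                and stability_gap(dist, mid) >= -tol:
            t_hi = mid
        else:
            t_lo = mid
    return float(t_hi) if t_hi > tol else 0.0


def stable_intervals(dist: SignalDistribution, tol: float = 1e-6,
                     step: float = _SCAN_STEP) -> list[tuple[float, float]]:
    """Maximal grid intervals on which the stability condition holds.

    The stable set need not be convex for unusual densities; this reports it
    at grid resolution ``step``.
    """
    grid = np.arange(step, dist.support_max, step)
    grid = grid[(np.asarray(dist.cdf(grid)) > 0.0) & (np.asarray(dist.sf(grid)) > 0.0)]
    if grid.size == 0:
        return []
    stable = _gap_vector(dist, grid) >= -tol
    out, start = [], None
    for t, s in zip(grid, stable):
        if s and start is None:
            start = t
        elif not s and start is not None:
            out.append((float(start), float(prev)))
            start = None
        prev = t
    if start is not None:
        out.append((float(start), float(grid[-1])))
    return out


def threshold_profile(dist: SignalDistribution, grid) -> pd.DataFrame:
    """Tabulate the coarsening quantities over a grid of thresholds.

    Columns: ``T, q_H, p_H, p_L, h, E_p, gap, stable`` — the data behind the
    threshold-range panels (posterior spread vs. prevalence as T varies).
    """
    grid = np.asarray(grid, dtype=float)
    F = np.asarray(dist.cdf(grid), dtype=float)
    sf = np.asarray(dist.sf(grid), dtype=float)
    if np.any(F <= 0.0) or np.any(sf <= 0.0):
        raise DegenerateThresholdError("grid must lie strictly inside the support")
    pe = np.asarray(dist.partial_mean(grid), dtype=float)
    mean = dist.mean
    p_H = pe / sf
    p_L = np.asarray(dist.lower_partial_mean(grid), dtype=float) / F
    h = p_H - p_L
    gap = h - mean
    return pd.DataFrame({
        "T": grid, "q_H": sf, "p_H": p_H, "p_L": p_L,
        "h": h, "E_p": mean, "gap": gap, "stable": gap >= 0.0,
    })
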