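"""Recursive cumulative payoffs of the two-physician prescription game.

Two physicians each treat one patient per period.  The state is the E-state
``k`` (doses of effectiveness left, ``e = k*alpha``); each administered dose
lowers next period's E-state by one, and the game ends at ``k <= 0``.  A
symmetric threshold strategy prescribes a treatment threshold ``d^k`` per
E-state: treat when the patient's signal satisfies ``p >= d^k``.

Let ``F`` be the signal CDF, ``PE(d) = ∫_d^1 p f(p) dp`` and ``U = alpha*(r2-r1)``.
With both players at threshold ``d`` in state ``k``, the cumulative expected
payoff from ``k`` onwards satisfies (solving the self-referential recursion
for the event that neither treats)

    v^k = [ kU·PE(d) + 2F(1-F)·v^{k-1} + (1-F)^2·v^{k-2} ] / (1 - F^2),

with ``v^k = 0`` for ``k <= 0``.  A unilateral one-stage deviation to
``d_bar`` against an opponent at ``d`` is valued by the asymmetric analogue
with partition probabilities ``A_j`` (= probability that exactly j physicians
treat).  The symmetric value extends continuously to ``d = 1`` (treat nobody
until the rival moves) with the limit ``v^k = kU/2 + v^{k-1}`` — used only by
the social planner, since ``d = 1`` is not a legal strategy.

Under a dichotomous signal at threshold ``T``, the strategy space per state
is {0, T} and the four payoff combinations reduce to the closed recursions
implemented by :func:`dichotomous_values`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coarsening import coarsen
from .signal_models import SignalDistribution
from .static_decision import UtilityParams

__all__ = [
    "GameConfig",
    "Strategy",
    "ValueTable",
    "symmetric_value_table",
    "deviation_value",
    "g_value",
    "dichotomous_values",
]

#: Treat symmetric thresholds within this distance of 1 as the d = 1 limit.
_ONE_TOL = 1e-12


@dataclass(frozen=True)
class GameConfig:
    """Horizon, information system and utilities of the dynamic game.

    The dynamic analysis requires ``c = 0`` (treating is statically dominant;
    the strategic tension is purely about depleting future effectiveness).
    """

    M: int
    dist: SignalDistribution
    params: UtilityParams

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.params.c != 0.0:
            raise ValueError("the dynamic game assumes c = 0")
        if self.M * self.params.alpha > 1.0 + 1e-12:
            raise ValueError("initial effectiveness e0 = M*alpha must be <= 1")

    @property
    def U(self) -> float:
        return self.params.U

    def stage_unit(self, k: int) -> float:
        """kU — the maximal immediate payoff at E-state k."""
        return k * self.params.U


@dataclass(frozen=True)
class Strategy:
    """Symmetric threshold strategy: ``thresholds[k-1]`` is ``d^k``."""

    thresholds: np.ndarray
    allow_one: bool = False  # d = 1 legal only for the planner (never-treat limit)

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        object.__setattr__(self, "thresholds", t)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("thresholds must be a nonempty vector")
        hi = 1.0 if self.allow_one else 1.0 - 1e-15
        if np.any((t < 0.0) | (t > hi)):
            raise ValueError("thresholds must lie in [0, 1); d = 1 only for the planner")

    @classmethod
    def constant(cls, d: float, M: int, allow_one: bool = False) -> "Strategy":
        return cls(np.full(M, float(d)), allow_one=allow_one)

    @property
    def M(self) -> int:
        return self.thresholds.size

    def validate_support(self, dist: SignalDistribution) -> None:
        sm = dist.support_max
        interior = self.thresholds[self.thresholds < 1.0]
        if np.any(interior > sm + 1e-12):
            raise ValueError(f"thresholds exceed the signal support_max = {sm}")


@dataclass(frozen=True)
class ValueTable:
    """Cumulative expected payoffs ``v^0..v^M`` (``values[k]`` is ``v^k``).

    ``v^k = 0`` for k <= 0; ``role`` distinguishes equilibrium values from
    the planner supremum.
    """

    values: np.ndarray
    role: str = "value"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v[0] != 0.0 or not np.all(np.isfinite(v)):
            raise ValueError("need v^0 = 0 and finite entries")

    def v(self, k: int) -> float:
        """v^k, with v^k = 0 for k <= 0."""
        return float(self.values[k]) if k > 0 else 0.0

    @property
    def M(self) -> int:
        return self.values.size - 1

    def to_frame(self, label: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"k": np.arange(self.values.size), "v_k": self.values})
        if label is not None:
            df["profile"] = label
        return df


def symmetric_stage_value(d: float, k: int, cfg: GameConfig,
                          v1: float, v2: float) -> float:
    """Stage-k symmetric value given continuations v^{k-1} = v1, v^{k-2} = v2."""
    if d >= 1.0 - _ONE_TOL:
        return 0.5 * cfg.stage_unit(k) + v1
    F = float(cfg.dist.cdf(d))
    s = float(cfg.dist.sf(d))  # survival form avoids cancellation near F = 1
    if s <= 0.0:  # threshold above the support: same limit as d -> 1
        return 0.5 * cfg.stage_unit(k) + v1
    pe = float(cfg.dist.partial_mean(d))
    return (cfg.stage_unit(k) * pe + 2.0 * F * s * v1 + s**2 * v2) / (s * (1.0 + F))


def symmetric_value_table(strategy: Strategy, cfg: GameConfig) -> ValueTable:
    """Bottom-up evaluation of a symmetric strategy for k = 1..M."""
    if strategy.M != cfg.M:
        raise ValueError("strategy length must equal cfg.M")
    strategy.validate_support(cfg.dist)
    v = np.zeros(cfg.M + 1)
    for k in range(1, cfg.M + 1):
        v[k] = symmetric_stage_value(float(strategy.thresholds[k - 1]), k, cfg,
                                     v[k - 1], v[k - 2] if k >= 2 else 0.0)
    return ValueTable(v)


def deviation_value(k: int, d_bar, d: float, table: ValueTable, cfg: GameConfig):
    """Value of a one-stage deviation to ``d_bar`` against an opponent at ``d``.

    Continuation values come from ``table`` (the symmetric profile): deviate
    now, conform thereafter.  Vectorized over ``d_bar``.  Undefined when both
    thresholds place zero treatment probability (F(d_bar) = F(d) = 1).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scalar = np.ndim(d_bar) == 0
    d_bar = np.atleast_1d(np.asarray(d_bar, dtype=float))
    Fd = float(cfg.dist.cdf(d))
    sd = float(cfg.dist.sf(d))
    Fb = np.asarray(cfg.dist.cdf(d_bar), dtype=float)
    sb = np.asarray(cfg.dist.sf(d_bar), dtype=float)
    if sd <= 0.0 and np.any(sb <= 0.0):
        raise ValueError("payoff undefined when neither physician ever treats "
                         "(the d_i = d_-i = 1 limit does not exist)")
    pe = np.asarray(cfg.dist.partial_mean(d_bar), dtype=float)
    A1 = Fb * sd + sb * Fd
    A2 = sb * sd
    not_A0 = sb + sd - sb * sd  # 1 - F(d_bar) F(d), cancellation-free
    v1 = table.v(k - 1)
    v2 = table.v(k - 2)
    out = (cfg.stage_unit(k) * pe + A1 * v1 + A2 * v2) / not_A0
    return float(out[0]) if scalar else out


def g_value(dist: SignalDistribution, d: float, d_bar: float | None = None) -> float:
    """The auxiliary g-function of the equilibrium analysis.

    For ``d_bar != d``:

        g_d(d_bar) = [ (1-F(d)^2)·PE(d_bar) - (1-F(d)F(d_bar))·PE(d) ]
                     / [ (1-F(d))^2 (F(d) - F(d_bar)) ]

    and at ``d_bar = d`` the continuous limit

        g_d(d) = d·(1+F(d))/(1-F(d)) - F(d)·PE(d)/(1-F(d))^2.

    Strictly increasing in ``d_bar`` — the monotonicity underlying the
    uniqueness of the stage best response.
    """
    if not (0.0 <= d < 1.0):
        raise ValueError("require 0 <= d < 1")
    F = float(dist.cdf(d))
    if F >= 1.0:
        raise ValueError("F(d) must be < 1")
    pe_d = float(dist.partial_mean(d))
    if d_bar is None or d_bar == d:
        return d * (1.0 + F) / (1.0 - F) - F * pe_d / (1.0 - F) ** 2
    Fb = float(dist.cdf(d_bar))
    if Fb == F:  # same CDF mass: fall back to the limit form
        return d * (1.0 + F) / (1.0 - F) - F * pe_d / (1.0 - F) ** 2
    pe_b = float(dist.partial_mean(d_bar))
    num = (1.0 - F**2) * pe_b - (1.0 - F * Fb) * pe_d
    den = (1.0 - F) ** 2 * (F - Fb)
    return num / den


_DICHOTOMOUS_PROFILES = ("both-all", "both-high", "deviate-all-vs-high",
                         "high-vs-deviate-all")


def dichotomous_values(T: float, cfg: GameConfig, profile: str = "both-high") -> ValueTable:
    """Per-E-state values under the dichotomous signal system at threshold T.

    Profiles (decision sets restricted to {0, T}):

    * ``both-all``      — both treat everyone:      v^k = kU·E(p) + v^{k-2}
    * ``both-high``     — both treat high only:
        v^k = [ kU·p_H + 2F·v^{k-1} + (1-F)·v^{k-2} ] / (1 + F)
    * ``deviate-all-vs-high`` — the reported player treats everyone against a
      population playing treat-high (continuations from the both-high table):
        v^k = F·[kU·p_L + v^{k-1}] + (1-F)·[kU·p_H + v^{k-2}]
    * ``high-vs-deviate-all`` — the reported player treats high only against a
      population treating everyone (continuations from the both-all table):
        v^k = F·v^{k-1} + (1-F)·[kU·p_H + v^{k-2}]
    """
    if profile not in _DICHOTOMOUS_PROFILES:
        raise ValueError(f"profile must be one of {_DICHOTOMOUS_PROFILES}")
    cs = coarsen(cfg.dist, T)  # raises on degenerate T
    F = cs.q_L
    mean = cfg.dist.mean
    v = np.zeros(cfg.M + 1)
    if profile in ("both-all", "both-high"):
        for k in range(1, cfg.M + 1):
            kU = cfg.stage_unit(k)
            v1 = v[k - 1]
            v2 = v[k - 2] if k >= 2 else 0.0
            if profile == "both-all":
                v[k] = kU * mean + v2
            else:
                v[k] = (kU * cs.p_H + 2.0 * F * v1 + (1.0 - F) * v2) / (1.0 + F)
        return ValueTable(v)
    # one-stage deviation values: continuation from the symmetric profile
    base = dichotomous_values(T, cfg, "both-high" if profile == "deviate-all-vs-high"
                              else "both-all")
    for k in range(1, cfg.M + 1):
        kU = cfg.stage_unit(k)
        v1 = base.v(k - 1)
        v2 = base.v(k - 2)
        if profile == "deviate-all-vs-high":
            v[k] = F * (kU * cs.p_L + v1) + (1.0 - F) * (kU * cs.p_H + v2)
        else:
            v[k] = F * v1 + (1.0 - F) * (kU * cs.p_H + v2)
    return ValueTable(v)
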