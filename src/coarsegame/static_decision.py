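"""Single-patient decision analysis: treatment thresholds and stage payoffs.

The static problem is the classic treatment-threshold analysis: treat when the
probability of bacterial infection exceeds the threshold at which the expected
utilities of treating and withholding are equal.  With three outcome utilities

* ``r1`` — bacterial infection, not (effectively) treated,
* ``r2`` — bacterial infection, treated with an effective antibiotic,
* ``r3`` — no bacterial infection (treated or not),  with ``r3 > r2 > r1``,

current antibiotic effectiveness ``e`` and iatrogenic-infection risk ``c``,
the threshold is ``T = c(r3-r1) / (e(r2-r1) + c(r3-r1))``.

In the dynamic game, effectiveness is discretized into E-states ``k`` with
``e = k*alpha``; the per-dose net-benefit unit is ``U = alpha*(r2 - r1)``.
The dynamic analysis sets ``c = 0`` (the risk is clinically small), under
which treating is statically dominant and the myopic policy treats everyone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UtilityParams",
    "pauker_kassirer_threshold",
    "static_threshold",
    "immediate_payoff",
    "myopic_policy",
]


class DegenerateThresholdError(ValueError):
    """Raised when both the net benefit and net risk of treatment vanish."""


@dataclass(frozen=True)
class UtilityParams:
    """Utilities and rates of the single-patient problem.

    ``alpha`` is the per-dose depletion of antibiotic effectiveness (in
    probability units); ``U = alpha*(r2 - r1)`` is the derived per-E-state
    net-benefit unit used by the dynamic game.
    """

    r1: float
    r2: float
    r3: float
    c: float = 0.0
    alpha: float = 1.0
    U: float = field(init=False)

    def __post_init__(self):
        if not (self.r3 > self.r2 > self.r1):
            raise ValueError("utility ordering r3 > r2 > r1 violated")
        if not (0.0 <= self.c <= 1.0):
            raise ValueError("c must lie in [0, 1]")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        object.__setattr__(self, "U", self.alpha * (self.r2 - self.r1))


def pauker_kassirer_threshold(u_BT: float, u_BN: float, u_NT: float, u_NN: float) -> float:
    """Four-outcome treatment threshold.

    ``T = net_risk / (net_benefit + net_risk)`` where the net risk is
    ``u(N, not treated) - u(N, treated)`` and the net benefit is
    ``u(B, treated) - u(B, not treated)``.
    """
    net_benefit = u_BT - u_BN
    net_risk = u_NN - u_NT
    if net_benefit < 0 or net_risk < 0:
        raise ValueError("treatment must benefit bacterial cases and "
                         "(weakly) harm non-bacterial cases")
    denom = net_benefit + net_risk
    if denom <= 0:
        raise DegenerateThresholdError("zero net benefit and net risk")
    return net_risk / denom


def static_threshold(params: UtilityParams, e: float) -> float:
    """Three-outcome threshold at effectiveness ``e``.

    ``T = c(r3-r1) / (e(r2-r1) + c(r3-r1))``; with ``c = 0`` antibiotics are
    statically dominant and the threshold is 0.
    """
    if not (0.0 < e <= 1.0):
        raise ValueError("effectiveness e must lie in (0, 1]")
    risk = params.c * (params.r3 - params.r1)
    benefit = e * (params.r2 - params.r1)
    if benefit + risk <= 0:
        raise DegenerateThresholdError("degenerate utilities: no benefit or risk")
    return risk / (benefit + risk)


def immediate_payoff(p, k: int, params: UtilityParams):
    """Expected stage payoff of treating a patient with signal ``p`` at E-state ``k``.

    ``p * k*alpha*(r2-r1) - (1-p) * c*(r3-r1)``; withholding yields 0.  With
    ``c = 0`` this is the dynamic game's stage payoff ``p * k * U``.
    """
    if k < 1:
        raise ValueError("E-state index k must be >= 1")
    p = np.asarray(p, dtype=float)
    out = (p * k * params.alpha * (params.r2 - params.r1)
           - (1.0 - p) * params.c * (params.r3 - params.r1))
    return out if out.ndim else float(out)


def myopic_policy(params: UtilityParams, M: int) -> np.ndarray:
    """Per-E-state thresholds of the myopic (single-patient) policy.

    Entry ``k-1`` holds the static threshold at effectiveness ``k*alpha``,
    for k = 1..M.  Nonincreasing in k; identically 0 when ``c = 0``.
    """
    if M < 1:
        raise ValueError("horizon M must be >= 1")
    if M * params.alpha > 1.0 + 1e-12:
        raise ValueError("initial effectiveness M*alpha exceeds 1")
    return np.array([static_threshold(params, k * params.alpha) for k in range(1, M + 1)])
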