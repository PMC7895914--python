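"""Monte Carlo play-out of the repeated prescription game.

Serves as an independent oracle for the value recursions and for policy
comparisons.  Each run starts at a chosen E-state; every period each
physician's patient draws a signal ``p ~ f``, the physician treats when
``p >= d^k``, treating accrues the expected stage payoff ``p * k * U``, and
the E-state drops by the number of doses administered.  A run ends when the
E-state reaches 0 (or below: when both treat at state 1, both doses count, so
the total number of treated patients is M or M+1).

Randomness is organized as one counter-based substream per period, with
uniform variates drawn for *every* run each period; a policy only decides
which variates it consumes.  Policy comparisons under the same seed therefore
reuse common random numbers.

Payoffs use the expected form of the stage payoff (the game's payoff
definition).  An exploratory ``realized`` mode instead draws the patient's
condition Bernoulli(p) and the drug's effectiveness Bernoulli(k*alpha) and
pays ``(r2 - r1)`` on success; it has the same mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .game_values import GameConfig, Strategy

__all__ = ["SimulationResult", "simulate_game", "mc_value_estimate"]

#: Guard against non-terminating profiles (thresholds at the support edge).
DEFAULT_MAX_PERIODS = 10**6

_HSTATES = ("BB", "BN", "NB", "NN")


@dataclass
class SimulationResult:
    """Per-run outcomes and aggregate summaries of a batch of runs."""

    payoffs: np.ndarray        # (n_runs, 2) cumulative payoff per physician
    doses_used: np.ndarray     # (n_runs,)
    periods: np.ndarray        # (n_runs,)
    visit_counts: np.ndarray   # (M+1,) periods spent at each E-state
    hstate_counts: dict        # joint patient-condition tallies over periods
    capped: np.ndarray         # (n_runs,) hit the max-period guard
    start_state: int

    @property
    def n_runs(self) -> int:
        return self.payoffs.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.payoffs.mean(axis=0)

    @property
    def se(self) -> np.ndarray:
        return self.payoffs.std(axis=0, ddof=1) / np.sqrt(self.n_runs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "payoff_1": self.payoffs[:, 0], "payoff_2": self.payoffs[:, 1],
            "doses_used": self.doses_used, "periods": self.periods,
            "capped": self.capped,
        })


def simulate_game(strat1: Strategy, strat2: Strategy, cfg: GameConfig,
                  n_runs: int, seed: int, start_state: int | None = None,
                  realized: bool = False,
                  max_periods: int = DEFAULT_MAX_PERIODS) -> SimulationResult:
    """Simulate ``n_runs`` independent plays of the game.

    ``start_state`` defaults to M.  Reproducible: identical arguments and
    seed give identical results.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if strat1.M != cfg.M or strat2.M != cfg.M:
        raise ValueError("strategy length must equal cfg.M")
    start = cfg.M if start_state is None else int(start_state)
    if not (1 <= start <= cfg.M):
        raise ValueError("start_state must lie in 1..M")
    d1 = strat1.thresholds
    d2 = strat2.thresholds
    U = cfg.U
    alpha = cfg.params.alpha
    r21 = cfg.params.r2 - cfg.params.r1

    k = np.full(n_runs, start, dtype=np.int64)
    pay = np.zeros((n_runs, 2))
    doses = np.zeros(n_runs, dtype=np.int64)
    periods = np.zeros(n_runs, dtype=np.int64)
    visits = np.zeros(cfg.M + 1, dtype=np.int64)
    hcounts = dict.fromkeys(_HSTATES, 0)

    t = 0
    active = k > 0
    while active.any():
        if t >= max_periods:
            break
        # per-period counter-based substream: variates depend only on
        # (seed, period, run), never on the policy -> common random numbers
        rng = np.random.default_rng([int(seed), t])
        u_sig = rng.uniform(size=(n_runs, 2))
        u_cond = rng.uniform(size=(n_runs, 2))
        u_eff = rng.uniform(size=(n_runs, 2))

        idx = np.nonzero(active)[0]
        ka = k[idx]
        visits += np.bincount(ka, minlength=cfg.M + 1)
        p1 = np.asarray(cfg.dist.ppf(u_sig[idx, 0]), dtype=float)
        p2 = np.asarray(cfg.dist.ppf(u_sig[idx, 1]), dtype=float)
        treat1 = p1 >= d1[ka - 1]
        treat2 = p2 >= d2[ka - 1]

        cond1 = u_cond[idx, 0] < p1  # bacterial?
        cond2 = u_cond[idx, 1] < p2
        for key, mask in (("BB", cond1 & cond2), ("BN", cond1 & ~cond2),
                          ("NB", ~cond1 & cond2), ("NN", ~cond1 & ~cond2)):
            hcounts[key] += int(mask.sum())

        if realized:
            eff1 = u_eff[idx, 0] < ka * alpha
            eff2 = u_eff[idx, 1] < ka * alpha
            pay[idx, 0] += np.where(treat1 & cond1 & eff1, r21, 0.0)
            pay[idx, 1] += np.where(treat2 & cond2 & eff2, r21, 0.0)
        else:
            pay[idx, 0] += np.where(treat1, p1 * ka * U, 0.0)
            pay[idx, 1] += np.where(treat2, p2 * ka * U, 0.0)

        n_treat = treat1.astype(np.int64) + treat2
        doses[idx] += n_treat
        periods[idx] += 1
        k[idx] = ka - n_treat
        active = k > 0
        t += 1

    return SimulationResult(payoffs=pay, doses_used=doses, periods=periods,
                            visit_counts=visits, hstate_counts=hcounts,
                            capped=(k > 0), start_state=start)


def mc_value_estimate(strategy: Strategy, cfg: GameConfig, n_runs: int,
                      seed: int, realized: bool = False) -> pd.DataFrame:
    """Empirical per-E-state values of a symmetric strategy.

    Runs ``n_runs`` plays from every starting state k = 1..M and reports the
    mean cumulative payoff of physician 1 with its standard error — the
    Monte Carlo counterpart of the value recursion.
    """
    rows = []
    for k in range(1, cfg.M + 1):
        res = simulate_game(strategy, strategy, cfg, n_runs,
                            seed=int(seed) + 1000003 * k,
                            start_state=k, realized=realized)
        rows.append({"k": k, "mean": float(res.payoffs[:, 0].mean()),
                     "se": float(res.payoffs[:, 0].std(ddof=1) / np.sqrt(n_runs))})
    return pd.DataFrame(rows)
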