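"""Equilibrium and planner solvers, verified against brute-force oracles."""

import numpy as np
import pytest

from coarsegame import (GameConfig, Strategy, UtilityParams,
                        check_stability_equivalence,
                        dichotomous_stage_equilibrium, make_beta,
                        solve_mpe, solve_social_optimum,
                        symmetric_value_table, verify_mpe)
from coarsegame.equilibrium import _dev_values


def unit_cfg(dist, M):
    return GameConfig(M=M, dist=dist, params=UtilityParams(
        r1=0.0, r2=1.0, r3=2.0, c=0.0, alpha=1.0 / M))


def brute_force_optimum(cfg, grid):
    """Exhaustive enumeration of symmetric threshold strategies on a grid.

    Independent oracle for the planner DP: evaluates v^M for every
    combination of per-state grid thresholds (plus the extended d = 1
    candidate) by the symmetric recursion expressed directly with
    cdf / survival / partial-expectation arrays.
    """
    F = np.asarray(cfg.dist.cdf(grid), dtype=float)
    s = np.asarray(cfg.dist.sf(grid), dtype=float)
    pe = np.asarray(cfg.dist.partial_mean(grid), dtype=float)

    def stage(k, v1, v2):
        # broadcast continuations against the current-stage grid axis;
        # final column is the never-treat limit value kU/2 + v^{k-1}
        kU = cfg.stage_unit(k)
        interior = (kU * pe + 2 * F * s * v1[..., None]
                    + s**2 * v2[..., None]) / (s * (1 + F))
        wait_val = kU / 2 + v1[..., None] * np.ones(1)
        return np.concatenate([interior, wait_val], axis=-1)

    v1 = stage(1, np.zeros(1), np.zeros(1))[0]              # (g,)
    v2 = stage(2, v1, np.zeros(1))                          # (g, g)
    v3 = stage(3, v2, np.broadcast_to(v1[:, None], v2.shape))  # (g, g, g)
    return float(v3.max())


def brute_force_mpe(cfg, grid):
    """Backward-induction stage-equilibrium search by exhaustive deviation.

    At each state, a grid point d is a stage equilibrium when no grid
    deviation improves on the symmetric payoff.  Mirrors the existence
    construction: picks 0 when 0 is an equilibrium, else the largest
    equilibrium grid point.
    """
    v = np.zeros(cfg.M + 1)
    d_out = np.zeros(cfg.M)
    for k in range(1, cfg.M + 1):
        v1, v2 = v[k - 1], v[k - 2] if k >= 2 else 0.0
        eq_points = []
        for d in grid:
            base = float(_dev_values(k, d, d, cfg, v1, v2))
            gains = _dev_values(k, grid, d, cfg, v1, v2) - base
            if gains.max() <= 1e-10:
                eq_points.append(d)
        assert eq_points, f"no grid stage equilibrium at k={k}"
        d_k = 0.0 if (abs(eq_points[0]) < 1e-12) else max(eq_points)
        d_out[k - 1] = d_k
        v[k] = float(_dev_values(k, d_k, d_k, cfg, v1, v2))
    return d_out


class TestSocialOptimum:
    def test_matches_brute_force_enumeration(self, beta_skewed):
        cfg = unit_cfg(beta_skewed, 3)
        rep = solve_social_optimum(cfg)
        # uniform grid plus geometric refinement toward the support edge,
        # where the planner optimum lives
        grid = np.unique(np.concatenate([
            np.linspace(0.0, 0.99, 199), 1.0 - np.geomspace(1e-2, 1e-6, 40)]))
        brute = brute_force_optimum(cfg, grid)
        assert brute <= rep.values.v(3) + 1e-9
        assert rep.values.v(3) - brute <= 0.01

    def test_single_state_uniform_tie_breaks_conservative(self, uniform):
        # at k=1 the uniform planner objective is flat: every threshold
        # yields kU/2; the tie breaks toward the larger (less treatment)
        rep = solve_social_optimum(unit_cfg(uniform, 1))
        assert rep.values.v(1) == pytest.approx(0.5, abs=1e-9)
        assert rep.strategy.thresholds[0] == pytest.approx(1.0)

    def test_thresholds_approach_one(self, uniform, beta_skewed):
        """With ample effectiveness the planner reserves doses for
        near-certain infections: optimal thresholds tend to 1 in k."""
        for dist in (uniform, beta_skewed):
            rep = solve_social_optimum(unit_cfg(dist, 200))
            assert np.all(rep.strategy.thresholds[-50:] > 0.99)


class TestMPE:
    def test_last_dose_treats_everyone(self, uniform, beta_half, beta_skewed):
        # k=1: continuations vanish and treating is dominant -> d = 0
        for dist in (uniform, beta_half, beta_skewed):
            rep = solve_mpe(unit_cfg(dist, 1))
            assert rep.strategy.thresholds[0] == 0.0

    def test_matches_brute_force_stage_search(self, uniform, beta_skewed):
        grid = np.linspace(0.0, 0.995, 200)
        for dist in (uniform, beta_skewed):
            cfg = unit_cfg(dist, 3)
            rep = solve_mpe(cfg)
            brute = brute_force_mpe(cfg, grid)
            np.testing.assert_allclose(rep.strategy.thresholds, brute,
                                       atol=grid[1] - grid[0])

    def test_certified_by_deviation_grid(self, uniform, beta_skewed):
        for dist in (uniform, beta_skewed):
            cfg = unit_cfg(dist, 25)
            rep = solve_mpe(cfg)
            ver = verify_mpe(rep.strategy, cfg, grid_size=999, tol=1e-8)
            assert ver.certified
            assert ver.max_gain <= 1e-8

    def test_social_optimum_not_an_equilibrium(self, uniform):
        """The planner policy invites profitable deviations: a physician
        facing near-1 thresholds gains by treating slightly earlier."""
        cfg = unit_cfg(uniform, 30)
        opt = solve_social_optimum(cfg)
        d = np.minimum(opt.strategy.thresholds, 1.0 - 1e-6)  # legal version
        ver = verify_mpe(Strategy(d), cfg, grid_size=999, tol=1e-8)
        assert not ver.certified

    def test_deviation_payoff_unimodal(self, beta_skewed):
        """No interior local maxima besides the global one (strong
        unimodality of the stage deviation payoff)."""
        cfg = unit_cfg(beta_skewed, 10)
        rep = solve_mpe(cfg)
        tab = rep.values
        grid = np.linspace(0.0, 1.0 - 1e-9, 1001)
        for k in (3, 6, 10):
            d = float(rep.strategy.thresholds[k - 1])
            vals = _dev_values(k, grid, d, cfg, tab.v(k - 1), tab.v(k - 2))
            sign = np.sign(np.diff(vals))
            sign = sign[sign != 0]
            # once decreasing, never increasing again
            assert np.all(np.diff(sign) <= 0)

    def test_overuse_relative_to_optimum(self, uniform, beta_skewed):
        for dist in (uniform, beta_skewed):
            cfg = unit_cfg(dist, 40)
            d_opt = solve_social_optimum(cfg).strategy.thresholds
            d_mpe = solve_mpe(cfg).strategy.thresholds
            assert np.all(d_mpe <= d_opt + 1e-6)
            assert d_mpe.max() < 0.9  # bounded away from 1


class TestDichotomousStageEquilibrium:
    def test_treat_everyone_stable_at_last_dose(self, uniform, beta_peaked):
        for dist in (uniform, beta_peaked):
            table = dichotomous_stage_equilibrium(0.5, unit_cfg(dist, 5))
            assert bool(table.loc[table["k"] == 1, "treat_all_stable"].iloc[0])

    def test_uniform_treat_high_stable_everywhere(self, uniform):
        # equality case of the stability condition: stable at every k, any T
        for T in (0.25, 0.5, 0.75):
            table = dichotomous_stage_equilibrium(T, unit_cfg(uniform, 30))
            assert table["treat_high_stable"].all()

    def test_peaked_treat_high_fails(self, beta_peaked):
        table = dichotomous_stage_equilibrium(0.5, unit_cfg(beta_peaked, 30))
        assert not table["treat_high_stable"].all()


class TestStabilityCriterion:
    def test_equality_and_failure_cases(self, uniform, beta_peaked):
        assert check_stability_equivalence(
            uniform, 0.5, unit_cfg(uniform, 50)) == (True, True)
        assert check_stability_equivalence(
            beta_peaked, 0.5, unit_cfg(beta_peaked, 50)) == (False, False)

    def test_criterion_matches_per_state_checks(self):
        """The closed-form condition p_H - p_L >= E(p) agrees with the
        exhaustive per-state stage-equilibrium inequalities."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            dist = make_beta(rng.uniform(0.3, 5), rng.uniform(0.3, 5))
            T = rng.uniform(0.05, 0.95)
            M = int(rng.integers(1, 51))
            cond, all_k = check_stability_equivalence(dist, T, unit_cfg(dist, M))
            assert cond == all_k
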