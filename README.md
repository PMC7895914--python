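# coarsegame

Game-theoretic analysis of empirical antibiotic prescription: equilibrium
solvers for a two-physician stochastic game with depletable drug
effectiveness, and an analysis of when *coarsening* the diagnostic signal
into a high/low dichotomy makes the socially desirable prescribing policy an
equilibrium.

## The problem

When a physician must decide on empirical antibiotic treatment before
culture results are available, the decision rests on a *signal*: the
posterior probability `p` that the patient's infection is bacterial, drawn
across patients from a density `f(p)` on [0, 1]. Antibiotic effectiveness is
a common-pool resource — every administered dose selects for resistance and
depletes future effectiveness. The model discretizes effectiveness into
E-states `k = M, M-1, …, 1` (effectiveness `e = kα`); each dose lowers the
next period's E-state by one, and the game ends at 0.

A physician who treats a patient with signal `p` at E-state `k` gains the
expected net benefit `p·kα(r₂ − r₁)` — where `r₂ > r₁` are the utilities of
treated and untreated bacterial infection — written `p·kU` with the
net-benefit unit `U = α(r₂ − r₁)`. Strategies are per-state thresholds
`d^k`: treat iff `p ≥ d^k`. Cumulative values satisfy the recursion

    v^k = [ kU·PE(d^k) + 2F(1−F)·v^{k−1} + (1−F)²·v^{k−2} ] / (1 − F²),

with `F = F(d^k)` the signal CDF and `PE(d) = ∫_d¹ p f(p) dp`.

Three results structure the analysis:

* **Social optimum** — dynamic programming over symmetric thresholds shows
  the planner's `d̂^k → 1` as `k` grows: with ample effectiveness it pays to
  reserve doses for near-certain infections.
* **Equilibrium overuse** — a symmetric pure-strategy Markov perfect
  equilibrium (MPE) always exists and is constructed by backward induction,
  but its thresholds `d̃^k` stay bounded away from 1: rational physicians
  always prescribe more than the optimum.
* **Coarsening** — replace the continuous signal by "high/low relative to a
  threshold T", inducing posteriors `p_H` and `p_L` with appearance
  probabilities `q_H = 1 − F(T)` and `q_L = F(T)`. Then *treat only
  high-signal patients at every E-state* is an MPE **iff**

      p_H − p_L ≥ E(p),

  i.e. the posterior spread exceeds the prevalence of bacterial infection —
  a condition on the information system alone, independent of utilities,
  depletion rate and horizon.

The package implements signal distributions (beta, truncated uniform, and a
logit-scale kernel density estimate for empirical posterior samples), the
static treatment-threshold analysis, the value recursions, both solvers, a
Monte Carlo simulator that serves as an independent oracle, the coarsening
stability analysis, and a synthetic-cohort pipeline emulating a pediatric
respiratory-infection dataset (n = 1202, bacterial co-infection prevalence
235/1202).

## Worked example

Solve a 10-state game with a right-skewed Beta(1, 5) signal (mostly
non-bacterial presentations, prevalence `E(p) = 1/6`), `α = 0.1`,
`r₂ − r₁ = 1`:

```python
import numpy as np
from coarsegame import (GameConfig, UtilityParams, make_beta,
                        solve_mpe, solve_social_optimum)

dist = make_beta(1, 5)
cfg = GameConfig(M=10, dist=dist,
                 params=UtilityParams(r1=0.0, r2=1.0, r3=2.0, c=0.0, alpha=0.1))
opt = solve_social_optimum(cfg)
mpe = solve_mpe(cfg)
```

The solved policies (columns: planner threshold and value, equilibrium
threshold and value):

```
k  d_opt      d_mpe      v_opt      v_mpe
1  1.000000   0.000000   0.050000   0.016667
2  1.000000   0.112336   0.150000   0.046255
5  1.000000   0.130716   0.750000   0.220798
10 1.000000   0.136997   2.750000   0.797160
```

The planner would wait for (near-)certain bacterial infections at every
E-state (`d̂^k = 1`, the extended never-treat-first limit), while the
equilibrium physicians treat any patient with `p ≳ 0.14` — massive overuse —
and collect less than a third of the attainable value at `k = 10`
(0.797 vs 2.750). Coarsening repairs this: for this distribution

```python
from coarsegame import min_stable_threshold, stability_gap
min_stable_threshold(dist)      # -> 0.0
stability_gap(dist, 0.3)        # -> 0.1338 (>= 0: stable)
```

any positive threshold `T` satisfies `p_H − p_L ≥ E(p)`, so "treat only
high-signal patients" can be made an equilibrium at whatever strictness the
regulator prefers. By contrast a nearly uninformative Beta(20, 20) signal
admits no stable threshold at all.

The same analyses are available from the shell:

```sh
coarsegame coarsen --dist beta:1,5 --grid 999 --out profile.csv
coarsegame solve --config game.yaml --policy both --out policies.csv
coarsegame cohort --n 1202 --prevalence 0.1955 --seed 7 --out cohort_out/
```

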