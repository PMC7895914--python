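# Methods

## Model

Two physicians each treat one patient per period. Antibiotic effectiveness
is discretized into E-states `k` with effectiveness `e = kα`; the initial
state satisfies `e₀ = Mα ≤ 1`. Each administered dose lowers the next
period's E-state by one (two simultaneous doses skip a state), and the game
ends when the state reaches 0 — so across a play-out either `M` or `M + 1`
patients receive a dose. Patients present i.i.d. signals `p ~ f(p)`, the
posterior probability of bacterial infection; the prevalence is
`P(B) = E(p)`. Payoffs are *net* expected utilities of treatment: treating a
patient with signal `p` at state `k` yields `p·kα(r₂ − r₁) − (1−p)·c(r₃ − r₁)`,
withholding yields 0.

The static module supports the full three-outcome threshold analysis with
iatrogenic risk `c > 0`. The dynamic game fixes `c = 0` (clinically the risk
is small, and treating is then statically dominant, which isolates the
strategic tension: current benefit vs. depletion of the common resource).
Strategies are stationary Markov threshold rules, one threshold per E-state;
with a fixed rival strategy the best response problem is a Markov decision
process, so restricting deviations to Markov strategies is without loss.

`d^k = 1` (never treat) is not a legal strategy — the asymmetric payoff has
no limit when both players never treat — but the *symmetric* value extends
continuously to `d = 1` with value `kU/2 + v^{k−1}` (each physician waits
for the other's patient to spend the dose; by symmetry each is "first" half
the time). The planner's strategy space includes this extension; the
equilibrium solver's does not.

## Signal distributions

* **Beta(a, b)** — CDF, survival and truncated first moments are evaluated
  through regularized incomplete beta functions (`betainc` / `betaincc`),
  including `PE(d) = mean · I_c(a+1, b; d)`. The complement forms keep
  deep-tail quantities accurate to relative precision, which matters because
  planner optima sit at thresholds where `1 − F(d)` is below 1e-12.
* **Truncated uniform (lo, hi)** — closed forms; `support_max = hi` and all
  threshold searches are restricted to `[0, support_max]`, since a higher
  threshold never binds.
* **Empirical (KDE)** — posterior samples are mapped to the logit scale, a
  Gaussian KDE with Silverman bandwidth is fitted there (respecting the
  (0, 1) boundaries), and the density is transformed back. A floor constant
  (default 1e-4) is added and the density renormalized, giving support on
  all of (0, 1); the mixture form makes the normalization exact. CDF and
  partial expectations are tabulated on a dense (8192-point) logit grid and
  interpolated monotonically (PCHIP); sampling inverts a 4096-point CDF
  table with a bisection sweep against the true CDF. The smoothing method
  and bandwidth are conventions of this package — only *that* the empirical
  density is smoothed and floored is inherited from the application.

## Coarsening and stability

Dichotomizing at `T` induces `q_H = 1 − F(T)`, `q_L = F(T)`,
`p_H = PE(T)/q_H`, `p_L = (E(p) − PE(T))/q_L` (computed from the lower
partial moment directly, again to avoid cancellation). The policy "treat
only high-signal patients at every E-state" is an MPE of the coarsened game
iff the spread condition `h(T) = p_H − p_L ≥ E(p)` holds; equality counts as
stable (the condition is a weak inequality). `min_stable_threshold` scans a
1e-3 grid of the gap `h(T) − E(p)` and refines the left boundary of the
stable set by bisection to the requested tolerance; grid points where
`F(T) ∈ {0, 1}` to machine precision are treated as degenerate and excluded.
The stable set need not be an interval for unusual densities;
`stable_intervals` reports it at grid resolution, while
`min_stable_threshold` returns only the infimum.

**Boundary artifact of the density floor.** As `T → 1`, `p_L → E(p)` and
`p_H → (1+T)/2` under the floored density, so the gap tends to `1 − 2E(p)`.
Any *estimated* density with mean below 1/2 therefore has technically-stable
thresholds in the extreme right tail — a high signal at such a threshold is
nearly conclusive — even when the generating family has none (e.g.
Beta(20, 20)). Conclusions about "no stable threshold" for estimated
densities should be read on the interior of (0, 1); the profile table makes
this visible rather than suppressing it.

## Value recursions and solvers

All stage values are implemented in the *solved* form of the recursion
(denominator `1 − F_i F_{−i}`), never by fixed-point iteration, and in
survival-function form (`1 − A₀ = s_i + s_{−i} − s_i s_{−i}` with
`s = 1 − F` computed directly) so thresholds within ulps of the support edge
remain well conditioned. Deviation values use one-stage-deviation semantics:
continuation values always come from the symmetric profile under evaluation.

* **Social optimum** — backward DP; each stage maximizes the symmetric
  stage value over a 1e-3 grid (endpoint included) with bounded scalar
  refinement to 1e-8, plus the extended `d = 1` candidate. Ties break toward
  the larger threshold (the more conservative policy), which also resolves
  the flat uniform-signal objective at `k = 1`. The grid-plus-refinement
  maximizer is used because the planner objective is not covered by the
  unimodality result for deviation payoffs.
* **MPE** — backward induction over states. The marginal one-stage deviation
  gain `G(d) = ∂v/∂d̄ |_{d̄=d}` is a central finite difference (step 1e-6,
  one-sided at box edges); strong unimodality of the deviation payoff makes
  this sign test sufficient (the minimal one-stage-deviation principle). If
  `G(0) ≤ 0`, the stage equilibrium is 0; otherwise the solver brackets the
  last sign change of `G` on a 1e-3 grid and bisects to tolerance (default
  1e-10), returning the supremum of points from which upward deviation is
  profitable. A bracket failure raises with per-state diagnostics rather
  than guessing.
* **Certification** — `verify_mpe` evaluates one-stage deviations on a grid
  (default 999 points plus the endpoints `{0, support_max − 1e-9}`) at every
  state and certifies when no gain exceeds the tolerance (default 1e-8 in
  payoff units).
* **Dichotomous checks** — with decisions restricted to `{0, T}` the four
  payoff combinations close into per-state recursions, and both stage-
  equilibrium conditions reduce to scalar inequalities per state;
  `check_theorem9_equivalence` cross-checks the closed-form criterion
  against these exhaustive per-state tests.

## Simulator

The Monte Carlo simulator is an independent oracle for the recursions: runs
draw signals per patient per period, apply the threshold rules, accrue the
expected-form stage payoff `p·kU`, and step the E-state down by the number
of doses. Variates are organized as one counter-based substream per period
with draws laid out per run, so different policies under the same seed
consume common random numbers. Patients' true conditions are drawn
Bernoulli(p) for reporting (calibration and joint-condition frequencies);
payoffs use the expected form exactly as the game defines them, with an
exploratory `realized` mode (condition × effectiveness lottery on
`r₂ − r₁`) that has the same mean. A max-period cap (default 1e6) guards
profiles that never deplete; capped runs are flagged, not silently
truncated.

## Synthetic cohort

The generator emulates the shape of the clinical application (1202
children with RSV bronchiolitis, 235 with bacterial co-infection): true
posteriors are drawn from Beta(a, b) with `a = 0.8` and `b` solved so the
mean equals the prevalence — a right-skewed density chosen as a plausible
stand-in for classifier output on a mostly-viral cohort — and labels are
drawn Bernoulli(p), so calibration holds by construction. The pipeline then
mirrors the empirical analysis: samples → floored logit-KDE density →
threshold profile → minimal stable threshold, with the generating family's
analytic minimal threshold reported alongside as the recovery target.

What passing tests show: the pipeline recovers the generating family's
minimal stable threshold to within ±0.02 at this sample size. What they do
not show: anything about a real classifier's posterior distribution — the
generator produces posteriors directly and perfectly calibrated, with no
feature noise, model misspecification or class imbalance in the estimation
step, so real-data thresholds (and the published real-data value) are out
of reach of any synthetic configuration.

## Problem sizes and defaults

Defaults used by the tests and examples: grids of 999 thresholds for
profiles and deviation checks; horizons M = 10 for simulation oracles
(1e5 runs, agreement within 3 SE), M = 50 for certification and M = 200 for
the asymptotic threshold-gap checks; 20 seeds for cohort parameter
recovery; `U` normalized via `r₂ − r₁ = 1` and `α = 1/M` so `e₀ = 1`. These
sizes were chosen so every qualitative regime of the model (last-dose, bulk
and near-edge states) is exercised while the whole suite remains quick to
run.

## Known limitations

* Only symmetric pure-strategy equilibria are computed; the backward
  construction yields one MPE and does not enumerate others, and
  asymmetric or mixed equilibria are out of scope (as is the n-physician
  extension).
* Coarsening analysis is dichotomous only; finer partitions and optimizing
  `T` against welfare are not implemented.
* The depletion model is an approximation of resistance dynamics — no
  mechanistic transmission, no effectiveness recovery, game ends at full
  depletion.
* The KDE floor's boundary artifact (above) means empirical minimal
  thresholds in the extreme right tail should be interpreted with care.
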