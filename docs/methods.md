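# Methods

This note records the models the package implements, the assumptions they
lean on, the defaults and why, and the places where the design was
genuinely open.

## Setting

A dataset D holds n i.i.d. rows over d variables. The target of inference
is the DAG G* of the probabilistic graphical model that factorizes the
joint distribution. Two estimation routes are implemented: a
constraint-based (PC-style) learner for discrete data and a score-based
continuous-optimization learner for real-valued data generated by a
linear structural equation model (SEM) F = WᵀF + Z. Privacy is
(ε, δ)-differential privacy under *one-row replacement* neighbors; all
data-dependent releases pass through the Laplace or analytic-Gaussian
mechanism, and an append-only accountant enforces the totals.

## Constraint-based learner

### CI statistic

The shipped statistic is Kendall's τ-b, tie-corrected, computed within
strata defined by the joint value of the (discrete) conditioning set S.
Strata with fewer than `min_stratum = 5` rows are excluded; the statistic
is the stratum-size-weighted mean of |τ| over usable strata, mapped to the
independence scale by the two-sided normal approximation
z = 3τ√(m(m−1))/√(2(2m+5)), f = 2(1 − Φ(|z|)) with m the total weight.
Larger f means "looks more independent"; an edge is deleted when the
noisy f exceeds T. If no stratum is usable (m = 0), the pair is
*untestable*: the edge is kept, nothing is released, no budget is spent,
and the event is flagged in the ledger. A stratum in which either variable
is constant carries no rank signal and contributes τ = 0 with its weight.

The conditional construction (stratification, weighting, the stratum
floor) is this package's design; the τ-to-p-value map is the standard
asymptotic one.

### Sensitivity

Laplace noise is calibrated to an l1-sensitivity bound of the form
Δ₁ = `score_lipschitz` × C/n, applied on the independence-score scale
(`score_lipschitz` defaults to 1.0, i.e. C is treated as calibrated on
the score scale directly). The default C = 6 dominates the exhaustive
one-row-replacement worst case of τ-b over all binary datasets at
n ∈ {3, 4, 5} (measured maxima: 1.0 at each n, so C/n = 2.0, 1.5, 1.2
bound them).

**Limitation.** For discrete data with heavy ties, the exact worst case
of τ-b under one-row replacement does not decay like 1/n: replacing one
row can collapse a column to a constant (τ undefined, mapped to 0), a
Θ(1) jump at any n. The C/n form is retained as the interface contract —
it is the right scaling for continuous data without ties and for
tau-a-style statistics — and both C and the score-scale Lipschitz factor
are configuration, with the exhaustive small-n oracle as the shipped
calibration check. Users who need a worst-case guarantee for heavily tied
discrete data at large n should set C accordingly (e.g. C = n·1.0).

### Decision rule and error bounds

The noisy statistic f̂ = f + Lap(Δ₁/ε) is compared against margins:
delete above T(1+β₂), keep below T(1−β₁), fair coin in between. Defaults:
T = 0.05, β₁ = β₂ = 0.1, c₁ = c₂ = 0.5.

The per-test relative error bounds q⁽ᵏ⁾ = c_k/2 + ½·e^{−Tβ_kε/Δ} treat
the slack constant c_k as absorbing the coin-region mass. With the clean
statistic exactly at the boundary f = T, the probability the noise lands
inside the coin band is 1 − ½e^{−Tβ₁ε/Δ} − ½e^{−Tβ₂ε/Δ}; half of it is
error. The bound with c = 0.5 therefore holds at the boundary whenever
e^{−x₁} + e^{−x₂} ≥ 1 for x_k = Tβ_kε/Δ (with β₁ = β₂ this is
x ≤ ln 2). The Monte-Carlo bound checks in the test suite use grid cells
inside this regime; outside it (very large ε·β/Δ) the c/2 slack no longer
covers the boundary coin mass and the bounds should be read as holding
for statistics separated from the threshold. The margins and slack
constants are configurable for exactly this reason.

### Budget allocation

At the start of order i with e_i surviving edges and remaining budget
ε_Total(i), the allocator minimizes
Π_j q_j⁽¹⁾ + 1 − Π_j(1 − q_j⁽²⁾) over (ε_i, …, ε_{d−2}) subject to

- Σ_j [t_j ε_j² + ε_j √(2 t_j ln(1/δ′))] ≤ ε_Total(i) — advanced
  composition inside each order (all order-j tests share (ε_j, δ)),
  summed across orders (basic composition);
- ε_j ≥ ε_{j+1} ≥ … ≥ `eps_floor` (default 1e−4; prevents the tail
  orders being driven to zero, where q → (c+1)/2 and tests are wasted).

Future test counts use the bound t_j = e_j·C(d−2, j) with unseen e_j
projected as the current e_i; the projection is self-correcting because
the problem is re-solved at every order on the observed edge count. The
solver is SLSQP (max 500 iterations) started from the uniform feasible
point — the single shared ε that saturates the leakage constraint, i.e.
the positive root of a quadratic; on solver failure the uniform plan is
used and flagged. If even the floor is infeasible the run stops and the
ledger is flagged truncated.

The ledger charges each order with the number of tests *actually*
performed (deleted pairs short-circuit their remaining subsets), which is
never more than the bound used inside the constraint. A uniform-budget
ablation mode (one shared ε for the whole run, sized against the
complete-graph bounds) ships as the non-adaptive baseline.

### Orientation

V-structures from recorded separation sets (unshielded triple a−b−c with
b ∉ sepset(a, c) orients a→b←c; conflicting claims resolve
first-applied-wins in lexicographic triple order), then Meek rules R1–R3
to closure. R4 is unreachable without background knowledge and is not
implemented. Any orientation that would create a directed cycle is
skipped, so the directed part is acyclic by construction. Orientation
reads only the skeleton and sepsets — postprocessing under DP.

## Score-based learner

### Objective and privacy

Minimize ℓ(W; D) + λ‖W‖₁ + (ρ/2)h(W)² + αh(W) with
ℓ = (1/2n)‖D − DW‖²_F, h(W) = tr(e^{W∘W}) − d (matrix exponential via
SciPy's scaling-and-squaring Padé routine), columns centered to zero mean
before fitting. Per iteration, the data gradient −(1/n)Dᵀ(D − DW)
(diagonal zeroed) is clipped to Frobenius radius s and perturbed with
Gaussian noise of scale σ(Δ₂, ε_i, δ) from the analytic calibration
(smallest σ satisfying the exact mechanism condition, by bisection to
relative tolerance 1e−10). The acyclicity terms are data-free and exact.
The ℓ1 term is handled by soft-thresholding after each step (proximal
step), and dual updates α ← α + ρh follow each inner stretch, with
ρ ← 10ρ while h stalls above a quarter of its previous value.

Gradient sensitivity under one-row replacement defaults to Δ₂ = 2s/n
(each row's contribution is bounded by s after clipping; replacing one
row moves the sum by at most 2s). The coarser d·s/n and d(d−1)·s/n
conventions are selectable via `sensitivity_mode`; the ledger records
which was used.

### Budget schedule

ε_i is nondecreasing in i: additive ε₀(1 + i/I), exponential
ε₀·exp(i/I), or multiplicative ε₀·mⁱ (geometric growth, default
m = 1.05 — the geometric reading is this package's concretization of a
multiplicative increment; the summation oracle, not a closed form, is
authoritative for how many iterations fit). The iteration count I is the
largest value whose scheduled sum stays within ε_Total, found by direct
summation. Closed forms are provided alongside for reference: additive
(ε_Total + ε₀/2)/(3ε₀/2) (exact at the oracle), exponential
ε_Total/(ε₀·e) (conservative). Iterations compose by basic composition,
each iteration being (ε_i, δ)-DP with δ = 1e−9 per iteration by default.

### Line search and step sizes

The backtracking search evaluates a *data-free* surrogate: the data term
is modelled by its first-order expansion through the already-released
noisy gradient plus a quadratic trust term, and the penalty terms are
evaluated exactly. η starts at 1 and halves until the Armijo condition
(coefficient 1e−4) holds; below 1e−10 the step is skipped. Because only
released quantities and data-free terms are touched, the search is
postprocessing and consumes no budget — by contrast with designs whose
probes query the data, which would need per-probe accounting.

The trust-term curvature is estimated from differences of successive
released gradients (a Barzilai–Borwein-style local Lipschitz estimate,
floor 1.0); without it a linear surrogate would accept the full step
everywhere and the iteration would overshoot whenever the loss curvature
exceeds 1. Non-finite trial evaluations (overflow of the matrix
exponential at wild points) are treated as infinitely bad and rejected.

With a hard iteration budget, a few long primal stretches beat many short
ones — every dual update restarts progress under a stiffer penalty — so
the default inner-loop cap is half the total iteration budget (500 in the
noise-bypassed reference mode, which is not budget-limited). The final
weights are pruned at |w| > ω; any cycles surviving pruning are broken by
repeatedly removing the smallest-|w| edge on a cycle.

### Defaults

λ = 0.1, ρ₀ = 1, α₀ = 0, s = 1.0, h_tol = 1e−8, ω = 0.3,
max_outer = 100, schedule multiplicative with ε₀ = 0.1, m = 1.05.
W is initialized at zero; the seed controls only the noise draws, so runs
with equal seeds are bit-identical.

## Privacy accounting

`PrivacyParams` defaults: per-test δ = 1e−15, advanced-composition slack
δ′ = 1e−12 (the δ′ ≤ n^−1.5 safety rule at n = 10⁵), cumulative
δ_Total = 1e−6. The advanced-composition expression used by the budget
optimizer is the simplified t·ε² + ε√(2t·ln(1/δ′)); a strict mode
switches the first term to the textbook t·ε(e^ε − 1). The ledger is
append-only, rejects any spend that would overshoot ε_Total or δ_Total
*before* noise is drawn, serializes to JSON, and replays to identical
totals.

## Synthetic workbench

The generators emulate the regimes the learners assume, at desk scale:

- **Discrete Bayesian networks**: Erdős–Rényi DAGs (uniform random
  topological order, forward-pair probability `expected_degree/(d−1)`,
  default degree ≈ 1.6–2), binary variables, CPT rows from a symmetric
  Dirichlet (concentration 0.5 — away from uniform so edges carry
  signal), ancestral sampling. Benchmark fixtures `tiny5`, `medium8`,
  `wide11` (d = 5, 8, 11) are seeded, connected, regenerated
  deterministically, and stand in for the small public CGD benchmarks;
  no external data is bundled or downloaded.
- **Linear SEMs**: acyclic weighted graphs with weights uniform on
  ±[0.5, 2.0] (bounded away from zero so the pruning threshold ω = 0.3
  is meaningful), unit Gaussian (or uniform) noise, rows solved as
  D = Z(I − W)⁻¹.

What passing tests on these generators do **not** show: behavior under
unfaithful or near-unfaithful distributions (e.g. parity mechanisms),
mixed discrete–continuous data, latent confounding, non-linear SEMs, or
the n = 10⁵ sample sizes of the public benchmark replications. Evaluation
scales were chosen for single-CPU runtimes: d ≤ 8, n ≤ 5000, 10–20 seeds
per condition, 50-run sweep protocol retained in the driver.

## Evaluation

F1 is computed on undirected skeletons by default (precision
|E∩E*|/|E|, recall |E∩E*|/|E*|); a directed mode counts an undirected
CPDAG edge as both orientations. Conventions: both edge sets empty → 1;
estimated empty against nonempty truth → 0. SHD is the symmetric
difference size. CI-test counts are the ledger's actual per-order totals.

## Numerical choices

- Matrix exponential: SciPy `expm`, no truncated series.
- Analytic Gaussian calibration: bisection, relative tolerance 1e−10,
  log-space evaluation of e^ε·Φ(·) to avoid overflow.
- SLSQP constraint tolerance 1e−8; returned plans are repaired onto the
  feasible set (floor clip, running-minimum monotonization) and fall back
  to the uniform plan if still infeasible or worse than the start.
- Ties in τ: variant b. Constant vectors: τ = 0, flagged.
- Degenerate pruning inputs: entries with |w| exactly equal to ω are
  excluded (strict inequality).

## Known limitations

- The τ-b sensitivity question for heavily tied data (above).
- Lemma-style error bounds hold in the margin/noise regime described
  above; the package does not verify per-dataset that the regime applies.
- The surrogate error objective treats per-order error bounds as
  independent across orders; correlations induced by shared data are not
  modelled.
- The score learner inherits the non-convexity of the continuous
  acyclicity program: no global-optimum guarantee, and recovery quality
  depends on the schedule granting enough iterations at workable noise.
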