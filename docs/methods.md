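# Methods

## Model

The package models a single gene by the standard two-state (telegraph)
abstraction of the central dogma. The state is (s, m, p): promoter
(s ∈ {0, 1}), RNA count m, protein count p. Six reactions with linear
propensities drive it:

| reaction | propensity | effect |
| --- | --- | --- |
| promoter activation | k_on·(1−s) | s → 1 |
| promoter inactivation | k_off·s | s → 0 |
| transcription | k_r·s | m → m+1 |
| RNA degradation | γ_r·m | m → m−1 |
| translation | k_p·m | p → p+1 |
| protein degradation | γ_p·p | p → p−1 |

All rates share one time unit (minutes by default). The stationary joint
law — hence every moment and every fitted quantity — is invariant under a
common rescaling of all six rates, so the unit choice only affects
rate-dimensioned report columns (RNA synthesis rate, burst frequency).
Assumptions inherited from the model: a single gene copy, no cell-cycle or
extrinsic-noise structure, first-order degradation (dilution folded into
γ_p), and transcription only from the ON state. k_off = 0 is admitted and
encodes a constitutive gene.

## Exact moments

Because every propensity is linear, multiplying the master equation by
s^a·mⁱ·pʲ and summing yields a *closed* linear system: d/dt E[s^a mⁱ pʲ]
involves only moments of combined order ≤ i+j. The package tracks the
ON-partial layer E[s·mⁱ·pʲ] and the total layer E[mⁱ·pʲ] for
1 ≤ i+j ≤ 4 — 14 index pairs × 2 layers = 28 unknowns — after substituting
the autonomous promoter occupancy E[s] = p_on = k_on/(k_on+k_off) in
closed form. Setting derivatives to zero and solving gives the exact
protein mean M, variance V, and central moments μ₃, μ₄.

All coefficients are generated programmatically (binomial expansion of
g(x+Δ)−g(x) per reaction, with the idempotency reduction s^k → s) rather
than transcribed, and are verified three independent ways in the test
suite: against hand-typed order-1/2 balance equations (the classical
published mean/variance), against the action of a dense truncated-CME
generator on arbitrary distributions (every coefficient of every row), and
against the stationary distribution of the truncated CME (finite state
projection, boundary mass < 1e−12) to 1e−6 relative on all four moments.

### Numerical choices

* **Central coordinates.** The solver works in moments of δm = m−⟨m⟩,
  δp = p−⟨p⟩ (same closed structure, constants shifted by the closed-form
  means). Raw fourth moments can exceed μ₄ by four orders of magnitude, so
  computing central moments from raw ones cancels digits; the central
  formulation delivers V, μ₃, μ₄ directly at near machine precision. The
  raw-moment system is still assembled (same generator) as the
  documentation/verification surface, and raw partial moments are
  recovered from central ones by the loss-free upward binomial conversion.
* **Block staging.** The system is block-triangular in total moment order
  and is solved as four dense blocks (4, 6, 8, 10 unknowns) with partial
  pivoting. Order-2 stops suffice for variance — the inverse search
  exploits this to reject most candidates after two small solves.
* **Pre-scaling.** Rates are divided by their geometric mean before
  assembly (a pure change of time unit) to keep block conditioning tame at
  extreme rate ratios; a RuntimeWarning reports condition numbers above
  1e12.
* **Canonical order.** Public matrices/vectors index moments layer-major
  (ON-partial first), total order ascending, RNA order descending, so rows
  are reproducible across runs and versions.

## ACES: the inverse search

Input: a target (M, V, μ₃, μ₄) and per-rate physiological ranges. The
search enumerates a log-spaced grid (default resolution 83 per rate, a
nominal 83⁶ ≈ 3.27·10¹¹ space) but never wastes work off the
mean-constraint surface:

1. Rates are assigned in a configurable order (default k_on, k_off, k_r,
   γ_r, k_p, with γ_p solved last; `reverse` flips the enumerated five).
2. Before assigning the next rate, the closed-form mean equation is solved
   for it at the corners of the still-free rates' ranges. The mean is
   monotone in every rate, so the corner values bracket its feasible
   interval exactly; the bracket is intersected with the rate's own range
   and infeasible branches are pruned. Corner inversions with no
   non-negative solution are the monotone limits of the bracket (+∞ when
   solving for k_on, 0 for k_off — occupancy saturates at 1).
3. The last free rate is solved exactly from the mean, so every complete
   candidate satisfies the mean to round-off.
4. Candidates are screened on the selected higher moments in increasing
   cost order — variance, then μ₃, then μ₄ — each at relative tolerance
   |calc − target| / max(|target|, 1e−12) ≤ tol (default 1%, the guard
   protecting near-zero μ₃ targets). Moment subsets MV / MVS / MVSK
   select how many are checked; ensembles nest accordingly.

**Grid semantics.** By default the search enumerates, inside each
constrained interval, the nodes of the *fixed full-range lattice*
(`grid_mode="lattice"`). This keeps every candidate on one global grid, so
any on-grid rate set whose moments match is provably returned — the
completeness property the tests verify against a naive full-lattice
oracle — and the number of nodes in an interval automatically shrinks by
the fraction of log-width lost, matching `rescale_resolution`
(max(1, round(n·constrained/full))). The alternative `respaced` mode
re-spreads the reduced point count across each constrained interval
(geometric midpoint when a single point remains); it searches off-lattice
and trades completeness guarantees for marginally denser local coverage.

Determinism: the enumeration order is fixed by the configuration and the
output is sorted by rate values, so identical inputs give identical
ensembles. Every accepted solution is re-evaluated through the full
forward solver for the recorded per-solution moments. An empty result
distinguishes "infeasible mean" (the target mean is outside the image of
the range box, or every branch was mean-pruned) from "no moment match".

The hot path (bound propagation, lattice subsetting, staged screening for
the two deepest levels) is JIT-compiled; a resolution-48 run over six
two-decade ranges screens ~1.5·10⁸ mean-consistent candidates in a few
minutes on one CPU. The acceptance script uses exactly that scale;
interactive analyses and the test suite use resolutions 6–24 of the same
code path.

## Ensemble analysis

Fit quality of an ensemble against a known truth is summarised by the
median log distance MD = median_i |log₁₀(value_i) − log₁₀(truth)| in
decades, computed for each of the six rates and eight derived ratios
(p_on, effective RNA synthesis rate k_r·p_on, burst size k_r/k_off, burst
frequency k_on·k_off/(k_on+k_off), mean RNA, proteins per RNA k_p/γ_p, and
the gamma-model ratios k_p/γ_r and k_r/γ_p). MD < 0.75 — the median
solution within an order of magnitude — is the strict "successful fit"
call. MD is a survey device: histograms of ensembles over fixed log bins
spanning each range are the faithful view, and MD is known to flatter
bimodal patterns. Maximally distant solution pairs are found under the
log-Euclidean metric sqrt(Σ log₁₀(θ_A/θ_B)²), exactly for ensembles up to
a configurable cap (2000) and on a seeded deterministic subsample beyond
it. Library-level tables average MD and success per parameter across
members and report Δ columns against a reference condition.

Where the printed sources of these conventions are ambiguous, the package
fixes: log base 10 for MD and log-Euclidean distances; burst frequency as
the steady-state rate of completed OFF→ON cycles; RNA synthesis rate as
k_r·p_on. All are single functions and trivially replaceable.

## Distribution metrics and the gamma reference method

KL divergence uses base-2 logs; the Jensen–Shannon divergence
JSD = ½KL(P‖M*) + ½KL(Q‖M*) with M* = (P+Q)/2 is then symmetric and
bounded in [0, 1] (0 identical, 1 disjoint). Moment vectors are compared
by the log-Euclidean distance over (M, V, μ₃, μ₄), with μ₃ excludable for
near-symmetric distributions whose μ₃ has no log coordinate.

The gamma (Friedman-type) reference method estimates shape a = M²/V
(≈ k_r/γ_p) and scale b = V/M (≈ k_p/γ_r) by moments. Its validity regime
is screened as γ_r/γ_p ≥ 100, mean protein > 1000 and p_on ≥ 0.99
(thresholds configurable); the scale estimate additionally needs
b ≫ 1 for the Poisson counting term in V to be negligible. A histogram is
called gamma-shaped when its JSD against the moment-matched gamma —
discretized over integer bins by CDF differencing — falls below 0.02; the
threshold is this package's construction (the criterion is not standard)
and is exposed as a parameter.

## Simulator

The Gillespie simulator is a validation oracle, not an inference engine:
one exact trajectory per cell from (0, 0, 0), sampled at a horizon of 10
slowest relaxation times (slowest of γ_p, γ_r, k_on+k_off; multiplier
configurable), giving an independent population snapshot comparable to
flow-cytometry data. Residual initial-condition bias at that horizon
(~e⁻¹⁰) is far below Monte-Carlo noise at the 10⁴–10⁵ cell counts used.
Runs whose projected event count (from steady-state mean propensities)
exceeds a cap (default 2·10⁹) are refused with guidance — exact SSA scales
poorly with molecule number, which is precisely why the inverse problem is
solved in moment space. Identical (rates, n_cells, seed) give
bit-identical samples.

## Synthetic data and what the tests do not show

The fixture generators produce: planted-truth targets whose five
enumerated coordinates sit exactly on search-lattice nodes (the sixth
solved from the mean, as the search itself would), regime panels
(constitutive, bursting, gamma-regime, low-count) verified by the forward
solver with rejection sampling, and a constructed conserved-ratio ensemble
for exercising degeneracy analytics. All are pure functions of their
arguments and a seed. Default draw windows sit at budding-yeast-like
magnitudes (RNA lifetimes of minutes–hours, protein loss dominated by
~90-minute dilution); the low-count panel is constrained to mean RNA ≤ 5
and mean protein ≤ 25 so the brute-force CME lattice stays below ~5·10³
states.

These synthetic inputs are exact realisations of the model. Passing tests
therefore demonstrate correctness of the mathematics and the search, not
robustness to what real cytometry data adds: autofluorescence background,
gating, measurement noise on moments (higher moments especially),
extrinsic cell-to-cell variability, and cell-cycle structure. The intended
experimental use is to widen the per-moment tolerance to the measured
moment error; none of that measurement layer is modelled here.

## Known limitations

* Moments above order 4 are not solved analytically (the fifth moment is
  available only as a sample moment from simulation — and for
  moment-matched ensembles it carries no additional signal).
* The search cost grows steeply with resolution and range width; the
  package scales the problem (resolution, two-decade windows) rather than
  approximating the algorithm.
* Exactly-on-boundary physiological ranges and rates spanning ≫ 12 decades
  can degrade conditioning; the solver warns rather than silently losing
  precision.
* Refractory/multi-ON promoter architectures, extrinsic noise and
  time-dependent moments are out of scope; the moment-and-search paradigm
  extends to any linear-propensity model, but only the two-state model is
  implemented.
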