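# Methods

## Model class and assumptions

A kinetic scheme is a finite, strongly connected, continuous-time Markov
chain.  States carry string labels; transitions carry strictly positive
base rates (units 1/time) and an `x_power` flag in {0, 1}.  The control
parameter x > 0 scales flagged rates linearly (mass action); "no
transition" is always encoded by edge absence, never by a zero rate,
because the tree-theorem products run over existing edges and a zero rate
would silently change the graph.  Time-varying rates, countably infinite
state spaces and multi-parameter perturbations are out of scope; a single
scalar x is assumed throughout.

The support of the perturbation is the set of states with at least one
outgoing x-dependent edge; its size m bounds every logarithmic steady-state
sensitivity.  This is purely structural: it depends on which edges carry x,
not on any rate value.

## Steady states by two independent routes

**Linear solve.**  `steady_state_linear` uses GTH (Grassmann–Taksar–
Heyman) elimination rather than a generic null-space solve.  GTH performs
no subtractions, so each stationary probability is obtained with
componentwise relative accuracy near machine precision even when
probabilities span many orders of magnitude — which they routinely do for
driven schemes with rate ratios of 10^6 and more.  The generator residual
‖Wπ‖∞ is checked against 1e-10 times the largest rate.

**Tree-theorem polynomials.**  The unnormalized stationary weight of state
k is the sum over spanning in-trees rooted at k of the product of edge
rates.  Each in-tree uses at most one outgoing edge per non-root state, so
the weight is a polynomial in x with nonnegative coefficients and degree
at most m.  Two backends compute these polynomials:

- *Enumeration* (small schemes): spanning trees of the undirected edge
  skeleton are enumerated exhaustively (union-find acyclicity over edge
  combinations), oriented toward each root, and kept when every oriented
  edge exists in the scheme.  The backend refuses schemes whose Kirchhoff
  spanning-tree count exceeds a cap (default 10^6); the count of
  undirected spanning trees upper-bounds the in-tree count for every root
  and is computable before any enumeration.
- *Interpolation* (all schemes): the weight of state k equals the
  determinant of −W(x) with row and column k deleted, so the polynomial is
  recovered by evaluating that minor at the m+1 geometric nodes
  x_j = 2^(j − ⌊m/2⌋) and interpolating.  Minors are computed by
  partial-pivot Gaussian elimination in extended (long double) precision —
  LAPACK determinants are double-only — and the Vandermonde system is
  solved with the Björck–Pereyra recurrences, which are well behaved for
  ordered positive nodes.  Coefficients below 1e-12 of the per-state
  maximum are structural zeros and are clipped; a coefficient more
  negative than 1e-6 of the maximum aborts with an error, since genuine
  tree polynomials are nonnegative.  An exact mode replaces both steps
  with rational arithmetic (base rates taken as exact binary fractions,
  Newton divided differences over rational nodes), which is the right tool
  when coefficients span very many orders of magnitude — e.g. nested
  hysteresis with s = 10^4, q = 10^-6.

Both backends must agree with each other and with GTH; the test suite
cross-checks 200 random schemes at 5 parameter values each with a
norm-relative discrepancy (max |Δπ| / max π) below 1e-8 (measured
~1e-14), and the enumeration route — a positive sum, hence componentwise
accurate — additionally agrees componentwise to better than 1e-8.
Componentwise accuracy of the interpolation route on states carrying
~1e-12 of the total mass is intrinsically limited (small coefficients are
differences of large minors); exact mode removes the limitation.

Polynomials are evaluated in the log domain (logsumexp over
log c_i + i log x), so distributions are well defined for any positive x
representable in floating point.

## Sensitivities and effective Hill coefficients

For positive observables A, B the ratio ⟨A⟩/⟨B⟩ is a ratio of
nonnegative-coefficient polynomials, and

    d log(⟨A⟩/⟨B⟩)/d log x = μ_A(x) − μ_B(x),

where μ is the coefficient-weighted mean degree, evaluated stably by
softmax in the log domain.  This makes every sensitivity exact; finite
differences appear only as an independent oracle in the tests (central
difference in log x, step 1e-5, agreement to 1e-5).  Each report carries
the support size m, the slack m − |value|, and the degree interval
[a_min − b_max, a_max − b_min], which provably contains the value.  For a
partition X, the chain rule gives d log π_X/d log x = (1 − π_X)(μ_A − μ_B),
and `check_support_bound` asserts the refined bound m(1 − π_X) with
tolerance 1e-9.

Three inequivalent effective-Hill definitions are implemented, all of
which are bounded by m:

- *midpoint*: twice the log-slope at the x where f is halfway between
  f(0+) and f(∞);
- *s90s10*: log 81 / log(S_0.9/S_0.1) where S_p solves f = p·f(∞).
  "Maximum value" is read as f(∞), the supremum of a monotone increasing
  curve; curves with f(0+) ≥ 0.1 f(∞) are rejected because the 10% point
  does not exist;
- *binding*: the log-slope of the odds ⟨n_b⟩/(n − ⟨n_b⟩), requiring
  per-state occupancy labels.

Monotonicity is a precondition, verified on a 64-point geometric grid over
x ∈ [1e-9, 1e9] — a check, not a proof.  Level equations are solved by
bisection in log x to absolute tolerance 1e-12 with the bracket
[1e-12, 1e12].  Scheme-backed curves carry exact limits read off the
extreme-degree coefficients, and exact derivatives; closed-form curves may
supply a derivative or fall back to a central difference with step 1e-6 in
log x.

At equilibrium (detailed balance, checked by the Kolmogorov cycle
criterion over a cycle basis with relative tolerance 1e-9), the identity
d log π_X/d log x = (⟨n_b⟩_X − ⟨n_b⟩_X̄)(1 − π_X) is computed from the
conditional occupancy means and verified against the exact derivative to
1e-8 on random detailed-balanced hypercubes.

## Model zoo and its saturating families

- *Independent sites*: site i binds at x/K_i, unbinds at 1; detailed
  balanced by construction.
- *Unordered binding*: the full 2^n hypercube with user-supplied flip
  rates; support 2^n − 1.
- *Nonequilibrium MWC*: two rings (CW/CCW) of occupancies 0..n with
  concerted flips; support 2n.  The equilibrium parameterization scales
  flip rates geometrically, (K_ccw/K_cw)^j, so every square cycle
  balances; the basal flip bias defaults to 0.01 so the clockwise bias
  rises from near 0 to near 1 and the S90/S10 estimator is well posed.
  The saturating family runs a hysteresis loop — climb CCW by binding,
  flip at full occupancy, descend CW by unbinding, flip back when empty —
  with the loop's two extreme states stabilized and the bottom flip
  weakened by ε = 1/λ.  As λ → ∞ the clockwise bias approaches a Hill
  function of coefficient 2n (measured 3.993 of 4 at λ = 10^8 for n = 2).
  A simpler family with strong flips at the extremes and no stabilization
  was tried first and plateaus near H ≈ 1.7: stabilization of the loop
  ends is essential, exactly as q is for nested hysteresis.
- *Hopfield proofreading*: the 3-state cycle with both dissociation edges
  of the wrong substrate carrying x = exp(Δ); ν = −d log(π_EW/π_E)/dΔ
  equals a tree-polynomial sensitivity because d/dΔ = d/d log x.  The
  saturating rates (1, λ², 1, 1, λ, λ³) follow from requiring the
  degree-2 terms to dominate π_E and the degree-0 terms to dominate π_EW;
  ν = 2 − O(1/λ).
- *Fence schemes and sensing*: x-dependent edges must cross the X/Y
  boundary (for KP fences, strictly Y → X).  The sensing error of an
  instantaneous count of R_T independent receptors is
  ε² = π_Y(1−π_Y)/(R_T (c dπ_Y/dc)²), bounded below by
  1/(R_T m² π_X(1−π_X)) ≥ 4/(R_T m²); both inequalities are asserted at
  computation time.
- *Nested hysteresis*: binding at site i requires all lower-numbered sites
  bound, unbinding requires them unbound; allowed flips at site i are
  slowed by s^(1−i) and keep binding/unbinding ratio x; every exit from
  the all-empty and all-full states is additionally slowed by q.  Only the
  gating rules, the timescale hierarchy and the ratio-x condition pin the
  construction; the per-edge constants chosen here (rate s^(1−i) for the
  unbinding direction) are the simplest realization.  In the s → ∞ limit
  the site marginals are x^(2^(i−1))/(1 + x^(2^(i−1))) and
  π_all = x^(2^n−1) / (1 + q·Σ_{j=1}^{2^n−2} x^j + x^(2^n−1)), approaching
  a Hill function with H = 2^n − 1 as q → 0.  At s = 10^4 the scheme's
  steady state is within 1% of the limit for x ∈ [0.5, 2] and n ≤ 4.

## Stochastic engine

Gillespie simulation uses one named PCG64 generator per trajectory,
inverse-transform exponential waiting times, and cumulative-rate search
for the next state, making trajectories bit-reproducible from their seed.
Master-equation propagation uses the matrix exponential of the generator;
for large t·‖W‖ the short-time propagator is squared repeatedly with
column renormalization, so probability is conserved to 1e-10 at any
stiffness.  Ergodicity is verified by comparing time-average occupancies
against the exact steady state within 3 batch-means standard errors.

## Synthetic data and what the tests do (and do not) show

Random schemes are built on a Hamiltonian-cycle backbone (strong
connectivity by construction, no rejection sampling) with Bernoulli extra
edges, log-uniform rates spanning six decades (10^±3), and Bernoulli
x-flags; detailed-balanced binding schemes draw state energies uniformly
on ±3 natural-log units, a spread wide enough that conditional occupancy
means differ meaningfully.  These fixtures probe the bounds across
structurally diverse graphs, but they are not calibrated to any measured
biochemistry: passing tests certify the mathematics and the numerics, not
that any particular biological system is described by these rate ranges.
The stochastic-consistency tests use rates within ±0.3 decades and
horizons of 2–3·10^4 time units (a few 10^4 jumps per trajectory), sizes
chosen so batch-means error bars are tight while the whole suite stays
fast; all random draws are fixed-seed and hypothesis tests are
derandomized, so results are reproducible run to run.

## Known limitations

- Single scalar perturbation only; no multi-parameter support.
- The float interpolation backend can reject schemes whose tree
  polynomials span more than ~12 orders of magnitude per state (it raises
  rather than returning clipped garbage); exact mode handles these.
- `is_detailed_balanced` tests a cycle basis at one x; for schemes whose
  imbalance depends on x it answers at the queried x only.
- The Gillespie engine is a straightforward Python loop (~4·10^5 jumps/s);
  it is meant for validation and illustration, not large-scale sampling.
- Hill estimators require monotone curves with finite limits; responses
  that peak in x are rejected, not analyzed.
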