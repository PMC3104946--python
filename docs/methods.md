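# Methods

## Models and state spaces

Both binding schemes are treated as continuous-time Markov chains on
integer particle-number configurations, assuming a well-mixed volume so
that counting particles suffices. A Hill configuration is
`c_H = (n0, nh, nA)`; an Adair-Klotz configuration is
`c_A = (n0, n1, ..., nh, nA)`. Two conservation laws (protein count `P0`,
ligand count `L0`) make both reachable spaces finite: the Hill space is
the one-dimensional chain `(P0−i, i, L0−h·i)`, `i = 0..min(P0, ⌊L0/h⌋)`,
and the Adair-Klotz space holds every occupancy vector of `P0` proteins
over 0..h bound ligands whose bound-ligand total does not exceed `L0`.

State order is fixed and documented so indices are stable across runs:
Hill by ascending complex count, Adair-Klotz by descending lexicographic
occupancy vector; index 0 is always the pure initial state. The Hill
coefficient is restricted to integers ≥ 1 and the number of Adair-Klotz
steps is always taken equal to it, which is what makes the one-to-one
common-state correspondence possible. Degenerate inputs (`P0 = 0`, or
`L0 < h`) yield a valid single-state or forward-reaction-free space
rather than an error.

## Propensities

Propensities are mass-action combination counts with count-based rate
constants (no volume factor):

* Hill forward `α · n0 · C(nA, h)` — one factor for the protein choice and
  one for the number of ways to pick the `h` ligands that bind
  simultaneously; back `β · nh`.
* Adair-Klotz step i forward `α_i · n_{i−1} · nA`; back `β_i · n_i`.

The combinatorial `C(nA, h)` convention for the one-step reaction is the
one under which lifetime matching (below) gives `α = α_1 L0 / C(L0, h)`,
e.g. `α = 0.5 /s` for `α_1 = 1 /s`, `L0 = 5` at both h = 2 and h = 3; the
alternatives `nA^h` or the falling factorial are inconsistent with that
calibration.

## Solvers

The generator is assembled dense with the column convention
`dP/dt = Q P`; columns sum to zero by construction. The primary solver is
the scaling-and-squaring matrix exponential, exact to machine precision
at these state-space sizes (≤ ~10² states); uniform time grids reuse a
single step propagator. Stationary distributions solve `Qπ = 0, Σπ = 1`
by replacing one balance row with the normalization row, with the residual
`‖Qπ‖∞` required below 1e-12 relative to the generator's largest entry.
Round-off negatives above −1e-12 are clipped to zero and the vector
renormalized; anything more negative is an error.

Two independent backends cross-check the solution:

* **Laplace/Durbin.** The transform `F(s) = (sI − Q)^{-1} p0` is inverted
  with Durbin's trapezoidal Fourier-series formula. Because the
  distribution itself does not decay, the centered deviation
  `r(t) = p(t) − π` is inverted instead (its transform is
  `(sI − Q)^{-1}(p0 − π)`), which removes aliasing from the non-decaying
  part. The evaluation time is placed at the midpoint of the expansion
  interval (`T = t`), making the series alternating, and the
  conditionally convergent tail is Euler-summed (binomial averaging over
  a 12-term window). The damping parameter is `a = 9.2/T`
  (aliasing ~ e^{-2aT} ≈ 1e-8). The number of quadrature points starts at
  64 and is doubled until the largest relative change of any entry falls
  below 1% (entries below 1e-6 compared absolutely at that floor), with a
  hard cap of 20 doublings; this 1% doubling rule is also the acceptance
  bar for expm-vs-Durbin agreement.
* **Gillespie SSA.** A direct-method simulator, vectorised over
  replicates and driven by a single seeded `numpy.random.Generator`, so
  repeat runs with the same seed are bit-identical (one shared stream
  rather than per-replicate substreams; the vectorised lock-step advance
  makes the call order, and hence the output, deterministic). Used only
  as a Monte-Carlo oracle in tests (10⁵ replicates, total-variation
  distance < 0.01).

## Similarity measures

With `ℐ` the image map from Hill states to intermediate-free Adair-Klotz
states, the measures are

* `δ = Σ sqrt(P_H(c) P_A(ℐ(c)))` (Bhattacharyya overlap on common states),
* `δ̄ = Σ_{complement} P_A` (intermediate occupancy),
* `δ̃ = Σ sqrt(P_H(c) P̃_A(c))` with `P̃_A` the projection renormalized to
  unit mass,

satisfying `δ = sqrt(1 − δ̄) · δ̃` identically and `0 ≤ δ, δ̄, δ̃ ≤ 1`.
Probabilities are clipped to [0, 1] before square roots to guard against
−1e-15 round-off. When the image mass is ≤ 1e-12 the shape of the
projected distribution is undefined and `δ̃` raises rather than returning
a silent 0, which would corrupt the factorization identity.

## Calibration

At equilibrium `δ∞` depends only on the dissociation constants, so both
models are built with unit forward rates and back rates set by the K's.
`K0` is optimized by a coarse 61-point log-spaced pre-scan over
[1e-6, 1e6] (a guard against local maxima — global unimodality is not
assumed) followed by golden-section search on log10 K0 to a relative
tolerance of 1e-8. A flat objective returns the scan-range midpoint with
a warning flag instead of an arbitrary interior point. For time-dependent
runs `α` is fixed by equating the initial state's total escape rate in
the two models (`α P0 C(L0,h) = α_1 P0 L0`), and `β = K0_opt · α`.

Parameter-space maps evaluate `δ_max` per grid point with an independent
`optimize_K0` call (the per-point Adair-Klotz stationary distribution is
computed once and reused across the K0 search). Default grids are
log-spaced, 41 points per axis over [1e-2, 1e2]; the h=4 cooperativity
scan uses K1 ∈ [1, 100] (50 points) × ξ ∈ [1.05, 100] (40 points). Level
sets (default level 0.9, the threshold used for the safe-substitution
region) are extracted by marching squares with linear interpolation
(`skimage.measure.find_contours`), with fractional grid indices mapped to
parameter values by interpolating in log10 of the axis values.

Peak location in a sampled time series takes the first interior local
maximum (falling back to the global argmax) and refines it by parabolic
interpolation through the three surrounding points; an edge maximum is
flagged as non-interior rather than refined.

The Hill dose-response utility uses `φ(a) = a^h/(K0 + a^h)`; the
convention `a^h/(K0^h + a^h)` differs only by reparameterising K0 and
nothing downstream depends on the choice.

## Reference conditions and problem sizes

All reference computations use `P0 = 2`, `L0 = 5` — deliberately small
copy numbers, where intrinsic noise matters most and the comparison of
full distributions is exact. Time courses use t ∈ [0, 2] s with 401
uniform points (step 0.005 s), which resolves the complement-occupancy
peak near t ≈ 0.25 s and the approach to equilibrium for the reference
rate sets. The h=4 scan above is 2000 grid points, each an independent
K0 optimization over an 11-state Adair-Klotz space.

## What the tests do and do not show

The suite verifies exact structural properties (enumeration against
brute-force filters for h ≤ 4, P0 ≤ 3, L0 ≤ 8; probability conservation;
the factorization identity to 1e-10; detailed balance on the Hill chain;
h = 1 equivalence of the two schemes) and cross-backend agreement (expm
vs Laplace/Durbin within 1%; SSA within Monte-Carlo error). These
establish correctness of the computational machinery at small copy
numbers. They do not address large copy numbers or h ≥ 5 (state-space
growth), mixed initial states, or spatially inhomogeneous systems — the
well-mixed assumption is built into the propensities.

## Known limitations

* State spaces are enumerated and stored dense; the approach is exact
  but exponential in h and polynomial in copy numbers, so it targets the
  low-copy-number regime.
* Calibration optimizes only the equilibrium similarity plus the lifetime
  rule; `(α, β)` are not jointly fitted to the full time course.
* The Durbin backend assumes the chain has a unique stationary
  distribution (guaranteed here: all reactions reversible and the pure
  initial state communicates with the whole space).
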