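# Methods

## Model and scope

The package solves the one-phase oxygen-absorption moving-boundary problem
`u_t = u_xx − g(x)` on `0 < x < s(t)` with constant boundary data: flux `h`
at the sealed surface, Dirichlet value `p` and Neumann value `q` at the
front, and a polynomial initial profile `φ(x)`. The packaged default is the
classic instance `g = 1`, `p = q = h = 0`, `φ = (1 − x)²/2`, `s(0) = 1`
(all quantities dimensionless; the scaling absorbs the diffusivity and the
absorption rate). Time-dependent boundary data, nonlinear absorption,
two-phase configurations and multi-dimensional domains are out of scope.

## Exact jet algebra

Decomposition components are polynomials in `(s − x)` whose coefficients
are rational-coefficient polynomials in the jets `s, s′, s″, …` of the
front. All symbolic arithmetic is exact (`fractions.Fraction`); floating
point enters only at evaluation time. This matters because the
deliverable of the symbolic chain is a set of *exact* integer/rational
coefficients (the factorial denominators of the components, the seven
terms of the front ODE, the integer cubic), and any floating-point
intermediate would turn coefficient identity into a tolerance question.
Two conventions fix the calculus:

* `x` is held fixed under `d/dt`, so `d/dt (s − x) = s′` — required for
  the recursion to produce `u₁ = s′(s−x)³/3!`;
* polynomials given in `x` are rebased onto the `(s − x)` basis on entry,
  which makes the inverse operator diagonal:
  `(s−x)^k → (s−x)^{k+2}/((k+1)(k+2))`.

Jet orders are unbounded; component `u_n` involves jets up to order `n`,
so the truncation order bounds the jet order automatically.

## Truncation and the residual diagnostic

The default truncation is N = 2 (three components, the fifth-degree
profile) — the operating point at which the closed-form boundary results
below hold. Higher N is supported by the algebra. No error bound for the
truncation is claimed; instead the package exposes the PDE residual of the
partial sum, which by the telescoping structure of the recursion equals
`∂u_N/∂t` exactly. The residual is a consistency check, not a convergence
rate: the series' convergence behaviour on this problem is not
characterised here.

## Front dynamics

Integrating the PDE over the domain and using the Leibniz rule gives the
flux balance `d/dt ∫₀ˢ u dx + ∫₀ˢ g dx + h − q = 0` (the Leibniz boundary
term carries a factor `p` and the implementation therefore requires
`p = 0`). Substituting the truncated profile yields a polynomial equation
in the jets; the common factor `s` is divided out, which is recorded as a
normalisation valid while `s > 0` — i.e. on the whole validity window.

Under the ansatz `s = √(1 + 2λt)` every jet satisfies
`s^(j) = c_j λ^j s^(1−2j)` with `c_j = (3 − 2j) c_{j−1}`, `c₀ = 1`
(c = 1, 1, −1, 3, −15, …). Each monomial of the front ODE must then shed
its `s` powers exactly; a monomial that does not is reported as a
structural error rather than silently dropped. For N = 2 the reduction
gives the integer cubic `λ³ + 6λ² + 24λ + 48` after clearing denominators.

The cubic's single real root is found by bisection/secant (Brent) inside a
Cauchy bound; a cubic with three real roots demands an explicit bracket
(the oxygen cubic never hits this path). Two λ modes exist:

* `exact_root` (library default): λ = −3.192143275966643;
* `paper_rounded`: λ = −3.2 exactly, the rounding with which the standard
  benchmark tables were generated — verified by the closed-form surface
  factor `1/2 + λ/6 + λ²/30` being exactly `77/250 = 0.308` at λ = −16/5.

Table-reproduction commands default to `paper_rounded`. The ansatz is
written with the radical, `s = √(1 + 2λt)`: the jet identities
(`ss′ = λ`, `s″s³ = −λ²`) and the tabulated values are only consistent
with the square root, and the extinction time `−1/(2λ) = 0.15625`
(λ = −3.2) follows.

When comparing regenerated table entries against their published values,
the tolerance is one unit of each entry's printed precision (1e−5 for
5-decimal entries, 1e−4 for 4-decimal ones): inspection shows some
published 4-decimal entries are truncated rather than rounded
(0.78485667 printed as 0.7848), so a uniform tighter band would reject
values that are in fact exact. Surface-concentration entries agree to
5e−6 (they are exact products).

## t-direction decomposition and the implicit front law

Inverting `d/dt` from the initial condition instead gives `u₀ = φ − g·t`,
`u_{n+1} = ∫₀ᵗ (u_n)_xx dt`. This scheme needs no boundary symbol and uses
a plain bivariate `(x, t)` polynomial representation. For the oxygen data
it terminates after two components and sums to the stationary profile
`(1 − x)²/2`. Feeding that profile into the same flux balance gives
`ds/dt = −2s/(1 − s)²`, singular at `s(0) = 1` (infinite initial slope).
The implicit integral `ln s − 2s + s²/2 = −2t − 3/2` is therefore the
primary solver: its left side is strictly increasing on `(0, 1]`
(derivative `(1 − s)²/s`), so the root is unique; it is bracketed
analytically by `[e^{−2t−3/2}, min(1, e^{−2t})]` (since
`2s − s²/2 ∈ (0, 3/2]` on `(0, 1]`) and solved by Brent's method with a
residual check at 1e−12. ODE integration is provided only as a
cross-check, started past the singular layer (at `s₀ = 0.9`; starting
nearer to 1 puts the slope in the 10⁶ range, which a fixed step cannot
follow).

## Comparators

The front-centred (Crank–Gupta) and surface-centred (Gupta–Banik) quartic
heat-balance profiles and their moment ODEs are implemented verbatim as
comparators, integrated by classical fixed-step RK4 (default step 1e−4,
far below table precision). Three caveats, all documented in code:

* the front-centred surface law is implemented as `1/2 − 2√(t/π)`: with
  the radical it reproduces the published surface column to 6 decimals;
  without it, it cannot.
* the front-centred front ODE `s′ = (20 + 8u₀′)s/(8u₀ + s²)` is kept
  exactly as printed and flagged: its numerator changes sign near
  t ≈ 0.063, producing a growing front inconsistent with the tabulated
  shrinking front — a suspected transcription typo. Its output is never
  used as a benchmark.
* the surface-centred ODE pair is *not* exactly consistent with the first
  moment law alone: symbolic differentiation of the moment
  `M = s²(s² + 12u₀)/120` along the pair leaves the residual
  `108u₀²/(5(5s² + 24u₀))` (≈ 0.123 at the start state). The
  `moment_balance_residual` diagnostic reports this quantity; its test
  asserts agreement with the independently derived closed form, not with
  zero.

The surface-centred trajectory starts at `t* = 4/(25π)` with `s = 1` and
`u₀ = 1/2 − 4/(5π)` (the front-centred surface value at `t*`), which makes
the admissibility condition `s² − 4u₀ = 0` marginal and the initial front
velocity exactly zero. Trajectory values of either comparator are not
benchmark targets.

## Numerical choices

* Root-finding tolerances: cubic root to |p(λ)| < 1e−12; implicit law to
  residual ≤ 1e−12 with a tiny absolute `xtol` so the relative criterion
  governs even for roots near zero (at t = 5 the root is ≈ 1e−5 and an
  absolute `xtol` of 1e−16 alone would already cost five digits of
  residual).
* CSV output uses 6 significant digits (matching the tables' precision)
  with a full-precision flag; byte output is deterministic.
* Degenerate inputs: a zero profile degenerates the flux balance to a
  constant equation (returned, not raised); times outside a trajectory's
  validity window raise errors naming the extinction time; missing table
  cells are written as empty CSV fields.

## What the tests do and do not show

The problem has no external data; all inputs are scalar parameters and
the fixed initial profile, so there is no synthetic-data gap to flag. The
structural tests (telescoping residual, ring axioms, operator-vs-
quadrature, boundary-condition identities) are exact or near machine
precision and hold for the randomized problem family (polynomial `g` up
to degree 3, rational `p`, `q`), not just the oxygen instance. What the
suite does *not* establish is the accuracy of the truncated profile
against the true solution of the PDE — only against the published
benchmark values, which are themselves approximations of the same order.
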