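# oxdiff

Adomian decomposition solver for the Crank–Gupta oxygen-diffusion
moving-boundary problem.

## The problem

Oxygen diffuses into a slab of tissue that absorbs it at a constant rate.
After the surface is sealed, the concentration `u(t, x)` obeys

    u_t = u_xx − 1,          0 < x < s(t),
    u_x(t, 0) = 0,                       (sealed surface)
    u(t, s(t)) = 0,   u_x(t, s(t)) = 0,  (moving front)
    u(0, x) = (1 − x)² / 2,   s(0) = 1,

where `s(t)` is the unknown depth still containing oxygen. Both the value
and the flux vanish at the front, so — unlike a classical Stefan problem —
no explicit equation for the front velocity exists; the front is pinned
implicitly. This is a standard benchmark for moving-boundary methods, of
interest to anyone working on free-boundary parabolic PDEs (tissue oxygen
transport, melting/solidification, fluid absorption).

## The method

The package constructs the Adomian decomposition `u = Σ uₙ` by repeatedly
applying the inverse spatial operator (a double integral from `x` to
`s(t)`) to the time derivative of the previous component, carrying all
coefficients as **exact rationals** in the jets `s, s′, s″, …` of the
boundary:

    u₀ = (s−x)²/2!,   u₁ = s′(s−x)³/3!,   u₂ = s′²(s−x)⁴/4! + s″(s−x)⁵/5!.

Truncating after u₂ gives a fifth-degree profile that satisfies the two
front conditions identically. Substituting it into the integrated flux
balance `d/dt ∫₀ˢ u dx = −s` yields a nonlinear ODE in the jets of `s`;
the ansatz `s(t) = √(1 + 2λt)` collapses that ODE to the cubic

    λ³ + 6λ² + 24λ + 48 = 0,

whose unique real root is λ = −3.192143275966643 (≈ −3.2). The front
position and surface concentration follow in closed form:
`s(t) = √(1 + 2λt)` and `u(t, 0) = s²(1/2 + λ/6 + λ²/30)` (= 0.308·s² at
λ = −3.2), valid until the front extinguishes at `t = −1/(2λ)`.

A second decomposition in the *t*-direction gives the stationary profile
`(1 − x)²/2` and the implicit front law `ln s − 2s + s²/2 = −2t − 3/2`,
solved here by bracketed root-finding. Classical heat-balance
integral-method approximations (quartic profiles with moment-derived
ODEs, integrated by fixed-step RK4) are included as comparators.

## Worked example

```
$ oxdiff derive
u_0 = ProfileSeries([JetPoly(1/2)]*(s-x)^2)
u_1 = ProfileSeries([JetPoly(1/6*s1)]*(s-x)^3)
u_2 = ProfileSeries([JetPoly(1/24*s1^2)]*(s-x)^4 + [JetPoly(1/120*s2)]*(s-x)^5)
boundary ODE lhs = JetPoly(1 + 1/2*s*s1 + 1/6*s^2*s1^2 + 1/24*s^3*s1^3 + 1/24*s^3*s2 + 1/40*s^4*s1*s2 + 1/720*s^5*s3)
ansatz polynomial coefficients (l^3..l^0) = (1, 6, 24, 48)
real root lambda = -3.192143275966643
```

`s1` denotes s′, `s2` denotes s″, and so on; the ODE line is the exact
flux-balance equation `ss′/2! + s²s′²/3! + s³s″/4! + s³s′³/4! +
3s⁴s′s″/5! + s⁵s‴/6! + 1 = 0` with each fraction carried exactly.

```
$ oxdiff solve --lambda-mode paper_rounded --times 0.04,0.08,0.12
lambda = -3.200000000000000
extinction time = 0.156250
t,s,u(t,0)
0.04,0.862554,0.229152
0.08,0.698570,0.150304
0.12,0.481664,0.071456
```

Each row gives the front depth `s(t)` and surface concentration `u(t,0)`:
at t = 0.04 the oxygenated layer has shrunk to 86 % of its initial depth
and the sealed-surface concentration has fallen from 0.5 to 0.229.
`oxdiff tdir` prints the implicit-law trajectory, `oxdiff compare` the
integral-method comparator, and `oxdiff tables` writes any of the tables
or figure curves as CSV.

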