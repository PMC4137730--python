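"""Independent sympy-based oracles for the exact-algebra tests.

Everything here re-derives quantities with sympy's own calculus (functions
of t, definite integrals with a variable limit), independently of the
package's jet-polynomial representation, so structural bugs in the package
algebra cannot cancel out of the comparison.
"""

from __future__ import annotations

import sympy as sp

T = sp.Symbol("t")
X = sp.Symbol("x")
S = sp.Function("s")(T)


def jetpoly_to_sympy(poly):
    """Map a JetPoly onto derivatives of the sympy function s(t)."""
    total = sp.Integer(0)
    for mono, coef in poly.terms.items():
        term = sp.Rational(coef.numerator, coef.denominator)
        for j, e in mono.exponents:
            term *= sp.diff(S, T, j) ** e
        total += term
    return total


def profile_to_sympy(series):
    """Map a ProfileSeries onto an expression in x, t and s(t)."""
    total = sp.Integer(0)
    for k, poly in series.coeffs.items():
        total += jetpoly_to_sympy(poly) * (S - X) ** k
    return total


def adm_recursion_sympy(n_components: int):
    """Run the x-direction decomposition recursion entirely in sympy.

    u_0 = (s-x)^2/2 (oxygen data), u_{k+1} = double integral from x to s
    of du_k/dt.  Returns the list of components as sympy expressions.
    """
    xi = sp.Symbol("xi")
    comps = [(S - X) ** 2 / 2]
    for _ in range(n_components - 1):
        integrand = sp.diff(comps[-1], T)
        inner = sp.integrate(integrand.subs(X, xi), (xi, X, S))
        outer = sp.integrate(inner.subs(X, xi), (xi, X, S))
        comps.append(sp.expand(outer))
    return comps


def sympy_equal(a, b) -> bool:
    return sp.simplify(sp.expand(a - b)) == 0
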