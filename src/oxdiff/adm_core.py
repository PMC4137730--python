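"""Adomian decomposition schemes for the oxygen diffusion moving-boundary problem.

The governing equation is ``u_t = u_xx - g(x)`` on ``0 < x < s(t)`` with a
prescribed flux ``h`` at the sealed surface ``x = 0``, Dirichlet value ``p``
and Neumann value ``q`` at the moving boundary ``x = s(t)``, and initial
profile ``phi(x)``.  The classic oxygen absorption problem is the special
case ``g = 1``, ``p = q = h = 0``, ``phi = (1 - x)**2 / 2``.

Two decompositions are provided:

* the **x-direction** scheme, inverting ``d^2/dx^2`` with the double
  integral from ``x`` to ``s(t)``, which yields profile components that are
  polynomials in ``(s - x)`` with boundary-jet coefficients;
* the **t-direction** scheme, inverting ``d/dt`` from the initial condition,
  which for the oxygen problem terminates after two components and returns
  the stationary profile ``(1 - x)**2 / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

from .jet_algebra import (
    JetPoly,
    ProfileSeries,
    RationalLike,
    series_double_integral,
    series_time_derivative,
    series_x_derivative,
    x_polynomial_to_series,
)

__all__ = [
    "ProblemSpec",
    "ADMExpansion",
    "XTPolynomial",
    "oxygen_problem",
    "x_direction_components",
    "truncated_profile",
    "pde_residual_series",
    "t_direction_components",
    "t_direction_solution",
]


@dataclass(frozen=True)
class ProblemSpec:
    """Data of the general moving-boundary diffusion problem.

    ``g_coeffs`` and ``phi_coeffs`` are polynomial coefficients in x
    (ascending powers).  ``p``, ``q``, ``h`` are the constant boundary data;
    the oxygen problem has all three equal to zero.
    """

    g_coeffs: tuple[Fraction, ...] = (Fraction(1),)
    p: Fraction = Fraction(0)
    q: Fraction = Fraction(0)
    h: Fraction = Fraction(0)
    phi_coeffs: tuple[Fraction, ...] = (
        Fraction(1, 2),
        Fraction(-1),
        Fraction(1, 2),
    )

    @staticmethod
    def make(
        g_coeffs: Sequence[RationalLike] = (1,),
        p: RationalLike = 0,
        q: RationalLike = 0,
        h: RationalLike = 0,
        phi_coeffs: Sequence[RationalLike] = (
            Fraction(1, 2),
            -1,
            Fraction(1, 2),
        ),
    ) -> "ProblemSpec":
        return ProblemSpec(
            g_coeffs=tuple(Fraction(c) for c in g_coeffs),
            p=Fraction(p),
            q=Fraction(q),
            h=Fraction(h),
            phi_coeffs=tuple(Fraction(c) for c in phi_coeffs),
        )


def oxygen_problem() -> ProblemSpec:
    """The oxygen absorption problem: g=1, p=q=h=0, phi=(1-x)^2/2."""
    return ProblemSpec()


@dataclass(frozen=True)
class ADMExpansion:
    """Ordered decomposition components u_0 ... u_N of the x-direction scheme."""

    components: tuple[ProfileSeries, ...]
    truncation_order: int

    def __post_init__(self):
        if len(self.components) != self.truncation_order + 1:
            raise ValueError("components must be u_0 ... u_N")


def x_direction_components(problem: ProblemSpec, N: int) -> ADMExpansion:
    """Run the x-direction recursion to order N.

    ``u_0 = p - q (s - x) + Lxx^{-1} g`` and ``u_{n+1} = Lxx^{-1} du_n/dt``
    where ``Lxx^{-1}`` is the double integral from x to s(t).  Component
    ``u_n`` involves boundary jets up to order n.
    """
    if N < 0:
        raise ValueError("truncation order must be non-negative")
    u0 = (
        ProfileSeries.monomial(0, problem.p)
        + ProfileSeries.monomial(1, -problem.q)
        + series_double_integral(x_polynomial_to_series(problem.g_coeffs))
    )
    comps = [u0]
    for _ in range(N):
        comps.append(series_double_integral(series_time_derivative(comps[-1])))
    return ADMExpansion(tuple(comps), N)


def truncated_profile(e: ADMExpansion) -> ProfileSeries:
    """Partial sum u_0 + ... + u_N of the expansion."""
    total = ProfileSeries.zero()
    for c in e.components:
        total = total + c
    return total


def pde_residual_series(e: ADMExpansion, problem: ProblemSpec | None = None) -> ProfileSeries:
    """Symbolic residual ``u_t - u_xx + g`` of the truncated sum.

    By the telescoping structure of the recursion this equals
    ``d u_N / dt`` exactly — the input the next component would absorb —
    whenever p and q are constants, giving an internal consistency
    diagnostic for the truncation.
    """
    if problem is None:
        problem = oxygen_problem()
    u = truncated_profile(e)
    g = x_polynomial_to_series(problem.g_coeffs)
    return (
        series_time_derivative(u)
        - series_x_derivative(series_x_derivative(u))
        + g
    )


# ---------------------------------------------------------------------------
# t-direction scheme: bivariate polynomials in x and t, no boundary symbol
# ---------------------------------------------------------------------------

class XTPolynomial:
    """Exact bivariate polynomial in x and t: ``terms[(i, j)] * x**i * t**j``."""

    __slots__ = ("terms",)

    def __init__(self, terms: Mapping[tuple[int, int], RationalLike] | None = None):
        clean: dict[tuple[int, int], Fraction] = {}
        if terms:
            for key, c in terms.items():
                c = Fraction(c)
                if c != 0:
                    clean[key] = clean.get(key, Fraction(0)) + c
        self.terms = {k: c for k, c in clean.items() if c != 0}

    def __add__(self, other: "XTPolynomial") -> "XTPolynomial":
        terms = dict(self.terms)
        for k, c in other.terms.items():
            terms[k] = terms.get(k, Fraction(0)) + c
        return XTPolynomial(terms)

    def __sub__(self, other: "XTPolynomial") -> "XTPolynomial":
        return self + XTPolynomial({k: -c for k, c in other.terms.items()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, XTPolynomial):
            return NotImplemented
        return self.terms == other.terms

    def __hash__(self):
        return hash(frozenset(self.terms.items()))

    def is_zero(self) -> bool:
        return not self.terms

    def d2dx2(self) -> "XTPolynomial":
        return XTPolynomial(
            {(i - 2, j): c * i * (i - 1) for (i, j), c in self.terms.items() if i >= 2}
        )

    def dt(self) -> "XTPolynomial":
        return XTPolynomial(
            {(i, j - 1): c * j for (i, j), c in self.terms.items() if j >= 1}
        )

    def integrate_t(self) -> "XTPolynomial":
        """Antiderivative in t vanishing at t = 0."""
        return XTPolynomial(
            {(i, j + 1): c * Fraction(1, j + 1) for (i, j), c in self.terms.items()}
        )

    def evaluate(self, x: float, t: float) -> float:
        return sum(float(c) * x**i * t**j for (i, j), c in self.terms.items())

    def __repr__(self) -> str:
        if not self.terms:
            return "XTPolynomial(0)"
        parts = [
            f"{c}*x^{i}*t^{j}" for (i, j), c in sorted(self.terms.items())
        ]
        return "XTPolynomial(" + " + ".join(parts) + ")"


def t_direction_components(problem: ProblemSpec, N: int) -> list[XTPolynomial]:
    """t-direction recursion: ``u_0 = phi(x) - g(x) t``, ``u_{n+1} = int_0^t (u_n)_xx dt``.

    For the oxygen problem the scheme terminates: u_0 = (1-x)^2/2 - t,
    u_1 = t, and every later component is identically zero.
    """
    if N < 0:
        raise ValueError("truncation order must be non-negative")
    u0 = XTPolynomial(
        {(i, 0): c for i, c in enumerate(problem.phi_coeffs)}
    ) + XTPolynomial({(i, 1): -c for i, c in enumerate(problem.g_coeffs)})
    comps = [u0]
    for _ in range(N):
        comps.append(comps[-1].d2dx2().integrate_t())
    return comps


def t_direction_solution(problem: ProblemSpec, N: int) -> XTPolynomial:
    """Partial sum of the t-direction components."""
    total = XTPolynomial()
    for c in t_direction_components(problem, N):
        total = total + c
    return total
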