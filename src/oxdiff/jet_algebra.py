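"""Exact symbolic algebra for moving-boundary profile series.

The Adomian decomposition of the oxygen diffusion problem produces spatial
profiles of the form ``sum_k c_k(t) * (s - x)**k`` where ``s(t)`` is the
(unknown) moving boundary and each coefficient ``c_k`` is a polynomial with
rational coefficients in the *jets* of the boundary: ``s, s', s'', ...``.
This module implements that coefficient ring (:class:`JetPoly`), the series
container (:class:`ProfileSeries`) and the calculus operations the
decomposition recursion needs: time differentiation (with ``d/dt s^(j) =
s^(j+1)`` and ``x`` held fixed, so ``d/dt (s - x) = s'``), the double
spatial integral from ``x`` to ``s``, and integration over ``[0, s]``.

All coefficient arithmetic is exact (:class:`fractions.Fraction`); floating
point enters only through :func:`series_evaluate`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, Union

RationalLike = Union[int, Fraction]

__all__ = [
    "JetMonomial",
    "JetPoly",
    "ProfileSeries",
    "jet_time_derivative",
    "series_time_derivative",
    "series_x_derivative",
    "series_double_integral",
    "series_integral_zero_to_s",
    "x_polynomial_to_series",
    "series_evaluate",
]


@dataclass(frozen=True)
class JetMonomial:
    """A monomial in the boundary jets, e.g. ``s * s''**2``.

    ``exponents`` maps jet order (0 for ``s``, 1 for ``s'``, ...) to a
    positive exponent, stored as a sorted tuple of pairs so the monomial is
    hashable.  The empty tuple is the constant monomial 1.
    """

    exponents: tuple[tuple[int, int], ...] = ()

    @staticmethod
    def from_map(exps: Mapping[int, int]) -> "JetMonomial":
        items = tuple(sorted((j, e) for j, e in exps.items() if e != 0))
        for j, e in items:
            if j < 0 or e < 0:
                raise ValueError(f"invalid jet monomial entry {j}^{e}")
        return JetMonomial(items)

    def as_map(self) -> dict[int, int]:
        return dict(self.exponents)

    def __mul__(self, other: "JetMonomial") -> "JetMonomial":
        exps = self.as_map()
        for j, e in other.exponents:
            exps[j] = exps.get(j, 0) + e
        return JetMonomial.from_map(exps)

    def max_jet_order(self) -> int:
        """Highest jet order present; -1 for the constant monomial."""
        return max((j for j, _ in self.exponents), default=-1)

    def evaluate(self, jets: Sequence[float]) -> float:
        val = 1.0
        for j, e in self.exponents:
            if j >= len(jets):
                raise ValueError(
                    f"jet order {j} required but only {len(jets)} values supplied"
                )
            val *= jets[j] ** e
        return val

    def label(self) -> str:
        """Canonical text form, e.g. ``s^2*s1`` for s**2 * s'."""
        if not self.exponents:
            return "1"
        parts = []
        for j, e in self.exponents:
            base = "s" if j == 0 else f"s{j}"
            parts.append(base if e == 1 else f"{base}^{e}")
        return "*".join(parts)


class JetPoly:
    """Polynomial in the boundary jets with exact rational coefficients."""

    __slots__ = ("terms",)

    def __init__(self, terms: Mapping[JetMonomial, RationalLike] | None = None):
        clean: dict[JetMonomial, Fraction] = {}
        if terms:
            for mono, coef in terms.items():
                c = Fraction(coef)
                if c != 0:
                    clean[mono] = clean.get(mono, Fraction(0)) + c
        self.terms = {m: c for m, c in clean.items() if c != 0}

    # -- constructors ---------------------------------------------------
    @staticmethod
    def zero() -> "JetPoly":
        return JetPoly()

    @staticmethod
    def constant(c: RationalLike) -> "JetPoly":
        return JetPoly({JetMonomial(): Fraction(c)})

    @staticmethod
    def jet(order: int, power: int = 1) -> "JetPoly":
        """The single jet symbol s^(order) raised to ``power``."""
        return JetPoly({JetMonomial.from_map({order: power}): Fraction(1)})

    # -- ring operations ------------------------------------------------
    def __add__(self, other: "JetPoly") -> "JetPoly":
        terms = dict(self.terms)
        for m, c in other.terms.items():
            terms[m] = terms.get(m, Fraction(0)) + c
        return JetPoly(terms)

    def __neg__(self) -> "JetPoly":
        return JetPoly({m: -c for m, c in self.terms.items()})

    def __sub__(self, other: "JetPoly") -> "JetPoly":
        return self + (-other)

    def __mul__(self, other: "JetPoly | RationalLike") -> "JetPoly":
        if isinstance(other, (int, Fraction)):
            return JetPoly({m: c * Fraction(other) for m, c in self.terms.items()})
        out: dict[JetMonomial, Fraction] = {}
        for m1, c1 in self.terms.items():
            for m2, c2 in other.terms.items():
                m = m1 * m2
                out[m] = out.get(m, Fraction(0)) + c1 * c2
        return JetPoly(out)

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, (int, Fraction)):
            other = JetPoly.constant(other)
        if not isinstance(other, JetPoly):
            return NotImplemented
        return self.terms == other.terms

    def __hash__(self):
        return hash(frozenset(self.terms.items()))

    def __bool__(self) -> bool:
        return bool(self.terms)

    # -- queries ---------------------------------------------------------
    def is_zero(self) -> bool:
        return not self.terms

    def max_jet_order(self) -> int:
        return max((m.max_jet_order() for m in self.terms), default=-1)

    def coefficient(self, exps: Mapping[int, int]) -> Fraction:
        return self.terms.get(JetMonomial.from_map(exps), Fraction(0))

    def evaluate(self, jets: Sequence[float]) -> float:
        return sum(float(c) * m.evaluate(jets) for m, c in self.terms.items())

    def multiply_jet_power(self, order: int, power: int) -> "JetPoly":
        """Multiply every term by s^(order)**power."""
        shift = JetMonomial.from_map({order: power})
        return JetPoly({m * shift: c for m, c in self.terms.items()})

    def __repr__(self) -> str:
        if not self.terms:
            return "JetPoly(0)"
        parts = [
            f"{c}*{m.label()}" if m.exponents else f"{c}"
            for m, c in sorted(self.terms.items(), key=lambda kv: kv[0].exponents)
        ]
        return "JetPoly(" + " + ".join(parts) + ")"

    def to_json_obj(self) -> dict[str, str]:
        return {
            m.label(): f"{c.numerator}/{c.denominator}"
            for m, c in sorted(self.terms.items(), key=lambda kv: kv[0].exponents)
        }


class ProfileSeries:
    """Finite series ``sum_k c_k(t) * (s - x)**k`` with JetPoly coefficients."""

    __slots__ = ("coeffs",)

    def __init__(self, coeffs: Mapping[int, JetPoly] | None = None):
        clean: dict[int, JetPoly] = {}
        if coeffs:
            for k, poly in coeffs.items():
                if k < 0:
                    raise ValueError("negative powers of (s - x) are not supported")
                if not poly.is_zero():
                    clean[k] = clean.get(k, JetPoly.zero()) + poly
        self.coeffs = {k: p for k, p in clean.items() if not p.is_zero()}

    @staticmethod
    def zero() -> "ProfileSeries":
        return ProfileSeries()

    @staticmethod
    def monomial(k: int, coeff: JetPoly | RationalLike) -> "ProfileSeries":
        if isinstance(coeff, (int, Fraction)):
            coeff = JetPoly.constant(coeff)
        return ProfileSeries({k: coeff})

    def __add__(self, other: "ProfileSeries") -> "ProfileSeries":
        coeffs = dict(self.coeffs)
        for k, p in other.coeffs.items():
            coeffs[k] = coeffs.get(k, JetPoly.zero()) + p
        return ProfileSeries(coeffs)

    def __neg__(self) -> "ProfileSeries":
        return ProfileSeries({k: -p for k, p in self.coeffs.items()})

    def __sub__(self, other: "ProfileSeries") -> "ProfileSeries":
        return self + (-other)

    def scale(self, c: RationalLike | JetPoly) -> "ProfileSeries":
        return ProfileSeries({k: p * c for k, p in self.coeffs.items()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileSeries):
            return NotImplemented
        return self.coeffs == other.coeffs

    def __hash__(self):
        return hash(frozenset((k, hash(p)) for k, p in self.coeffs.items()))

    def is_zero(self) -> bool:
        return not self.coeffs

    def max_jet_order(self) -> int:
        return max((p.max_jet_order() for p in self.coeffs.values()), default=-1)

    def __repr__(self) -> str:
        if not self.coeffs:
            return "ProfileSeries(0)"
        parts = [f"[{p!r}]*(s-x)^{k}" for k, p in sorted(self.coeffs.items())]
        return "ProfileSeries(" + " + ".join(parts) + ")"

    def to_json_obj(self) -> dict[str, dict[str, str]]:
        return {str(k): p.to_json_obj() for k, p in sorted(self.coeffs.items())}

    def to_json(self) -> str:
        return json.dumps(self.to_json_obj(), sort_keys=True)


# ---------------------------------------------------------------------------
# calculus operations
# ---------------------------------------------------------------------------

def jet_time_derivative(p: JetPoly) -> JetPoly:
    """d/dt of a jet polynomial: ``d/dt s^(j) = s^(j+1)`` with product rule."""
    out = JetPoly.zero()
    for mono, coef in p.terms.items():
        exps = mono.as_map()
        for j, e in exps.items():
            new = dict(exps)
            new[j] = e - 1
            new[j + 1] = new.get(j + 1, 0) + 1
            out = out + JetPoly({JetMonomial.from_map(new): coef * e})
    return out


def series_time_derivative(u: ProfileSeries) -> ProfileSeries:
    """d/dt of a profile series at fixed x, so ``d/dt (s - x) = s'``."""
    sprime = JetPoly.jet(1)
    out = ProfileSeries.zero()
    for k, c in u.coeffs.items():
        out = out + ProfileSeries.monomial(k, jet_time_derivative(c))
        if k >= 1:
            out = out + ProfileSeries.monomial(k - 1, c * sprime * k)
    return out


def series_x_derivative(u: ProfileSeries) -> ProfileSeries:
    """d/dx: maps ``c_k (s-x)^k -> -k c_k (s-x)^(k-1)``."""
    return ProfileSeries(
        {k - 1: c * (-k) for k, c in u.coeffs.items() if k >= 1}
    )


def series_double_integral(u: ProfileSeries) -> ProfileSeries:
    """The inverse operator: double integral from x to s(t).

    Diagonal on the (s - x) basis: ``(s-x)^k -> (s-x)^(k+2)/((k+1)(k+2))``.
    The result and its x-derivative vanish identically at ``x = s``.
    """
    return ProfileSeries(
        {k + 2: c * Fraction(1, (k + 1) * (k + 2)) for k, c in u.coeffs.items()}
    )


def series_integral_zero_to_s(u: ProfileSeries) -> JetPoly:
    """``int_0^s u dx``: maps ``c_k (s-x)^k -> c_k s^(k+1)/(k+1)``."""
    out = JetPoly.zero()
    for k, c in u.coeffs.items():
        out = out + c.multiply_jet_power(0, k + 1) * Fraction(1, k + 1)
    return out


def x_polynomial_to_series(coeffs_in_x: Iterable[RationalLike]) -> ProfileSeries:
    """Rebase a polynomial given in x onto the (s - x) basis via x = s - (s - x).

    ``coeffs_in_x[i]`` is the coefficient of ``x**i``.
    """
    out = ProfileSeries.zero()
    for i, a in enumerate(coeffs_in_x):
        a = Fraction(a)
        if a == 0:
            continue
        # x^i = (s - (s-x))^i = sum_m C(i,m) s^(i-m) (-(s-x))^m
        from math import comb

        for m in range(i + 1):
            coef = JetPoly.jet(0, i - m) if i - m > 0 else JetPoly.constant(1)
            sign = Fraction(-1) ** m
            out = out + ProfileSeries.monomial(m, coef * (a * comb(i, m) * sign))
    return out


def series_evaluate(u: ProfileSeries, jets: Sequence[float], x: float) -> float:
    """Numeric evaluation; ``jets[0]`` is s, ``jets[1]`` is s', and so on."""
    needed = u.max_jet_order()
    if needed >= len(jets):
        raise ValueError(
            f"series requires jet order {needed} but only {len(jets)} values supplied"
        )
    s = jets[0]
    return sum(c.evaluate(jets) * (s - x) ** k for k, c in u.coeffs.items())
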