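"""Front-dynamics tests: ODE derivation, ansatz reduction, trajectories."""

import math
from fractions import Fraction

import numpy as np
import pytest

from oxdiff.adm_core import ProblemSpec, oxygen_problem
from oxdiff.boundary_dynamics import (
    AnsatzReductionError,
    BoundaryODE,
    LambdaCubic,
    SqrtBoundary,
    boundary_jets,
    extinction_time,
    flux_balance_ode,
    implicit_boundary_solve,
    implicit_law_residual,
    oxygen_boundary_ode,
    oxygen_lambda_cubic,
    oxygen_profile,
    oxygen_sqrt_boundary,
    real_root,
    s_of_t,
    sqrt_ansatz_reduce,
    surface_concentration,
    t_direction_boundary_rhs,
)
from oxdiff.jet_algebra import JetPoly, ProfileSeries

s = JetPoly.jet(0)
s1 = JetPoly.jet(1)
s2 = JetPoly.jet(2)

EXACT_LAMBDA = -3.192143275966643


# ---------------------------------------------------------------------------
# symbolic derivation
# ---------------------------------------------------------------------------

class TestFluxBalanceODE:
    def test_oxygen_fifth_degree_ode_coefficients(self):
        # s s'/2 + s^2 s'^2/6 + s^3 s''/24 + s^3 s'^3/24
        #   + s^4 s' s''/40 + s^5 s'''/720 + 1 = 0
        lhs = oxygen_boundary_ode(2).lhs
        expected = {
            (): Fraction(1),
            ((0, 1), (1, 1)): Fraction(1, 2),
            ((0, 2), (1, 2)): Fraction(1, 6),
            ((0, 3), (2, 1)): Fraction(1, 24),
            ((0, 3), (1, 3)): Fraction(1, 24),
            ((0, 4), (1, 1), (2, 1)): Fraction(1, 40),
            ((0, 5), (3, 1)): Fraction(1, 720),
        }
        actual = {m.exponents: c for m, c in lhs.terms.items()}
        assert actual == expected

    def test_zero_profile_degenerates_to_constant(self):
        ode = flux_balance_ode(ProfileSeries.zero(), oxygen_problem())
        assert ode.lhs == JetPoly.constant(1)

    def test_leading_order_profile(self):
        # u_0 alone: d/dt (s^3/6) = s^2 s'/2, plus s, divided by s
        ode = flux_balance_ode(oxygen_profile(0), oxygen_problem())
        assert ode.lhs == s * s1 * Fraction(1, 2) + JetPoly.constant(1)

    def test_nonzero_dirichlet_value_rejected(self):
        problem = ProblemSpec.make(p=Fraction(1, 2))
        with pytest.raises(ValueError, match="Dirichlet"):
            flux_balance_ode(oxygen_profile(2), problem)


class TestSqrtAnsatzReduce:
    def test_oxygen_ode_reduces_to_integer_cubic(self):
        cubic = sqrt_ansatz_reduce(oxygen_boundary_ode(2))
        assert cubic.coeffs == (1, 6, 24, 48)

    def test_leading_order_reduces_to_linear(self):
        ode = BoundaryODE(s * s1 * Fraction(1, 2) + JetPoly.constant(1))
        assert sqrt_ansatz_reduce(ode).coeffs == (0, 0, 1, 2)

    def test_ansatz_identities_cancel(self):
        # s'' s^3 = -lambda^2 and s'^2 s^2 = lambda^2 sum to zero
        ode = BoundaryODE(s2 * JetPoly.jet(0, 3) + s1 * s1 * JetPoly.jet(0, 2))
        assert sqrt_ansatz_reduce(ode).coeffs == (0, 0, 0, 0)

    def test_non_cancelling_monomial_is_rejected(self):
        with pytest.raises(AnsatzReductionError, match="s"):
            sqrt_ansatz_reduce(BoundaryODE(s + JetPoly.constant(1)))

    def test_full_symbolic_round_trip(self, oxygen):
        # no hand-coded intermediates: profile -> flux balance -> ansatz
        from oxdiff.adm_core import truncated_profile, x_direction_components

        profile = truncated_profile(x_direction_components(oxygen, 2))
        cubic = sqrt_ansatz_reduce(flux_balance_ode(profile, oxygen))
        assert cubic.coeffs == (1, 6, 24, 48)


class TestRealRoot:
    def test_oxygen_cubic_root(self):
        root = real_root(oxygen_lambda_cubic())
        assert abs(root - EXACT_LAMBDA) < 1e-12
        assert abs(oxygen_lambda_cubic()(root)) < 1e-12

    def test_pure_cube(self):
        assert real_root(LambdaCubic((1, 0, 0, -8))) == pytest.approx(2.0, abs=1e-12)

    def test_three_real_roots_demand_bracket(self):
        cubic = LambdaCubic((1, 0, -1, 0))  # roots -1, 0, 1
        with pytest.raises(ValueError, match="bracket"):
            real_root(cubic)
        assert real_root(cubic, bracket=(0.5, 2.0)) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# square-root trajectory
# ---------------------------------------------------------------------------

class TestSqrtBoundary:
    def test_rounded_mode_front_positions(self):
        b = oxygen_sqrt_boundary("paper_rounded")
        assert round(s_of_t(b, 0.051), 5) == 0.82073
        assert s_of_t(b, 0.100) == pytest.approx(0.6000, abs=1e-12)
        assert s_of_t(b, 0.0) == 1.0

    def test_extinction_time(self):
        assert extinction_time(oxygen_sqrt_boundary("paper_rounded")) == 0.15625
        assert extinction_time(SqrtBoundary(-0.5)) == 1.0
        exact = extinction_time(oxygen_sqrt_boundary("exact_root"))
        assert exact == pytest.approx(1 / (2 * 3.192143275966643), rel=1e-12)

    def test_nonnegative_lambda_rejected(self):
        with pytest.raises(ValueError):
            SqrtBoundary(0.3)

    def test_out_of_window_time_names_extinction(self):
        b = oxygen_sqrt_boundary("paper_rounded")
        with pytest.raises(ValueError, match="0.15625"):
            s_of_t(b, 0.2)

    def test_monotone_decreasing(self):
        b = oxygen_sqrt_boundary("exact_root")
        ts = np.linspace(0, extinction_time(b) * 0.999, 200)
        vals = [s_of_t(b, t) for t in ts]
        assert all(a > b_ for a, b_ in zip(vals, vals[1:]))


class TestBoundaryJets:
    def test_ansatz_identity_products(self):
        b = oxygen_sqrt_boundary("paper_rounded")
        lam = b.lam
        for t in (0.0, 0.03, 0.1):
            sv, sp, spp, sppp = boundary_jets(b, t, 3).values
            assert sv * sp == pytest.approx(lam, rel=1e-13)
            assert spp * sv**3 == pytest.approx(-(lam**2), rel=1e-13)
            assert sppp * sv**5 == pytest.approx(3 * lam**3, rel=1e-13)
            assert spp * sp * sv**4 == pytest.approx(-(lam**3), rel=1e-13)

    def test_initial_jets(self):
        b = oxygen_sqrt_boundary("paper_rounded")
        jets = boundary_jets(b, 0.0, 1)
        assert jets.values == (1.0, b.lam)

    def test_fourth_jet_against_finite_differences(self):
        # high-precision 4th central difference of sqrt(1+2*lam*t) (the
        # plain double-precision stencil bottoms out near 5e-5 relative)
        import mpmath as mp

        b = SqrtBoundary(-3.2)
        jet4 = boundary_jets(b, 0.05, 4).values[4]
        with mp.workdps(40):
            t, h, lam = mp.mpf("0.05"), mp.mpf("1e-5"), mp.mpf("-3.2")
            stencil = [
                mp.sqrt(1 + 2 * lam * (t + k * h)) for k in (-2, -1, 0, 1, 2)
            ]
            fd4 = (stencil[0] - 4 * stencil[1] + 6 * stencil[2]
                   - 4 * stencil[3] + stencil[4]) / h**4
        assert abs(float(fd4) - jet4) / abs(jet4) < 1e-5

    def test_jets_satisfy_boundary_ode(self):
        # substituting the ansatz jets at the exact root into the derived
        # ODE annihilates it numerically across the validity window
        b = oxygen_sqrt_boundary("exact_root")
        lhs = oxygen_boundary_ode(2).lhs
        rng = np.random.default_rng(42)
        t_ext = extinction_time(b)
        for t in rng.uniform(0, t_ext * 0.999, size=100):
            jets = boundary_jets(b, t, 3).values
            assert abs(lhs.evaluate(jets)) < 1e-10


class TestSurfaceConcentration:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.04, 0.229152), (0.08, 0.150304), (0.12, 0.0714560), (0.15, 0.0123200)],
    )
    def test_published_values(self, t, expected):
        b = oxygen_sqrt_boundary("paper_rounded")
        assert surface_concentration(b, t) == pytest.approx(expected, abs=5e-7)

    def test_closed_form_factor(self):
        # u(t,0) = s^2 (1/2 + lam/6 + lam^2/30); the factor is exactly
        # 0.308 = 77/250 at lam = -3.2
        b = oxygen_sqrt_boundary("paper_rounded")
        factor = float(
            Fraction(1, 2) + Fraction(-16, 5) / 6 + Fraction(-16, 5) ** 2 / 30
        )
        assert factor == 0.308
        for t in (0.0, 0.05, 0.13):
            sv = s_of_t(b, t)
            assert surface_concentration(b, t) == pytest.approx(
                0.308 * sv * sv, rel=1e-14
            )


# ---------------------------------------------------------------------------
# t-direction implicit law
# ---------------------------------------------------------------------------

class TestImplicitBoundaryLaw:
    def test_initial_position(self):
        assert implicit_boundary_solve(0.0) == 1.0
        assert implicit_law_residual(1.0, 0.0) == 0.0

    @pytest.mark.parametrize("t", [0.0, 0.1, 0.5, 1.0, 5.0])
    def test_residual_at_tight_tolerance(self, t):
        sv = implicit_boundary_solve(t, tol=1e-12)
        assert abs(implicit_law_residual(sv, t)) <= 1e-12

    def test_strictly_decreasing_and_positive(self):
        ts = np.linspace(0, 3, 150)
        vals = [implicit_boundary_solve(t) for t in ts]
        assert all(v > 0 for v in vals)
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_unique_root_matches_grid_scan(self):
        # dense grid scan + bisection as an independent oracle at t=1
        t = 1.0
        grid = np.linspace(1e-6, 1.0, 200001)
        vals = np.log(grid) - 2 * grid + grid**2 / 2 + 2 * t + 1.5
        crossings = np.nonzero(np.diff(np.sign(vals)))[0]
        assert len(crossings) == 1
        lo, hi = grid[crossings[0]], grid[crossings[0] + 1]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if (math.log(mid) - 2 * mid + mid**2 / 2 + 2 * t + 1.5) < 0:
                lo = mid
            else:
                hi = mid
        assert implicit_boundary_solve(t) == pytest.approx(0.5 * (lo + hi), rel=1e-10)

    def test_implicit_differentiation_gives_ode_rhs(self):
        # ds/dt from the implicit law equals -2s/(1-s)^2
        h = 1e-7
        for t in (0.05, 0.3, 1.0):
            sv = implicit_boundary_solve(t)
            numeric = (
                implicit_boundary_solve(t + h) - implicit_boundary_solve(t - h)
            ) / (2 * h)
            assert numeric == pytest.approx(t_direction_boundary_rhs(t, sv), rel=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            implicit_boundary_solve(-0.1)
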