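"""Heat-balance integral-method references for the oxygen diffusion problem.

Two classical polynomial-profile approximations serve as comparators for
the decomposition solution:

* the Crank-Gupta quartic profile centred at the moving front, with the
  surface value ``u0(t) = 1/2 - 2*sqrt(t/pi)`` and a front ODE obtained
  from the zeroth moment of the PDE;
* the Gupta-Banik quartic profile centred at the sealed surface, with a
  coupled ODE pair for (u0, s) from the first moment.

A classical fixed-step fourth-order Runge-Kutta integrator drives the ODE
systems.  These are comparators only: their trajectories contextualise the
decomposition results and are not themselves benchmark quantities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "IntegralMethodState",
    "RK4Config",
    "crank_gupta_u0",
    "crank_gupta_u0_prime",
    "crank_gupta_profile",
    "crank_gupta_s_rhs",
    "gupta_banik_profile",
    "gupta_banik_rhs",
    "gupta_banik_start_state",
    "gupta_banik_moment",
    "rk4_integrate",
    "rk4_step",
    "moment_balance_residual",
    "CRANK_GUPTA_T_MAX",
    "GUPTA_BANIK_T_START",
]

#: u0(t) = 1/2 - 2*sqrt(t/pi) reaches zero at t = pi/16.
CRANK_GUPTA_T_MAX = math.pi / 16.0

#: The surface-centred scheme only starts once s^2 - 4*u0 >= 0 is
#: compatible with the surface value, at t* = 4/(25*pi).
GUPTA_BANIK_T_START = 4.0 / (25.0 * math.pi)


@dataclass(frozen=True)
class IntegralMethodState:
    """State (t, s, u0) of a surface-anchored integral-method trajectory."""

    t: float
    s: float
    u0: float


@dataclass(frozen=True)
class RK4Config:
    step: float
    t_start: float
    t_end: float

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.step > self.t_end - self.t_start:
            raise ValueError("step exceeds the integration interval")


# ---------------------------------------------------------------------------
# Crank-Gupta (front-centred quartic)
# ---------------------------------------------------------------------------

def crank_gupta_u0(t: float) -> float:
    """Surface concentration ``1/2 - 2*sqrt(t/pi)`` of the front-centred scheme.

    Non-negative only for t <= pi/16; beyond that a warning is issued and
    the (negative) value returned unchanged.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t > CRANK_GUPTA_T_MAX:
        warnings.warn(
            f"t={t} exceeds pi/16; the surface concentration is negative "
            "and the profile no longer physical",
            stacklevel=2,
        )
    return 0.5 - 2.0 * math.sqrt(t / math.pi)


def crank_gupta_u0_prime(t: float) -> float:
    """d u0/dt = -1/sqrt(pi t)."""
    if t <= 0:
        raise ValueError("derivative requires t > 0")
    return -1.0 / math.sqrt(math.pi * t)


def crank_gupta_profile(x: float, s: float, u0: float) -> float:
    """Front-centred quartic in (1 - x/s), anchored so u(0) = u0 when s = 1.

    Vanishes together with its x-derivative at x = s.
    """
    if not 0.0 <= x <= s:
        raise ValueError(f"x={x} outside [0, s={s}]")
    z = 1.0 - x / s
    return (
        0.5 * s * s * z**2
        + (4.0 * u0 - s * s) * z**3
        - (3.0 * u0 - 0.5 * s * s) * z**4
    )


def crank_gupta_s_rhs(t: float, s: float) -> float:
    """Front ODE ``s' = (20 + 8 u0'(t)) s / (8 u0(t) + s^2)``, t >= 4/(25 pi).

    Comparator only — verify against the original integral-method source
    before trusting: direct evaluation near t = 0.08 yields a positive
    slope, inconsistent with a shrinking front, which suggests a
    transcription typo in the printed rate.  Implemented verbatim.
    """
    if t < GUPTA_BANIK_T_START:
        raise ValueError("front ODE applies only for t >= 4/(25*pi)")
    denom = 8.0 * crank_gupta_u0(t) + s * s
    if denom <= 0:
        raise ValueError(f"nonpositive denominator {denom} at t={t}, s={s}")
    return (20.0 + 8.0 * crank_gupta_u0_prime(t)) * s / denom


# ---------------------------------------------------------------------------
# Gupta-Banik (surface-centred quartic)
# ---------------------------------------------------------------------------

def gupta_banik_profile(x: float, s: float, u0: float) -> float:
    """Surface-centred quartic in x/s; equals u0 at x = 0 and vanishes with
    its x-derivative at x = s."""
    if not 0.0 <= x <= s:
        raise ValueError(f"x={x} outside [0, s={s}]")
    r = x / s
    return (
        u0
        + 0.5 * (s * s - 12.0 * u0) * r**2
        + (8.0 * u0 - s * s) * r**3
        + 0.5 * (s * s - 6.0 * u0) * r**4
    )


def gupta_banik_rhs(state: IntegralMethodState) -> tuple[float, float]:
    """Coupled moment ODEs (du0/dt, ds/dt) of the surface-centred scheme.

    du0/dt = -(5 s^4 + 30 s^2 u0 + 24 u0^2) / (s^2 (5 s^2 + 24 u0)),
    ds/dt  = -60 (s^2 - 4 u0) / (s (5 s^2 + 24 u0)).
    """
    s, u0 = state.s, state.u0
    if s <= 0:
        raise ValueError("front position must be positive")
    denom = 5.0 * s * s + 24.0 * u0
    if denom <= 0:
        raise ValueError(f"nonpositive denominator 5s^2+24u0={denom}")
    du0 = -(5.0 * s**4 + 30.0 * s * s * u0 + 24.0 * u0 * u0) / (s * s * denom)
    ds = -60.0 * (s * s - 4.0 * u0) / (s * denom)
    return du0, ds


def gupta_banik_start_state() -> IntegralMethodState:
    """Start of the surface-centred trajectory: t* = 4/(25 pi), s = 1.

    The surface value at t* is taken from the front-centred law,
    u0(t*) = 1/2 - 4/(5 pi), which makes s^2 - 4 u0 = 0 — the marginal
    admissibility condition — hold with ds/dt = 0 at start.
    """
    t0 = GUPTA_BANIK_T_START
    return IntegralMethodState(t=t0, s=1.0, u0=crank_gupta_u0(t0))


def gupta_banik_moment(s: float, u0: float) -> float:
    """First moment ``int_0^s x u(x) dx`` of the surface-centred quartic.

    Closed form: with a = (s^2 - 12 u0)/2, b = 8 u0 - s^2,
    c = (s^2 - 6 u0)/2, the moment is s^2 (u0/2 + a/4 + b/5 + c/6).
    """
    a = 0.5 * (s * s - 12.0 * u0)
    b = 8.0 * u0 - s * s
    c = 0.5 * (s * s - 6.0 * u0)
    return s * s * (u0 / 2.0 + a / 4.0 + b / 5.0 + c / 6.0)


# ---------------------------------------------------------------------------
# fixed-step RK4
# ---------------------------------------------------------------------------

def rk4_step(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    t: float,
    y: np.ndarray,
    h: float,
) -> np.ndarray:
    k1 = rhs(t, y)
    k2 = rhs(t + 0.5 * h, y + 0.5 * h * k1)
    k3 = rhs(t + 0.5 * h, y + 0.5 * h * k2)
    k4 = rhs(t + h, y + h * k3)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def rk4_integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: Sequence[float],
    cfg: RK4Config,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical fourth-order Runge-Kutta with a fixed step.

    Returns (times, states) including the initial point; the final step is
    shortened to land exactly on ``t_end``.  If the vector field raises,
    integration aborts with the failing time in the error message.
    """
    y = np.asarray(y0, dtype=float)
    t = cfg.t_start
    times = [t]
    states = [y.copy()]
    while t < cfg.t_end - 1e-15 * max(1.0, abs(cfg.t_end)):
        h = min(cfg.step, cfg.t_end - t)
        try:
            y = rk4_step(rhs, t, y, h)
        except Exception as exc:
            raise RuntimeError(f"integration aborted at t={t}: {exc}") from exc
        t += h
        times.append(t)
        states.append(y.copy())
    return np.array(times), np.array(states)


def moment_balance_residual(
    state: IntegralMethodState, dt: float = 1e-4
) -> float:
    """Diagnostic: first-moment balance ``d/dt int_0^s x u dx = u0 - s^2/2``.

    Differentiates the moment numerically (central difference of RK4
    micro-steps along the surface-centred flow) and returns the deviation
    from the right-hand side; near zero up to finite-difference error for
    consistent states.
    """
    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        du0, ds = gupta_banik_rhs(IntegralMethodState(t, y[1], y[0]))
        return np.array([du0, ds])

    y = np.array([state.u0, state.s])
    fwd = rk4_step(rhs, state.t, y, dt)
    bwd = rk4_step(rhs, state.t, y, -dt)
    m_fwd = gupta_banik_moment(fwd[1], fwd[0])
    m_bwd = gupta_banik_moment(bwd[1], bwd[0])
    dmdt = (m_fwd - m_bwd) / (2.0 * dt)
    return dmdt - (state.u0 - 0.5 * state.s * state.s)
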