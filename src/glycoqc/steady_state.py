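"""Analytic steady states of the quality-control cycle.

At steady state the eight mass-action balances reduce, by eliminating all
concentrations in favour of the available chaperone ``CA``, to a quartic
polynomial in ``CA``.  The elimination proceeds through the flux balance
on the foldable pool (kp = kf*Pc + kd*P), the folded- and background-bound
balances (Pcf = kf*Pc/(kr+kmc), Pcb = kmr*Pb*CA/kr), and two 2x2 linear
systems for (Pg, Pc) and (Pg*, Pc*) whose solutions are rational in CA.
Substituting into the chaperone conservation law and clearing denominators
yields the quartic.  Real roots in (0, 1] are back-substituted and
filtered for nonnegative concentrations and a small dynamical residual.

The elimination here keeps the release rate ``kr`` symbolic so the same
formulas cover the no-tag-memory variant (kr = 0); with kr = 1 they reduce
to the physiological non-dimensionalized form.

A stiff ODE integrator (:func:`integrate_dynamics`) serves as an
independent oracle: it resolves root multiplicity, confirms existence, and
diagnoses unbounded accumulation when production outruns the chaperone
release capacity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.integrate import solve_ivp

from .model import RateSet, StateVector, _rhs, available_chaperone, total_unfolded

__all__ = [
    "QuarticIntermediates",
    "SteadyStateResult",
    "DegenerateRootError",
    "quartic_coefficients",
    "back_substitute",
    "solve_steady_state",
    "integrate_dynamics",
    "steady_state_exists",
]

logger = logging.getLogger(__name__)

#: Componentwise clamp for tiny negative concentrations from root extraction.
CLAMP_TOL = 1e-10

#: Max-norm residual of the dynamics below which a root counts as a steady state.
RESIDUAL_TOL = 1e-8


class DegenerateRootError(ValueError):
    """A back-substitution denominator vanished at the candidate root."""


@dataclass(frozen=True)
class QuarticIntermediates:
    """Auxiliary constants of the CA-elimination.

    Unstarred symbols belong to the foldable 2x2 system, starred (``s``
    suffix) to the misfolded one.  ``m1 = -kmr*kf/kd`` couples the
    untagged rebinding flux back into the chaperone-bound balance; the
    ``r`` coefficients are the determinant polynomials, ``p``/``q`` the
    Cramer numerators for Pg and Pc respectively.
    """

    m1: float
    n1: float
    n2: float
    b1: float
    b2: float
    p0: float
    p1: float
    q1: float
    q2: float
    r0: float
    r1: float
    r2: float
    n1s: float
    b1s: float
    b2s: float
    p0s: float
    p1s: float
    q1s: float
    q2s: float
    r0s: float
    r1s: float


@dataclass(frozen=True)
class SteadyStateResult:
    """Outcome of a steady-state computation.

    ``exists`` is False when no feasible root (or no converged
    trajectory) was found; ``diagnosis`` then says why.
    """

    state: StateVector
    CA: float
    residual: float
    exists: bool
    diagnosis: str = ""


def _intermediates(r: RateSet) -> QuarticIntermediates:
    if r.kd <= 0:
        raise ValueError("kd must be positive (appears in elimination denominators)")
    m1 = -r.kmr * r.kf / r.kd
    n1 = -(r.kf + r.kr + r.kmc)
    n2 = r.kmc - r.kg * r.kf / r.kd
    b1 = -r.kmr * r.kp / r.kd
    b2 = -(r.kp + r.kg * r.kp / r.kd)
    r2 = r.kc * m1
    r1 = r.kmg * m1 + r.kc * n1 + r.kc * n2
    r0 = r.kmg * n1
    p1 = b1 * n2 - m1 * b2
    p0 = -n1 * b2
    q2 = r.kc * b1
    q1 = r.kmg * b1 + r.kc * b2
    n1s = -(r.kr + r.kmc)
    b1s = -r.kmr * r.kps / r.kd
    b2s = -(r.kps + r.kg * r.kps / r.kd)
    r1s = -r.kc * r.kr
    r0s = r.kmg * n1s
    p1s = r.kmc * b1s
    p0s = -n1s * b2s
    q2s = r.kc * b1s
    q1s = r.kmg * b1s + r.kc * b2s
    return QuarticIntermediates(
        m1=m1, n1=n1, n2=n2, b1=b1, b2=b2, p0=p0, p1=p1, q1=q1, q2=q2,
        r0=r0, r1=r1, r2=r2, n1s=n1s, b1s=b1s, b2s=b2s, p0s=p0s, p1s=p1s,
        q1s=q1s, q2s=q2s, r0s=r0s, r1s=r1s,
    )


def _background_factor(r: RateSet) -> float:
    # CA*(1 + kmr*Pb/kr) appears in the closure; kmr = 0 removes the
    # background term entirely (also covering kr = 0 in the NTM variant).
    if r.kmr == 0.0:
        return 1.0
    return 1.0 + r.kmr * r.Pb / r.kr


def quartic_coefficients(rates: RateSet) -> tuple[np.ndarray, QuarticIntermediates]:
    """Coefficients (degree 4 down to constant) of the CA polynomial.

    The leading coefficients may be exactly zero for degenerate variants
    (e.g. ``kmr = 0`` makes ``r2 = 0`` and drops the degree); callers
    solve the reduced-degree polynomial.
    """
    inter = _intermediates(rates)
    if rates.kr + rates.kmc <= 0:
        raise ValueError("kr + kmc must be positive (folded-protein release)")
    phi = 1.0 + rates.kf / (rates.kr + rates.kmc)
    A = _background_factor(rates)
    D = np.array([inter.r0, inter.r1, inter.r2])        # det of foldable system
    Ds = np.array([inter.r0s, inter.r1s])               # det of misfolded system
    Nc = np.array([0.0, inter.q1, inter.q2])            # Pc numerator
    Ncs = np.array([0.0, inter.q1s, inter.q2s])         # Pc* numerator
    DDs = npoly.polymul(D, Ds)
    # A*CA*D*Ds - D*Ds + phi*Nc*Ds + Ncs*D = 0
    poly = npoly.polyadd(
        npoly.polysub(npoly.polymulx(A * DDs), DDs),
        npoly.polyadd(npoly.polymul(phi * Nc, Ds), npoly.polymul(Ncs, D)),
    )
    asc = np.zeros(5)
    asc[: poly.size] = poly
    return asc[::-1].copy(), inter


def back_substitute(CA: float, rates: RateSet) -> StateVector:
    """Full state implied by an available-chaperone value.

    Applies the Cramer solutions of the two 2x2 systems and the flux
    relations for P, P*, Pcf and Pcb.  Performs no feasibility check.
    """
    if not 0.0 < CA <= 1.0 + 1e-9:
        raise ValueError(f"CA must lie in (0, 1], got {CA}")
    it = _intermediates(rates)
    det = (it.r2 * CA + it.r1) * CA + it.r0
    dets = it.r1s * CA + it.r0s
    if det == 0.0:
        raise DegenerateRootError(f"foldable determinant vanished at CA={CA}")
    Pg = (it.p1 * CA + it.p0) / det
    Pc = (it.q2 * CA + it.q1) * CA / det
    if rates.kps > 0.0 or rates.Pb * rates.kmr > 0.0:
        if dets == 0.0:
            raise DegenerateRootError(f"misfolded determinant vanished at CA={CA}")
    if dets == 0.0:
        Pgs = Pcs = 0.0
    else:
        Pgs = (it.p1s * CA + it.p0s) / dets
        Pcs = (it.q2s * CA + it.q1s) * CA / dets
    P = rates.kp / rates.kd - rates.kf * Pc / rates.kd
    Ps = rates.kps / rates.kd
    Pcf = rates.kf * Pc / (rates.kr + rates.kmc)
    Pcb = 0.0 if rates.kmr == 0.0 else rates.kmr * rates.Pb * CA / rates.kr
    return StateVector(Pg=Pg, Pc=Pc, Pcf=Pcf, P=P, Pgs=Pgs, Pcs=Pcs, Ps=Ps, Pcb=Pcb)


def _closure_residual(CA: float, rates: RateSet) -> float:
    """Rational closure g(CA); well-conditioned near a simple root."""
    st = back_substitute(CA, rates)
    phi_pc = st.Pc + st.Pcf
    return _background_factor(rates) * CA - 1.0 + phi_pc + st.Pcs


def _polish_root(x0: float, rates: RateSet) -> float:
    """A few secant steps on the rational closure function."""
    x, xp = x0, x0 * (1.0 + 1e-9) + 1e-15
    try:
        fx, fxp = _closure_residual(x, rates), _closure_residual(xp, rates)
        for _ in range(30):
            if fxp == fx:
                break
            xn = xp - fxp * (xp - x) / (fxp - fx)
            if not 0.0 < xn <= 1.0 + 1e-9:
                break
            x, fx, xp, fxp = xp, fxp, xn, _closure_residual(xn, rates)
            if abs(xp - x) < 1e-15 * max(1.0, abs(xp)):
                break
        return min(xp, 1.0) if 0.0 < xp <= 1.0 + 1e-9 else x0
    except (DegenerateRootError, ZeroDivisionError, FloatingPointError):
        return x0


def _clamp_state(state: StateVector) -> StateVector | None:
    """Clamp tiny negative components to zero; None if genuinely negative."""
    y = state.to_array()
    if np.any(y < -CLAMP_TOL) or not np.all(np.isfinite(y)):
        return None
    return StateVector.from_array(np.maximum(y, 0.0))


def _candidate_roots(rates: RateSet) -> list[float]:
    desc, _ = quartic_coefficients(rates)
    asc = desc[::-1]
    scale = np.max(np.abs(asc))
    if scale == 0.0:
        return []
    # drop numerically-zero leading coefficients: reduced degree is legal
    keep = asc.size
    while keep > 1 and abs(asc[keep - 1]) <= 1e-13 * scale:
        keep -= 1
    if keep == 1:
        return []
    roots = np.roots(asc[:keep][::-1])
    out = []
    for z in roots:
        if abs(z.imag) > 1e-8 * max(1.0, abs(z)):
            continue
        x = float(z.real)
        if 1e-14 < x <= 1.0 + 1e-9:
            out.append(min(x, 1.0))
    return sorted(set(out), reverse=True)


def solve_steady_state(
    rates: RateSet,
    residual_tol: float = RESIDUAL_TOL,
    ode_check: bool = True,
) -> SteadyStateResult:
    """Steady state via the CA quartic, with feasibility filtering.

    All real roots in (0, 1] are polished against the rational closure
    equation and back-substituted; roots giving componentwise nonnegative
    states (after a 1e-10 clamp) with dynamics residual below
    ``residual_tol`` are feasible.  A unique feasible root is returned
    directly.  With several, the one matching the ODE trajectory from the
    empty state is selected (``ode_check=True``) or the largest-CA root is
    taken (the branch reached from an initially empty system); a
    multiplicity warning is emitted either way.  No feasible root yields
    ``exists=False`` with a diagnosis.
    """
    feasible: list[tuple[float, StateVector, float]] = []
    for x in _candidate_roots(rates):
        x = _polish_root(x, rates)
        try:
            raw = back_substitute(x, rates)
        except DegenerateRootError:
            continue
        state = _clamp_state(raw)
        if state is None:
            continue
        ca = available_chaperone(state)
        if not 0.0 < ca <= 1.0 + 1e-9:
            continue
        res = float(np.max(np.abs(_rhs(state.to_array(), rates))))
        if res < residual_tol:
            feasible.append((x, state, res))
    if not feasible:
        cap = rates.kr + rates.kmc + rates.kmg  # release + safety-valve channels
        return SteadyStateResult(
            state=StateVector.zero(), CA=float("nan"), residual=float("inf"),
            exists=False,
            diagnosis=(
                "no feasible root of the chaperone-availability polynomial "
                f"(production kpt={rates.kpt:.4g} vs release capacity "
                f"kr+kmc+kmg={cap:.4g} per chaperone)"
            ),
        )
    if len(feasible) > 1:
        warnings.warn(
            f"multiple feasible steady-state roots (CA={[f'{x:.6g}' for x, _, _ in feasible]}); "
            "selecting the dynamically realized branch",
            stacklevel=2,
        )
        if ode_check:
            ode = integrate_dynamics(rates)
            if ode.exists:
                ref = ode.state.to_array()
                feasible.sort(key=lambda t: float(np.max(np.abs(t[1].to_array() - ref))))
        # without an oracle: the largest-CA branch is the one reached from
        # an empty system (CA starts at 1)
    x, state, res = feasible[0]
    return SteadyStateResult(state=state, CA=x, residual=res, exists=True)


_UNFOLDED_IDX = np.array([0, 1, 3, 4, 5, 6])  # Pg, Pc, P, Pg*, Pc*, P*


def integrate_dynamics(
    rates: RateSet,
    init: StateVector | None = None,
    horizon: float = 50.0,
    tol: float = 1e-9,
    max_horizon: float = 2e6,
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> SteadyStateResult:
    """Integrate the dynamics to a fixed point (independent oracle).

    Runs a stiff solver over doubling time windows until the max-norm of
    the right-hand side drops below ``tol``, the horizon cap is reached,
    or unbounded accumulation is detected (total unfolded protein growing
    monotonically with a non-vanishing rate across successive windows —
    the signature of production outrunning chaperone release).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    y = (init or StateVector.zero()).to_array()
    if np.any(y < 0):
        raise ValueError("initial concentrations must be nonnegative")
    res = float(np.max(np.abs(_rhs(y, rates))))
    if res < tol:
        return SteadyStateResult(StateVector.from_array(y), available_chaperone(StateVector.from_array(y)), res, True)
    t, T = 0.0, horizon
    punf_hist: list[float] = []
    dpunf_hist: list[float] = []
    while t < max_horizon:
        sol = solve_ivp(
            lambda _, yy: _rhs(yy, rates), (t, t + T), y,
            method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"integrator failure ({sol.message}) for rates {rates}")
        t = float(sol.t[-1])
        y = np.maximum(sol.y[:, -1], 0.0)
        rhs = _rhs(y, rates)
        res = float(np.max(np.abs(rhs)))
        if res < tol:
            state = _clamp_state(StateVector.from_array(y))
            if state is None:  # pragma: no cover - clamp after max() cannot fail
                break
            return SteadyStateResult(state, available_chaperone(state), res, True)
        punf = float(y[_UNFOLDED_IDX].sum())
        dpunf = float(rhs[_UNFOLDED_IDX].sum())
        punf_hist.append(punf)
        dpunf_hist.append(dpunf)
        growing = (
            len(punf_hist) >= 4
            and all(b > a for a, b in zip(punf_hist[-4:], punf_hist[-3:]))
            and dpunf_hist[-1] > max(1e-8, 0.25 * max(dpunf_hist[-4:]))
        )
        if growing or punf > 1e8:
            return SteadyStateResult(
                StateVector.from_array(y), available_chaperone(StateVector.from_array(y)),
                res, False,
                diagnosis="unbounded accumulation: total unfolded protein grows "
                "without plateau (production exceeds processing capacity)",
            )
        T *= 2.0
    return SteadyStateResult(
        StateVector.from_array(y), available_chaperone(StateVector.from_array(y)),
        res, False,
        diagnosis=f"no convergence within horizon {max_horizon:g} (residual {res:.3g})",
    )


def steady_state_exists(rates: RateSet, confirm: bool = True) -> tuple[bool, str]:
    """Whether a feasible steady state exists, with a diagnosis.

    Analytic existence (a feasible quartic root) optionally confirmed by
    the ODE oracle, since a root can exist mathematically yet be
    dynamically unreachable.
    """
    analytic = solve_steady_state(rates)
    if not analytic.exists:
        return False, analytic.diagnosis
    if confirm:
        ode = integrate_dynamics(rates)
        if not ode.exists:
            return False, ode.diagnosis
    return True, "feasible steady state"
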