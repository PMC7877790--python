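import numpy as np
import pytest

from glycoqc.model import (
    Conditions,
    StateVector,
    VARIANTS,
    assemble_rates,
    available_chaperone,
    dynamics_rhs,
)
from glycoqc.io import random_rate_fixture
from glycoqc.steady_state import (
    back_substitute,
    integrate_dynamics,
    quartic_coefficients,
    solve_steady_state,
    steady_state_exists,
)

COND = Conditions(kpt=0.1, mf=0.001, kf=1.0, Pb=1.0)


def _sympy_ca_polynomial(rates):
    """Independent symbolic elimination of the steady state down to CA.

    Writes the eight mass-action balances directly in sympy (treating CA
    as a parameter), solves the linear system for the concentrations, and
    clears denominators in the chaperone-conservation closure.  Shares no
    code with the implementation's coefficient construction.
    """
    import sympy as sp
    from fractions import Fraction

    x = sp.Symbol("x")  # available chaperone
    Pg, Pc, Pcf, P, Pgs, Pcs, Ps, Pcb = sp.symbols("Pg Pc Pcf P Pgs Pcs Ps Pcb")
    R = {k: sp.Rational(Fraction(getattr(rates, k)).limit_denominator(10**12))
         for k in ("kc", "kmc", "kmr", "kg", "kmg", "kd", "kf", "kp", "kps",
                   "Pb", "kr")}
    eqs = [
        R["kg"] * P + R["kmc"] * Pc - (R["kc"] * x + R["kmg"]) * Pg + R["kp"],
        (R["kc"] * Pg + R["kmr"] * P) * x - (R["kr"] + R["kmc"] + R["kf"]) * Pc,
        R["kr"] * Pc + R["kmg"] * Pg - (R["kg"] + R["kmr"] * x + R["kd"]) * P,
        R["kf"] * Pc - (R["kr"] + R["kmc"]) * Pcf,
        R["kg"] * Ps + R["kmc"] * Pcs - (R["kc"] * x + R["kmg"]) * Pgs + R["kps"],
        (R["kc"] * Pgs + R["kmr"] * Ps) * x - (R["kr"] + R["kmc"]) * Pcs,
        R["kr"] * Pcs + R["kmg"] * Pgs - (R["kg"] + R["kmr"] * x + R["kd"]) * Ps,
        R["kmr"] * x * R["Pb"] - R["kr"] * Pcb,
    ]
    unknowns = [Pg, Pc, Pcf, P, Pgs, Pcs, Ps, Pcb]
    if R["kr"] == 0 and R["kmr"] == 0:
        # the Pcb balance is identically zero; no background binding occurs
        eqs, unknowns = eqs[:-1] + [Pcb], unknowns
    sol = sp.solve(eqs, unknowns, dict=True)
    assert len(sol) == 1
    closure = sp.together(1 - sol[0][Pc] - sol[0][Pcf] - sol[0][Pcs]
                          - sol[0][Pcb] - x)
    num = sp.expand(sp.numer(closure))
    return sp.Poly(num, x).all_coeffs()


@pytest.mark.parametrize("variant,seed", [("FULL", 1), ("PHYS", 2), ("WB", 3),
                                          ("NTM", 4), ("CNSV", 5)])
def test_quartic_matches_symbolic_elimination(variant, seed):
    """Coefficient construction agrees with an independent sympy elimination."""
    rates = random_rate_fixture(VARIANTS[variant], seed, 1)[0]
    desc, _ = quartic_coefficients(rates)
    ref = np.array([float(c) for c in _sympy_ca_polynomial(rates)], dtype=float)

    def trim(c):
        c = np.trim_zeros(np.asarray(c, float), "f")
        return c / np.max(np.abs(c))

    a, b = trim(desc), trim(ref)
    # sympy cancels common factors, so the implementation's cleared-denominator
    # polynomial may equal the reference times an extra polynomial factor:
    # divide the higher-degree one by the lower and require zero remainder
    if a.size < b.size:
        a, b = b, a
    _, rem = np.polydiv(a, b)
    assert np.max(np.abs(rem)) < 1e-8


def test_degree_drops_without_untagged_rebinding():
    """kmr = 0 kills the quartic term (r2 = -kc*kmr*kf/kd = 0)."""
    r = assemble_rates(VARIANTS["PHYS"], COND,
                       {"kc": 10.0, "kg": 1.0, "kmg": 0.1, "kd": 0.5})
    desc, inter = quartic_coefficients(r)
    assert inter.r2 == 0.0
    assert desc[0] == 0.0  # degree <= 3


class TestBackSubstitute:
    def test_misfolded_free_pool_from_flux_balance(self):
        r = assemble_rates(VARIANTS["PHYS"],
                           Conditions(kpt=0.4, mf=0.5, kf=1.0, Pb=0.0),
                           {"kc": 10.0, "kg": 1.0, "kmg": 0.1, "kd": 0.4})
        # kps = 0.2, kd = 0.4 -> P* = 0.5 for any CA
        for ca in (0.2, 0.5, 1.0):
            assert back_substitute(ca, r).Ps == pytest.approx(0.5)

    def test_folded_pool_proportional_to_pc(self):
        r = assemble_rates(VARIANTS["CNSV"], COND, {"kc": 10.0, "kg": 1.0, "kd": 0.5})
        st = back_substitute(0.5, r)
        # kmc = 0, kr = 1: Pcf = kf*Pc/(kr+kmc) = Pc
        assert st.Pcf == pytest.approx(r.kf * st.Pc / (r.kr + r.kmc))

    def test_no_background_binding_without_kmr(self):
        r = assemble_rates(VARIANTS["PHYS"], COND,
                           {"kc": 10.0, "kg": 1.0, "kmg": 0.1, "kd": 0.5})
        assert back_substitute(0.5, r).Pcb == 0.0

    def test_ca_out_of_range_rejected(self):
        r = assemble_rates(VARIANTS["OS"], COND, {"kc": 1.0, "kd": 1.0})
        with pytest.raises(ValueError):
            back_substitute(0.0, r)


class TestSolveSteadyState:
    def test_agrees_with_ode_oracle(self, phys_rates):
        ss = solve_steady_state(phys_rates)
        assert ss.exists
        ode = integrate_dynamics(phys_rates)
        assert ode.exists
        np.testing.assert_allclose(ss.state.to_array(), ode.state.to_array(),
                                   atol=1e-6)

    def test_residual_at_steady_state(self, phys_rates):
        ss = solve_steady_state(phys_rates)
        assert np.max(np.abs(dynamics_rhs(ss.state, phys_rates))) < 1e-8

    def test_chaperone_conservation(self, phys_rates):
        ss = solve_steady_state(phys_rates)
        s = ss.state
        total = s.Pc + s.Pcf + s.Pcs + s.Pcb + available_chaperone(s)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_flux_balances(self, phys_rates):
        ss = solve_steady_state(phys_rates)
        r, s = phys_rates, ss.state
        assert r.kp == pytest.approx(r.kf * s.Pc + r.kd * s.P, abs=1e-8)
        assert r.kps == pytest.approx(r.kd * s.Ps, abs=1e-8)

    def test_nonexistence_is_result_not_error(self):
        cond = Conditions(kpt=2.0, mf=0.001, kf=1.0, Pb=1.0)
        r = assemble_rates(VARIANTS["CNSV"], cond, {"kc": 100.0, "kg": 10.0, "kd": 1.0})
        ss = solve_steady_state(r)
        assert not ss.exists
        assert "no feasible root" in ss.diagnosis


class TestIntegrateDynamics:
    def test_steady_init_returned_unchanged(self, phys_rates):
        ss = solve_steady_state(phys_rates)
        ode = integrate_dynamics(phys_rates, init=ss.state)
        assert ode.exists
        np.testing.assert_allclose(ode.state.to_array(), ss.state.to_array(),
                                   atol=1e-9)

    def test_unbounded_accumulation_detected(self):
        cond = Conditions(kpt=2.0, mf=0.001, kf=1.0, Pb=1.0)
        r = assemble_rates(VARIANTS["WB"], cond,
                           {"kc": 100.0, "kmc": 1.0, "kd": 1.0})
        ode = integrate_dynamics(r)
        assert not ode.exists
        assert "unbounded accumulation" in ode.diagnosis

    def test_rejects_bad_arguments(self, phys_rates):
        with pytest.raises(ValueError):
            integrate_dynamics(phys_rates, horizon=-1.0)
        with pytest.raises(ValueError):
            integrate_dynamics(phys_rates, init=StateVector(Pg=-1, Pc=0, Pcf=0, P=0))


class TestExistence:
    @pytest.mark.parametrize("variant,free", [
        ("PHYS", {"kc": 100.0, "kg": 10.0, "kmg": 0.01, "kd": 1.0}),
        ("CNSV", {"kc": 100.0, "kg": 10.0, "kd": 1.0}),
        ("WB", {"kc": 100.0, "kmc": 10.0, "kd": 1.0}),
    ])
    def test_exists_at_low_production(self, variant, free):
        cond = Conditions(kpt=0.5, mf=0.001, kf=1.0, Pb=1.0)
        ok, diag = steady_state_exists(assemble_rates(VARIANTS[variant], cond, free))
        assert ok, diag

    def test_cnsv_saturates_above_unit_production(self):
        # release capacity is kr*Ctot = 1: production 1.5 cannot be processed
        cond = Conditions(kpt=1.5, mf=0.001, kf=1.0, Pb=1.0)
        for free in ({"kc": 100.0, "kg": 10.0, "kd": 1.0},
                     {"kc": 1000.0, "kg": 0.001, "kd": 1000.0}):
            ok, _ = steady_state_exists(assemble_rates(VARIANTS["CNSV"], cond, free))
            assert not ok
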