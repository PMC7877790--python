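import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoqc.model import (
    Conditions,
    ModelVariant,
    RateSet,
    StateVector,
    VARIANTS,
    assemble_rates,
    available_chaperone,
    cycle_energy,
    dynamics_rhs,
    folding_fraction,
    total_unfolded,
)

COND = Conditions(kpt=0.1, mf=0.001, kf=1.0, Pb=1.0)


class TestConditions:
    def test_production_split(self):
        assert COND.kp == pytest.approx(0.0999)
        assert COND.kps == pytest.approx(1e-4)

    @pytest.mark.parametrize("kwargs", [
        dict(kpt=0.0, mf=0.1, kf=1.0, Pb=1.0),
        dict(kpt=0.1, mf=1.2, kf=1.0, Pb=1.0),
        dict(kpt=0.1, mf=-0.1, kf=1.0, Pb=1.0),
        dict(kpt=0.1, mf=0.1, kf=-1.0, Pb=1.0),
        dict(kpt=0.1, mf=0.1, kf=1.0, Pb=-1.0),
    ])
    def test_invalid_conditions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Conditions(**kwargs)


class TestAssembleRates:
    def test_phys_mask(self):
        r = assemble_rates(VARIANTS["PHYS"], COND,
                           {"kc": 10.0, "kg": 1.0, "kmg": 0.1, "kd": 0.5})
        assert r.kmc == 0.0 and r.kmr == 0.0 and r.kr == 1.0
        assert r.kp == pytest.approx(0.0999)
        assert r.kps == pytest.approx(1e-4)

    def test_os_mask(self):
        r = assemble_rates(VARIANTS["OS"], COND, {"kc": 10.0, "kd": 0.5})
        assert r.kmc == r.kmr == r.kg == r.kmg == 0.0

    def test_ntm_mask(self):
        r = assemble_rates(VARIANTS["NTM"], COND,
                           {"kc": 10.0, "kg": 1.0, "kmg": 0.1, "kd": 0.5})
        assert r.kr == 0.0 and r.kmc == 1.0 and r.kmr == 0.0

    def test_non_free_rate_rejected(self):
        with pytest.raises(ValueError, match="kmr"):
            assemble_rates(VARIANTS["PHYS"], COND,
                           {"kc": 10.0, "kg": 1.0, "kmg": 0.1, "kd": 0.5, "kmr": 0.5})

    def test_missing_rate_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            assemble_rates(VARIANTS["PHYS"], COND, {"kc": 10.0})

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            assemble_rates(VARIANTS["OS"], COND, {"kc": 1e4, "kd": 0.5})


class TestModelVariant:
    def test_masks_partition_adjustable_rates(self):
        for v in VARIANTS.values():
            names = sorted((*v.free_rates, *v.fixed_zero, *v.fixed_other))
            assert names == sorted(("kc", "kmc", "kmr", "kg", "kmg", "kd"))

    def test_bad_partition_rejected(self):
        with pytest.raises(ValueError):
            ModelVariant("BAD", ("kc", "kd"), ("kmc",))

    def test_pin_moves_rate(self):
        pinned = VARIANTS["FULL"].pin(kmr=0.5)
        assert "kmr" not in pinned.free_rates
        assert pinned.fixed_other["kmr"] == 0.5
        with pytest.raises(ValueError):
            VARIANTS["PHYS"].pin(kmr=0.5)  # not free in PHYS


class TestDynamics:
    def test_source_terms_only_at_empty_state(self):
        r = assemble_rates(VARIANTS["PHYS"], COND,
                           {"kc": 10.0, "kg": 1.0, "kmg": 0.1, "kd": 0.5})
        d = dynamics_rhs(StateVector.zero(), r)
        expected = np.zeros(8)
        expected[0] = r.kp    # dPg/dt
        expected[4] = r.kps   # dPg*/dt
        np.testing.assert_allclose(d, expected, atol=1e-15)

    def test_background_binding_feeds_pcb(self):
        r = assemble_rates(VARIANTS["FULL"], COND,
                           {"kc": 1.0, "kmc": 1.0, "kmr": 2.0, "kg": 1.0,
                            "kmg": 1.0, "kd": 1.0})
        d = dynamics_rhs(StateVector.zero(), r)
        # empty chaperone (CA=1), reservoir Pb=1: influx kmr*CA*Pb
        assert d[7] == pytest.approx(2.0)

    def test_negative_state_rejected(self):
        r = assemble_rates(VARIANTS["OS"], COND, {"kc": 1.0, "kd": 1.0})
        with pytest.raises(ValueError):
            dynamics_rhs(StateVector(Pg=-0.1, Pc=0, Pcf=0, P=0), r)

    def test_chaperone_bound_derivative_matches_closure(self):
        # d(Pc+Pcf+Pcs+Pcb)/dt must equal -dCA/dt by the conservation law
        r = assemble_rates(VARIANTS["FULL"], COND,
                           {"kc": 3.0, "kmc": 0.5, "kmr": 0.2, "kg": 1.0,
                            "kmg": 0.3, "kd": 0.7})
        s = StateVector(Pg=0.2, Pc=0.1, Pcf=0.05, P=0.3, Pgs=0.1, Pcs=0.05,
                        Ps=0.2, Pcb=0.1)
        d = dynamics_rhs(s, r)
        bound = d[1] + d[2] + d[5] + d[7]  # Pc, Pcf, Pcs, Pcb
        eps = 1e-7
        # finite-difference dCA/dt along the flow
        s2 = StateVector.from_array(np.maximum(s.to_array() + eps * d, 0))
        dca = (available_chaperone(s2) - available_chaperone(s)) / eps
        assert bound == pytest.approx(-dca, rel=1e-5)


class TestMetrics:
    def test_available_chaperone_values(self):
        assert available_chaperone(StateVector.zero()) == 1.0
        s = StateVector(Pg=0, Pc=0.3, Pcf=0.2, P=0, Pcs=0.1, Pcb=0.1)
        assert available_chaperone(s) == pytest.approx(0.3)
        full = StateVector(Pg=0, Pc=0.5, Pcf=0.3, P=0, Pcs=0.1, Pcb=0.1)
        assert available_chaperone(full) == pytest.approx(0.0)

    def test_cycle_energy_detailed_balance(self):
        r = RateSet(kc=1, kmc=1, kmr=1, kg=1, kmg=1, kd=1, kf=1, kp=0.1,
                    kps=0.0, Pb=0.0)
        assert cycle_energy(r) == pytest.approx(0.0)

    def test_cycle_energy_value(self):
        r = RateSet(kc=10, kmc=0.1, kmr=0.1, kg=10, kmg=0.1, kd=1, kf=1,
                    kp=0.1, kps=0.0, Pb=0.0)
        assert cycle_energy(r) == pytest.approx(math.log(1e5))

    def test_cycle_energy_unbounded_when_irreversible(self):
        r = RateSet(kc=10, kmc=0.1, kmr=0.0, kg=10, kmg=0.1, kd=1, kf=1,
                    kp=0.1, kps=0.0, Pb=0.0)
        assert cycle_energy(r) == math.inf

    def test_cycle_energy_zero_forward_rejected(self):
        r = RateSet(kc=0.0, kmc=0.1, kmr=0.1, kg=10, kmg=0.1, kd=1, kf=1,
                    kp=0.1, kps=0.0, Pb=0.0)
        with pytest.raises(ValueError):
            cycle_energy(r)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1e-3, 1e3), st.floats(1e-3, 1e3),
           st.floats(1e-3, 1e3), st.floats(1e-3, 1e3))
    def test_cycle_energy_antisymmetric(self, kc, kmc, kg, kmg):
        fwd = RateSet(kc=kc, kmc=kmc, kmr=1.0, kg=kg, kmg=kmg, kd=1, kf=1,
                      kp=0.1, kps=0.0, Pb=0.0)
        rev = RateSet(kc=kmc, kmc=kc, kmr=1.0, kg=kmg, kmg=kg, kd=1, kf=1,
                      kp=0.1, kps=0.0, Pb=0.0)
        assert cycle_energy(fwd) == pytest.approx(-cycle_energy(rev), abs=1e-12)

    def test_folding_fraction(self):
        r = RateSet(kc=1, kmc=0, kmr=0, kg=1, kmg=0.1, kd=1, kf=1.0,
                    kp=0.1, kps=0.0, Pb=0.0)
        s = StateVector(Pg=0, Pc=0.05, Pcf=0, P=0)
        assert folding_fraction(s, r) == pytest.approx(0.5)
        r0 = r.with_(kf=0.0)
        assert folding_fraction(s, r0) == 0.0
        with pytest.raises(ValueError):
            folding_fraction(s, r.with_(kp=0.0))

    def test_total_unfolded_excludes_folded_and_background(self):
        assert total_unfolded(StateVector.zero()) == 0.0
        s = StateVector(Pg=0.1, Pc=0.1, Pcf=0.4, P=0.1, Pgs=0.05, Pcs=0.05,
                        Ps=0.05, Pcb=0.2)
        assert total_unfolded(s) == pytest.approx(0.45)
        assert total_unfolded(StateVector(Pg=0, Pc=0, Pcf=1.0, P=0)) == 0.0
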