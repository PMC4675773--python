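"""Gas transport, shunt, dead space and the metabolic Fick closure."""

import numpy as np
import pytest

import ardsim._kernel as kernel
from ardsim.gas_exchange import (CirculationConfig, GasDynamics,
                                 InfeasibleCirculationError, arterial_mix,
                                 gas_flux, inspired_po2, mixed_venous_update,
                                 physiological_dead_space, steady_state_gas)
from ardsim.mechanics import CompartmentSet, VentilatorSettings, run_breaths
from ardsim import blood


def settled_gas(comp, vent, circ, fio2):
    summary = run_breaths(comp, vent, 600.0)
    return summary, steady_state_gas(summary.dV, comp.q_frac, circ, fio2,
                                     v_t=vent.V_T, rr=vent.RR)


class TestMixedVenous:
    def test_zero_uptake_keeps_contents(self):
        circ = CirculationConfig(CO=10.0, Hb=100.0, VO2=1e-9, VCO2=1e-9)
        cv_o2, cv_co2 = mixed_venous_update(15.0, 48.0, circ)
        assert cv_o2 == pytest.approx(15.0)
        assert cv_co2 == pytest.approx(48.0)

    def test_fick_arithmetic(self):
        circ = CirculationConfig(CO=10.0, Hb=100.0, VO2=250.0, VCO2=200.0)
        cv_o2, _ = mixed_venous_update(18.0, 48.0, circ)
        assert 18.0 - cv_o2 == pytest.approx(2.5)

    def test_doubling_cardiac_output_halves_av_difference(self):
        d = []
        for co in (5.0, 10.0):
            circ = CirculationConfig(CO=co, Hb=100.0, VO2=250.0, VCO2=200.0)
            cv_o2, _ = mixed_venous_update(18.0, 48.0, circ)
            d.append(18.0 - cv_o2)
        assert d[0] == pytest.approx(2 * d[1])

    def test_exhausted_venous_oxygen_is_infeasible(self):
        circ = CirculationConfig(CO=1.0, Hb=100.0, VO2=250.0, VCO2=200.0)
        with pytest.raises(InfeasibleCirculationError):
            mixed_venous_update(10.0, 48.0, circ)


class TestArterialMix:
    def test_no_shunt_when_everything_ventilated(self):
        n = 5
        cc = np.full(n, 19.0)
        bg = arterial_mix(cc, np.full(n, 46.0), np.full(n, 0.2),
                          np.ones(n, bool), cv_o2=14.0, cv_co2=50.0, hb=140.0)
        assert bg.shunt_frac == pytest.approx(0.0)

    def test_total_shunt_returns_venous_blood(self):
        n = 4
        bg = arterial_mix(np.full(n, 19.0), np.full(n, 46.0),
                          np.full(n, 0.25), np.zeros(n, bool),
                          cv_o2=14.0, cv_co2=50.0, hb=140.0)
        assert bg.shunt_frac == 1.0
        assert bg.CaO2 == pytest.approx(14.0)
        assert bg.PaO2 == pytest.approx(blood.o2_tension(14.0, 140.0))

    def test_two_population_shunt_fraction_emerges(self):
        # 7 of 20 equally-perfused units collapsed -> venous admixture 0.35
        n = 20
        top = np.full(n, 10.0)
        s = np.full(n, 0.05)
        pext = np.full(n, 0.0)
        top[:7] = 55.0
        pext[:7] = 25.0     # collapse during expiration, never reopen
        c = CompartmentSet.from_parameters(top, s, pext)
        c.equilibrate(5.0)
        c.is_open[:] = True
        vent = VentilatorSettings(V_T=560, RR=12.5, DC=0.33, PEEP=5, FiO2=0.5)
        _, g = settled_gas(c, vent, CirculationConfig(CO=5.0, Hb=150.0), 0.5)
        assert g.blood.shunt_frac == pytest.approx(0.35, abs=0.01)


class TestSteadyState:
    def test_unventilated_compartments_carry_venous_blood(self):
        n = 6
        dv = np.zeros(n)
        dv[3:] = 150.0
        q = np.full(n, 1 / n)
        g = steady_state_gas(dv, q, CirculationConfig(CO=5.0, Hb=150.0),
                             0.6, v_t=450.0, rr=15.0)
        np.testing.assert_allclose(g.PA_O2[:3], g.blood.PvO2, rtol=1e-3)
        np.testing.assert_allclose(g.PA_CO2[:3], g.blood.PvCO2, rtol=1e-3)

    def test_alveolar_gas_equation_limit(self, homogeneous_lung):
        # homogeneous lung with RQ = 1: PAO2 ~ PIO2 - PACO2
        vent = VentilatorSettings(V_T=500, RR=15, DC=0.33, PEEP=5.0, FiO2=1.0)
        circ = CirculationConfig(CO=5.0, Hb=150.0, VO2=250.0, VCO2=250.0)
        _, g = settled_gas(homogeneous_lung, vent, circ, 1.0)
        assert g.PA_O2[0] == pytest.approx(
            inspired_po2(1.0) - g.PA_CO2[0], abs=2.0)

    def test_fluxes_balance_metabolic_rates(self, homogeneous_lung):
        vent = VentilatorSettings(V_T=500, RR=15, DC=0.33, PEEP=5.0, FiO2=0.21)
        circ = CirculationConfig(CO=5.0, Hb=150.0, VO2=250.0, VCO2=200.0)
        s, g = settled_gas(homogeneous_lung, vent, circ, 0.21)
        vo2, vco2 = gas_flux(g, s.dV, homogeneous_lung.q_frac, circ,
                             vent.RR, vent.V_T)
        assert vo2 == pytest.approx(250.0, rel=0.02)
        assert vco2 == pytest.approx(200.0, rel=0.02)

    def test_paco2_strictly_decreasing_in_tidal_volume(self, baseline_vent):
        paco2 = []
        for vt in (300.0, 450.0, 600.0):
            c = CompartmentSet.homogeneous(10, TOP=5.0, S=0.05, P_ext=0.0)
            c.equilibrate(5.0)
            vent = VentilatorSettings(V_T=vt, RR=12.5, DC=0.33, PEEP=5.0)
            _, g = settled_gas(c, vent, CirculationConfig(CO=5.0, Hb=150.0),
                               0.21)
            paco2.append(g.blood.PaCO2)
        assert paco2[0] > paco2[1] > paco2[2]


class TestDeadSpace:
    def test_enghoff_arithmetic(self):
        r = physiological_dead_space(500.0, 40.0, 27.2)
        assert r.V_D_phys == pytest.approx(160.0)

    def test_no_co2_cleared_means_all_dead_space(self):
        r = physiological_dead_space(500.0, 40.0, 0.0)
        assert r.V_D_phys == pytest.approx(500.0)

    def test_rejects_nonpositive_paco2(self):
        with pytest.raises(ValueError):
            physiological_dead_space(500.0, 0.0, 20.0)

    def test_homogeneous_shunt_free_lung_recovers_anatomical_value(
            self, homogeneous_lung, baseline_vent):
        _, g = settled_gas(homogeneous_lung, baseline_vent,
                           CirculationConfig(CO=5.0, Hb=150.0), 0.21)
        assert g.dead_space.V_D_phys == pytest.approx(160.0, rel=0.05)


class TestDynamicRoute:
    def test_time_sliced_integration_agrees_with_algebraic_solution(self):
        """Independent cross-check: explicit store-by-store integration of
        the gas transport converges to the bisection steady state."""
        c = CompartmentSet.homogeneous(6, TOP=5.0, S=0.05, P_ext=0.0)
        c.equilibrate(5.0)
        vent = VentilatorSettings(V_T=500, RR=15, DC=0.33, PEEP=5.0, FiO2=0.21)
        circ = CirculationConfig(CO=5.0, Hb=150.0, VO2=250.0, VCO2=250.0)
        s = run_breaths(c.copy(), vent, 300.0)
        g = steady_state_gas(s.dV, c.q_frac, circ, 0.21, vent.V_T, vent.RR)
        gd = GasDynamics(compartments=c, circ=circ, fio2=0.21, tau_venous=5.0)
        dt = 0.01
        for _ in range(int(120 / vent.t_cycle)):
            for phase, paw_flow in (("insp", vent.F_insp), ("exp", vent.PEEP)):
                t_ph = vent.t_insp if phase == "insp" else vent.t_cycle - vent.t_insp
                tau = 0.0
                while tau < t_ph - 1e-12:
                    h = min(dt, t_ph - tau)
                    v0 = c.V.copy()
                    if phase == "insp":
                        paw = kernel.solve_paw(c.TOP, c.S, c.P_ext, c.R_aw,
                                               c.V, c.is_open, vent.F_insp)
                    else:
                        paw = vent.PEEP
                    kernel.step_paw(c.TOP, c.S, c.P_ext, c.R_aw, c.V,
                                    c.is_open, paw, h)
                    gd.step(c.V - v0, h)
                    tau += h
        bg = gd.blood_gas()
        assert bg.PaO2 == pytest.approx(g.blood.PaO2, rel=0.03)
        assert bg.PaCO2 == pytest.approx(g.blood.PaCO2, rel=0.03)
        assert bg.PvCO2 == pytest.approx(g.blood.PvCO2, rel=0.03)
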