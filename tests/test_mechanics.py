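"""Mechanics of the parallel-compartment lung."""

import numpy as np
import pytest

from ardsim.mechanics import (AlveolarCompartment, CompartmentSet,
                              MechanicsState, SimulationError,
                              VentilatorSettings, compartment_pressure,
                              dynamic_compliance, dynamic_strain,
                              peak_alveolar_pressure, run_breaths,
                              simulate_breaths_dense, step_mechanics)
from conftest import random_lung


def make_state(comp: CompartmentSet) -> MechanicsState:
    return MechanicsState(t=0.0, compartments=comp)


class TestCompartmentPressure:
    @pytest.mark.parametrize("S,V,P_ext,expected", [
        (0.05, 0.0, 0.0, 0.0),
        (0.05, 10.0, 28.8, 33.8),
        (0.5, 10.0, -20.0, 30.0),
    ])
    def test_quadratic_recoil(self, S, V, P_ext, expected):
        c = AlveolarCompartment(index=1, TOP=30.0, S=S, P_ext=P_ext, V=V)
        assert compartment_pressure(c) == pytest.approx(expected)

    def test_strictly_increasing_in_volume(self):
        ps = [compartment_pressure(
            AlveolarCompartment(index=1, S=0.05, P_ext=0.0, V=v))
            for v in (1.0, 5.0, 20.0)]
        assert ps == sorted(ps) and len(set(ps)) == 3

    def test_negative_volume_is_integrator_fault(self):
        c = AlveolarCompartment(index=3, V=1.0)
        c.V = -1.0
        with pytest.raises(SimulationError):
            compartment_pressure(c)

    def test_bounds_enforced_on_construction(self):
        with pytest.raises(ValueError):
            AlveolarCompartment(index=1, TOP=61.0)
        with pytest.raises(ValueError):
            AlveolarCompartment(index=1, P_ext=29.0)


class TestStepMechanics:
    def test_homogeneous_lung_stays_symmetric(self):
        c = CompartmentSet.homogeneous(8, TOP=5.0, S=0.05, P_ext=0.0)
        c.equilibrate(5.0)
        state = make_state(c)
        for _ in range(200):
            state = step_mechanics(state, 15.0, 0.005)
        assert np.ptp(state.compartments.V) == 0.0

    def test_collapsed_below_threshold_stays_collapsed(self):
        c = CompartmentSet.homogeneous(4, TOP=30.0, S=0.05, P_ext=0.0)
        c.is_open[:] = False
        state = step_mechanics(make_state(c), 30.0 - 1e-6, 0.005)
        assert not state.compartments.is_open.any()
        assert state.flow_total == 0.0

    def test_reopens_at_threshold(self):
        c = CompartmentSet.homogeneous(4, TOP=30.0, S=0.05, P_ext=0.0)
        c.is_open[:] = False
        state = step_mechanics(make_state(c), 30.0, 0.005)
        assert state.compartments.is_open.all()

    def test_converges_to_static_volume(self):
        # one open compartment at constant pressure settles at the volume
        # solving S*V^2 + P_ext = P_aw (closed-form fixed point)
        c = CompartmentSet.from_parameters([10.0], [0.09], [2.0],
                                           scale_to=None)
        state = make_state(c)
        paw = 20.0
        for _ in range(20000):
            state = step_mechanics(state, paw, 0.005)
        v_star = np.sqrt((paw - 2.0) / 0.09)
        assert state.compartments.V[0] == pytest.approx(v_star, rel=1e-4)

    def test_raising_pressure_never_closes_open_units(self):
        c = random_lung(4)
        state = make_state(c)
        state = step_mechanics(state, 20.0, 0.005)
        open_before = state.compartments.is_open.copy()
        state = step_mechanics(state, 40.0, 0.005)
        assert (state.compartments.is_open | ~open_before).all()

    def test_rejects_oversized_step(self):
        c = CompartmentSet.homogeneous(4)
        with pytest.raises(ValueError):
            step_mechanics(make_state(c), 10.0, 0.05)


class TestRunBreaths:
    def test_zero_duration_leaves_state_unchanged(self, homogeneous_lung,
                                                  baseline_vent):
        v0 = homogeneous_lung.V.copy()
        assert run_breaths(homogeneous_lung, baseline_vent, 0.0) is None
        np.testing.assert_array_equal(homogeneous_lung.V, v0)

    def test_inspiratory_timing(self):
        # DC * 60/RR: 0.33 * 60/12.5 = 1.584 s of a 4.8 s cycle
        v = VentilatorSettings(V_T=560, RR=12.5, DC=0.33)
        assert v.t_insp == pytest.approx(1.584)
        assert v.t_cycle == pytest.approx(4.8)

    def test_commanded_flow_matches_settings_table(self):
        v = VentilatorSettings(V_T=385, RR=24, DC=0.33)
        assert v.F_insp == pytest.approx(466.67, abs=0.01)

    def test_delivers_tidal_volume(self, homogeneous_lung, baseline_vent):
        s = run_breaths(homogeneous_lung, baseline_vent, 120.0)
        assert s.dV.sum() == pytest.approx(baseline_vent.V_T, rel=1e-6)

    def test_pressure_cap_reported_not_truncated(self, baseline_vent):
        # a stiff 4-unit lung forced to take a full tidal volume
        c = CompartmentSet.from_parameters([5.0] * 4, [0.05] * 4, [0.0] * 4,
                                           scale_to=None)
        c.equilibrate(5.0)
        messages = []
        s = run_breaths(c, baseline_vent, 60.0, warn=messages.append)
        assert s.cap_exceeded and messages
        assert s.dV.sum() == pytest.approx(baseline_vent.V_T, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_conservation_per_breath(self, seed):
        c = random_lung(seed)
        vent = VentilatorSettings(V_T=400, RR=20, DC=0.33, PEEP=5.0)
        start = c.V.sum()
        t, paw, flow, V, op = simulate_breaths_dense(c, vent, 3, dt=0.005)
        integrated = np.sum(flow * np.diff(np.concatenate([[0.0], t])))
        assert abs((V[-1].sum() - start) - integrated) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_dt_halving_changes_volume_below_tenth_percent(self, seed):
        vent = VentilatorSettings(V_T=400, RR=20, DC=0.33, PEEP=5.0)
        res = []
        for dt in (0.005, 0.0025):
            c = random_lung(seed)
            s = run_breaths(c, vent, 60.0, dt=dt, min_breaths=10)
            res.append(s.v_lung_end_insp)
        assert abs(res[0] - res[1]) / res[1] < 1e-3

    def test_dense_path_agrees_with_compiled_loop(self, baseline_vent):
        c1 = random_lung(7)
        c2 = c1.copy()
        simulate_breaths_dense(c1, baseline_vent, 2, dt=0.005)
        run_breaths(c2, baseline_vent, 2 * baseline_vent.t_cycle, dt=0.005,
                    settle_tol=0.0)
        np.testing.assert_allclose(c1.V, c2.V, atol=1e-9)


class TestAggregates:
    def test_peak_pressure_mean_of_top_quartile(self):
        assert peak_alveolar_pressure(np.arange(1.0, 101.0)) == pytest.approx(88.0)

    def test_peak_pressure_identity_on_uniform(self):
        assert peak_alveolar_pressure(np.full(40, 17.3)) == pytest.approx(17.3)

    def test_peak_pressure_outlier(self):
        p = np.full(100, 10.0)
        p[0] = 50.0
        assert peak_alveolar_pressure(p) == pytest.approx((50 + 24 * 10) / 25)

    def test_peak_pressure_needs_four_units(self):
        with pytest.raises(ValueError):
            peak_alveolar_pressure([1.0, 2.0, 3.0])

    @pytest.mark.parametrize("vt,frc,expected", [(560, 2000, 0.28),
                                                 (0.0, 1500, 0.0),
                                                 (272.5, 1090, 0.25)])
    def test_dynamic_strain(self, vt, frc, expected):
        assert dynamic_strain(vt, frc) == pytest.approx(expected)

    def test_dynamic_strain_rejects_nonpositive_frc(self):
        with pytest.raises(ValueError):
            dynamic_strain(560, 0.0)

    def test_compliance_arithmetic(self, homogeneous_lung, baseline_vent):
        s = run_breaths(homogeneous_lung, baseline_vent, 120.0)
        cd = dynamic_compliance(s, baseline_vent)
        assert cd == pytest.approx(
            baseline_vent.V_T / (s.paw_end_insp - baseline_vent.PEEP))

    def test_compliance_invariant_to_tidal_volume_in_linear_lung(self):
        # a nearly linear single-compartment lung: halving V_T leaves the
        # volume/pressure-swing ratio almost unchanged
        out = []
        for vt in (100.0, 50.0):
            c = CompartmentSet.from_parameters([5.0], [1e-5], [0.0],
                                               scale_to=None, validate=False,
                                               R_aw=[0.015], V_rest=[3000.0])
            c.equilibrate(5.0)
            vent = VentilatorSettings(V_T=vt, RR=12.5, DC=0.33, PEEP=5.0)
            s = run_breaths(c, vent, 120.0)
            out.append(dynamic_compliance(s, vent))
        assert out[0] == pytest.approx(out[1], rel=0.05)
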