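"""Genetic-algorithm patient matching."""

import numpy as np
import pytest

from ardsim import (GAConfig, ParameterVector, configure_patient, cost_ET,
                    ga_minimize, run_ga, simulate_to_steady_state)
from ardsim.matching import (derive_metabolic_rates, structured_population)
from conftest import MATCH_CONFIG, N_REDUCED


class TestCostET:
    def test_perfect_match_is_zero(self):
        data = {"PaO2": 100.0, "PvO2": 40.0, "PvCO2": 46.0, "shunt": 20.0}
        assert cost_ET(dict(data), data) == 0.0

    def test_ten_percent_on_one_output(self):
        data = {"PaO2": 100.0, "PvO2": 40.0}
        model = {"PaO2": 110.0, "PvO2": 40.0}
        assert cost_ET(model, data) == pytest.approx(0.01)

    def test_published_patient_fit_worked_value(self, datasets, fixtures):
        # the printed model-vs-data columns of the mildest patient give a
        # total squared relative error of 0.00771
        a = datasets["A"]
        assert cost_ET(fixtures["model_fits"]["A"], a.targets) == pytest.approx(
            0.00771, abs=1e-4)

    def test_missing_output_rejected(self):
        with pytest.raises(KeyError):
            cost_ET({"PaO2": 100.0}, {"PaO2": 100.0, "shunt": 30.0})


class TestParameterVector:
    def test_nominal_vector_configures_valid_patient(self, datasets):
        p = configure_patient(datasets["A"], ParameterVector.nominal(N_REDUCED))
        assert p.n == N_REDUCED
        assert p.compartments.q_frac.sum() == pytest.approx(1.0, abs=1e-9)
        # baseline tidal volume is 8 ml/kg x 70 kg
        assert p.vent_baseline.V_T == pytest.approx(560.0)

    def test_out_of_bounds_rejected(self):
        v = ParameterVector.nominal(10).values.copy()
        v[0] = 61.0
        with pytest.raises(ValueError):
            ParameterVector(v)

    def test_metabolic_rates_follow_fick_from_targets(self, datasets):
        # patient A: measured contents imply VO2 = 10*CO*(CaO2-CvO2) ~ 417
        vo2, vco2 = derive_metabolic_rates(datasets["A"])
        assert vo2 == pytest.approx(417.0, rel=0.01)
        assert 0 < vco2 < vo2


class TestGACore:
    def test_degenerate_population_is_stationary(self):
        lo = np.zeros(4)
        hi = np.ones(4)
        x0 = np.full(4, 0.5)
        cfg = GAConfig(population=8, generations=5, crossover_rate=0.0,
                       mutation_indpb=0.0, seed=1, threshold=1e-12)
        init = np.tile(x0, (8, 1))
        best, cost, hist, _ = ga_minimize(lambda x: float(np.sum(x ** 2)),
                                          lo, hi, cfg, init_population=init)
        np.testing.assert_array_equal(best, x0)
        assert all(h[1] == hist[0][1] for h in hist)

    def test_best_cost_monotone_nonincreasing(self):
        lo, hi = ParameterVector.bounds(10)
        rng = np.random.default_rng(3)
        xstar = lo + rng.random(30) * (hi - lo)
        cfg = GAConfig(population=20, generations=40, seed=3, threshold=1e-12)
        _, _, hist, _ = ga_minimize(
            lambda x: float(np.mean(((x - xstar) / (hi - lo)) ** 2)),
            lo, hi, cfg)
        best = [h[1] for h in hist]
        assert all(b2 <= b1 for b1, b2 in zip(best, best[1:]))

    def test_quadratic_surrogate_converges(self):
        # 300 bounded variables, no simulator in the loop
        lo, hi = ParameterVector.bounds(100)
        rng = np.random.default_rng(0)
        xstar = lo + rng.random(300) * (hi - lo)
        span = hi - lo
        cfg = GAConfig(population=60, generations=400, seed=1, threshold=1e-12)
        _, best, _, _ = ga_minimize(
            lambda x: float(np.mean(((x - xstar) / span) ** 2)), lo, hi, cfg)
        assert best < 1e-3

    def test_seeded_runs_are_identical(self, datasets):
        cfg = GAConfig(population=12, generations=3, seed=42, threshold=1e-9)
        r1 = run_ga(datasets["C"], cfg, n_compartments=N_REDUCED)
        r2 = run_ga(datasets["C"], cfg, n_compartments=N_REDUCED)
        np.testing.assert_array_equal(r1.params.values, r2.params.values)
        assert r1.history == r2.history

    def test_candidates_respect_bounds(self):
        lo = np.array([0.0, -1.0])
        hi = np.array([1.0, 1.0])
        seen = []

        def cost(x):
            seen.append(x.copy())
            return float(np.sum(x ** 2))

        ga_minimize(cost, lo, hi, GAConfig(population=10, generations=10,
                                           seed=0, threshold=1e-12,
                                           mutation_scale=0.5))
        arr = np.array(seen)
        assert (arr >= lo).all() and (arr <= hi).all()

    def test_structured_population_within_bounds(self):
        lo, hi = ParameterVector.bounds(10)
        pop = structured_population(np.random.default_rng(0), 30, 10)
        assert (pop >= lo).all() and (pop <= hi).all()


class TestFixtureMatching:
    def test_matched_outputs_reproduce_targets(self, datasets,
                                               matched_patients):
        """Output recovery on the two feasible printed datasets: the fit
        reaches the termination region and every matched output lands
        within 5% of its measured value."""
        for pid in ("B", "C"):
            r = matched_patients[pid]
            assert r.cost <= 0.02
            for k, d in datasets[pid].targets.items():
                assert r.outputs[k] == pytest.approx(d, rel=0.05), (pid, k)

    def test_severity_ordering_preserved(self, matched_patients):
        pf = {}
        for pid, r in matched_patients.items():
            p = r.patient.copy()
            p.reset_state()
            pf[pid] = simulate_to_steady_state(p).pf_ratio
        assert pf["A"] > pf["B"] > pf["C"]

    def test_synthetic_self_recovery(self):
        """Matching a generated patient's own observations recovers the
        outputs (E_T <= 0.01) even though parameters are unidentifiable."""
        from ardsim import SyntheticPatientSpec, generate_patient, observed_dataset
        p, s = generate_patient(SyntheticPatientSpec(seed=5, severity="moderate",
                                                     n=N_REDUCED), verify=False)
        ds = observed_dataset(p, s)
        r = run_ga(ds, GAConfig(population=48, generations=120, seed=5,
                                threshold=0.005), n_compartments=N_REDUCED)
        assert r.cost <= 0.01
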