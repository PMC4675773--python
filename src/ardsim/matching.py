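"""Configure virtual patients from blood-gas datasets.

The matching problem: find per-compartment threshold opening pressures,
stiffnesses and extrinsic pressures (3n parameters) such that the simulated
arterial/mixed-venous gases and shunt reproduce a patient's measurements.
The fit quality is the total squared relative error

    E_T = sum_i ((x_i - x_id)/x_id)^2

over the matched outputs {PaO2, PvO2, PvCO2, shunt}.  A seeded generational
genetic algorithm (tournament selection, blend crossover, annealed Gaussian
mutation, elitism) searches the bounded parameter box.  The problem is
heavily under-determined — 3n parameters against four outputs — so the
contract is output recovery, never parameter recovery.

Global metabolism is configured from the dataset itself: O2 uptake follows
from the Fick principle applied to the measured arterial/venous contents,
and CO2 output is respiratory-quotient-scaled with a cap that keeps the
venous CO2 target reachable at the configured ventilation (see the methods
note for the rationale).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import blood
from .gas_exchange import (CirculationConfig, InfeasibleCirculationError,
                           VD_ANAT_DEFAULT)
from .mechanics import (CompartmentSet, VentilatorSettings, PEXT_BOUNDS,
                        PEXT_NOMINAL, S_BOUNDS, S_NOMINAL, TOP_BOUNDS,
                        TOP_NOMINAL)
from .patient import (IBW_DEFAULT, VirtualPatient, model_outputs,
                      simulate_to_steady_state)

MATCHED_OUTPUTS = ("PaO2", "PvO2", "PvCO2", "shunt")

#: respiratory quotient used to scale VCO2 from the Fick-derived VO2
RQ_DEFAULT = 0.8
#: fraction of the feasibility cap actually used for VCO2, leaving slack
#: for ventilation-perfusion spread within the aerated compartments
VCO2_CAP_SAFETY = 0.97

BAD_COST = 1.0e6


@dataclass
class PatientDataset:
    """One patient's measured configuration and matching targets."""

    id: str
    CO: float
    FiO2: float
    Hb: float
    PVR: float
    C_dyn: float
    DC: float
    RR: float
    targets: dict

    def __post_init__(self) -> None:
        if not 0 < self.FiO2 <= 1:
            raise ValueError("FiO2 must lie in (0, 1]")
        for k, v in self.targets.items():
            if v <= 0:
                raise ValueError(f"target {k} must be positive")


@dataclass
class ParameterVector:
    """Concatenated [TOP(n), S(n), P_ext(n)] with per-block bounds."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size % 3:
            raise ValueError("parameter vector length must be a multiple of 3")
        lo, hi = self.bounds(self.n)
        if np.any(self.values < lo) or np.any(self.values > hi):
            raise ValueError("parameter vector violates physiological bounds")

    @property
    def n(self) -> int:
        return self.values.size // 3

    @property
    def TOP(self) -> np.ndarray:
        return self.values[:self.n]

    @property
    def S(self) -> np.ndarray:
        return self.values[self.n:2 * self.n]

    @property
    def P_ext(self) -> np.ndarray:
        return self.values[2 * self.n:]

    @staticmethod
    def bounds(n: int):
        lo = np.concatenate([np.full(n, TOP_BOUNDS[0]), np.full(n, S_BOUNDS[0]),
                             np.full(n, PEXT_BOUNDS[0])])
        hi = np.concatenate([np.full(n, TOP_BOUNDS[1]), np.full(n, S_BOUNDS[1]),
                             np.full(n, PEXT_BOUNDS[1])])
        return lo, hi

    @classmethod
    def nominal(cls, n: int) -> "ParameterVector":
        return cls(np.concatenate([np.full(n, TOP_NOMINAL), np.full(n, S_NOMINAL),
                                   np.full(n, PEXT_NOMINAL)]))


@dataclass
class GAConfig:
    """Genetic-algorithm settings (all configurable; see methods note)."""

    population: int = 60
    generations: int = 150
    crossover_rate: float = 0.9
    crossover_alpha: float = 0.25  # blend extrapolation; 0 = arithmetic blend
    mutation_scale: float = 0.05   # sigma as fraction of each gene's range
    mutation_indpb: float = 0.15   # per-gene mutation probability
    mutation_decay: float = 0.995  # sigma anneal factor per generation
    tournament: int = 3
    elitism: int = 2
    seed: int = 0
    threshold: float = 0.01        # stop once best cost falls below this

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be at least 4")
        if self.threshold <= 0:
            raise ValueError("termination threshold must be positive")


def cost_ET(model: dict, data: dict) -> float:
    """Total squared relative matching error over the outputs in ``data``."""
    total = 0.0
    for key, x_id in data.items():
        if key not in model:
            raise KeyError(f"model outputs missing matched quantity '{key}'")
        if x_id == 0:
            raise ValueError(f"data value for '{key}' must be non-zero")
        e = (model[key] - x_id) / x_id
        total += e * e
    return total


def derive_metabolic_rates(dataset: PatientDataset,
                           v_t: float | None = None,
                           vd_anat: float = VD_ANAT_DEFAULT,
                           rq: float = RQ_DEFAULT,
                           cap_safety: float = VCO2_CAP_SAFETY):
    """Metabolic rates consistent with the dataset's blood-gas targets.

    VO2 follows directly from the Fick principle applied to the arterial
    and mixed-venous O2 contents implied by the targets.  VCO2 is rq*VO2,
    capped at the largest value for which the venous CO2 target remains
    reachable: at the configured ventilation the lowest attainable arterial
    CO2 content (every aerated unit ideally ventilated, the target shunt
    fraction admixing venous blood) is

        Ca_min = C(0.863*VCO2/V̇A) + f/(1-f) * VCO2/(10*CO)

    and the target implies Ca_req = C(PvCO2) - VCO2/(10*CO); VCO2 above the
    crossing point makes the target unreachable for any compartment
    parameters.  Returns (VO2, VCO2) in ml/min.
    """
    t = dataset.targets
    v_t = v_t if v_t is not None else 8.0 * IBW_DEFAULT
    ca = blood.o2_content(t["PaO2"], dataset.Hb)
    cv = blood.o2_content(t["PvO2"], dataset.Hb)
    vo2 = 10.0 * dataset.CO * (ca - cv)
    if vo2 <= 0:
        raise ValueError("targets imply non-positive O2 uptake")
    va_ideal = dataset.RR * (v_t - vd_anat) / 1000.0  # l/min BTPS
    cv_co2_t = blood.co2_content(t["PvCO2"])
    f = t.get("shunt", 0.0) / 100.0
    fac = 1.0 / (1.0 - f) if f < 1.0 else np.inf

    def margin(vco2):
        ca_req = cv_co2_t - vco2 / (10.0 * dataset.CO)
        if ca_req <= 1.0:
            return -1.0
        ca_min = (blood.co2_content(0.863 * vco2 / va_ideal)
                  + f * fac * vco2 / (10.0 * dataset.CO))
        return ca_req - ca_min

    lo, hi = 5.0, 10.0 * dataset.CO * (cv_co2_t - 1.0)
    if margin(hi) > 0:
        cap = hi
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if margin(mid) > 0:
                lo = mid
            else:
                hi = mid
        cap = 0.5 * (lo + hi)
    vco2 = min(rq * vo2, cap_safety * cap)
    if vco2 <= 5.0:
        raise ValueError("targets leave no feasible CO2 production")
    return vo2, vco2


def _dataset_seed(dataset_id: str) -> int:
    return zlib.crc32(dataset_id.encode()) & 0x7FFFFFFF


def perfusion_resistances(n: int, pvr: float, sigma: float = 0.3,
                          seed: int | None = None) -> np.ndarray:
    """Fixed per-compartment peri-alveolar vascular resistances.

    Mildly heterogeneous (lognormal spread ``sigma``), scaled so the
    parallel total equals the configured PVR.  Perfusion fractions follow
    as q_i ∝ 1/R_vasc,i (no hypoxic vasoconstriction).
    """
    rng = np.random.default_rng(seed)
    r = np.exp(rng.normal(0.0, sigma, size=n))
    scale = pvr / (1.0 / np.sum(1.0 / r))
    return r * scale


def baseline_settings(dataset: PatientDataset, peep: float = 5.0,
                      ibw: float = IBW_DEFAULT) -> VentilatorSettings:
    """Baseline ventilation during matching: V_T = 8 ml/kg IBW at the
    dataset's RR and duty cycle."""
    return VentilatorSettings(V_T=8.0 * ibw, RR=dataset.RR, DC=dataset.DC,
                              PEEP=peep, FiO2=dataset.FiO2)


def configure_patient(dataset: PatientDataset, params: ParameterVector,
                      peep: float = 5.0, ibw: float = IBW_DEFAULT,
                      rvasc_sigma: float = 0.3,
                      vd_anat: float = VD_ANAT_DEFAULT) -> VirtualPatient:
    """Build a virtual patient from a dataset and a compartment parameter
    vector; bound violations are rejected by :class:`ParameterVector`."""
    n = params.n
    rvasc = perfusion_resistances(n, dataset.PVR, rvasc_sigma,
                                  seed=_dataset_seed(dataset.id))
    comp = CompartmentSet.from_parameters(params.TOP, params.S, params.P_ext,
                                          R_vasc=rvasc)
    vent = baseline_settings(dataset, peep=peep, ibw=ibw)
    vo2, vco2 = derive_metabolic_rates(dataset, v_t=vent.V_T, vd_anat=vd_anat)
    circ = CirculationConfig(CO=dataset.CO, Hb=dataset.Hb, PVR=dataset.PVR,
                             VO2=vo2, VCO2=vco2)
    patient = VirtualPatient(compartments=comp, circulation=circ,
                             FiO2=dataset.FiO2, vent_baseline=vent,
                             vd_anat=vd_anat, ibw=ibw, id=dataset.id)
    patient.reset_state()
    return patient


def ga_minimize(cost, lo: np.ndarray, hi: np.ndarray, config: GAConfig,
                init_population: np.ndarray | None = None):
    """Seeded generational GA over a bounded real box.

    Tournament selection, per-gene blend crossover, per-gene Gaussian
    mutation with annealed sigma, elitism, clipping at the bounds.
    Returns (best_x, best_cost, history, converged) where history is a list
    of (generation, best_cost, mean_cost).
    """
    rng = np.random.default_rng(config.seed)
    d = lo.size
    span = hi - lo
    npop = config.population
    if init_population is not None:
        pop = np.clip(np.asarray(init_population, dtype=float), lo, hi)
        if pop.shape != (npop, d):
            raise ValueError("init population has wrong shape")
    else:
        pop = lo + rng.random((npop, d)) * span
    costs = np.array([cost(x) for x in pop])
    order = np.argsort(costs)
    best_x = pop[order[0]].copy()
    best_cost = float(costs[order[0]])
    history = [(0, best_cost, float(costs.mean()))]
    converged = best_cost < config.threshold
    sigma = config.mutation_scale
    gen = 0
    while gen < config.generations and not converged:
        gen += 1
        new = np.empty_like(pop)
        # elitism: carry the current best individuals unchanged
        elite = np.argsort(costs)[:config.elitism]
        new[:config.elitism] = pop[elite]
        for k in range(config.elitism, npop):
            i1 = _tournament(rng, costs, config.tournament)
            child = pop[i1].copy()
            if rng.random() < config.crossover_rate:
                i2 = _tournament(rng, costs, config.tournament)
                a = config.crossover_alpha
                u = rng.uniform(-a, 1.0 + a, size=d)
                child = pop[i1] + u * (pop[i2] - pop[i1])
            mask = rng.random(d) < config.mutation_indpb
            child[mask] += rng.normal(0.0, sigma, size=int(mask.sum())) * span[mask]
            new[k] = np.clip(child, lo, hi)
        pop = new
        costs = np.array([cost(x) for x in pop])
        gi = int(np.argmin(costs))
        if costs[gi] < best_cost:
            best_cost = float(costs[gi])
            best_x = pop[gi].copy()
        history.append((gen, best_cost, float(costs.mean())))
        sigma *= config.mutation_decay
        converged = best_cost < config.threshold
    return best_x, best_cost, history, converged


def _tournament(rng, costs, k):
    idx = rng.integers(0, costs.size, size=k)
    return idx[np.argmin(costs[idx])]


def structured_population(rng: np.random.Generator, npop: int, n: int) -> np.ndarray:
    """Informed initial population spanning collapse fractions 0..0.6.

    Individual k assigns a fraction of units "injured" (high TOP, high
    extrinsic pressure) and the rest "aerated" (low TOP, mild extrinsic
    pressure, log-spread stiffness), which seeds the GA with the clinically
    relevant region of the 3n-dimensional box.
    """
    pop = np.empty((npop, 3 * n))
    for k in range(npop):
        fc = 0.6 * k / max(npop - 1, 1)
        n_inj = int(round(fc * n))
        injured = rng.permutation(n)[:n_inj]
        top = rng.uniform(8.0, 25.0, size=n)
        pext = rng.uniform(-10.0, 10.0, size=n)
        s = np.exp(rng.uniform(np.log(0.01), np.log(0.2), size=n))
        top[injured] = rng.uniform(25.0, 60.0, size=n_inj)
        pext[injured] = rng.uniform(12.0, PEXT_BOUNDS[1], size=n_inj)
        pop[k] = np.concatenate([top, s, pext])
    return pop


@dataclass
class MatchResult:
    """Outcome of one matching run."""

    dataset: PatientDataset
    params: ParameterVector
    cost: float
    history: list
    converged: bool
    patient: VirtualPatient
    outputs: dict
    warnings: list = field(default_factory=list)


def run_ga(dataset: PatientDataset, config: GAConfig,
           n_compartments: int = 100, simulator=None,
           dt: float = 0.005) -> MatchResult:
    """Match one patient dataset with the genetic algorithm.

    ``simulator(patient) -> outputs dict`` may be injected for testing; by
    default each candidate is evaluated by simulating to steady state at
    the dataset's RR/DC with V_T = 8 ml/kg IBW.  Fully reproducible from
    ``config.seed``; best-so-far cost is non-increasing by elitism.
    """
    n = n_compartments
    template = configure_patient(dataset, ParameterVector.nominal(n))
    data = {k: dataset.targets[k] for k in MATCHED_OUTPUTS if k in dataset.targets}

    def default_sim(patient: VirtualPatient) -> dict:
        s = simulate_to_steady_state(patient, patient.vent_baseline, dt=dt)
        return model_outputs(s)

    sim = simulator or default_sim

    rvasc = template.compartments.R_vasc

    def cost(x: np.ndarray) -> float:
        p = template.copy()
        p.compartments = CompartmentSet.from_parameters(
            x[:n], x[n:2 * n], x[2 * n:], R_vasc=rvasc, validate=False)
        p.reset_state()
        try:
            return cost_ET(sim(p), data)
        except (InfeasibleCirculationError, RuntimeError):
            return BAD_COST

    lo, hi = ParameterVector.bounds(n)
    rng = np.random.default_rng(config.seed)
    init = structured_population(rng, config.population, n)
    best_x, best_cost, history, converged = ga_minimize(
        cost, lo, hi, config, init_population=init)
    params = ParameterVector(best_x)
    patient = configure_patient(dataset, params)
    outputs = sim(patient)
    patient_final = configure_patient(dataset, params)
    warnings_ = soft_configuration_checks(dataset, patient_final, dt=dt)
    return MatchResult(dataset=dataset, params=params, cost=best_cost,
                       history=history, converged=converged,
                       patient=patient_final, outputs=outputs,
                       warnings=warnings_)


def soft_configuration_checks(dataset: PatientDataset,
                              patient: VirtualPatient, dt: float = 0.005,
                              rel_tol: float = 0.15) -> list:
    """Warn (never fail) when the matched patient's dynamic compliance
    deviates more than ``rel_tol`` from the dataset's configured value.
    PVR is configured exactly by construction of the vascular resistances."""
    out = []
    p = patient.copy()
    p.reset_state()
    s = simulate_to_steady_state(p, p.vent_baseline, dt=dt)
    if np.isfinite(s.c_dyn) and dataset.C_dyn > 0:
        rel = abs(s.c_dyn - dataset.C_dyn) / dataset.C_dyn
        if rel > rel_tol:
            out.append(f"C_dyn {s.c_dyn:.1f} ml/cmH2O deviates "
                       f"{100 * rel:.0f}% from configured {dataset.C_dyn}")
    return out
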