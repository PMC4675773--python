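"""Synthetic patients and packaged table fixtures.

Ships the in-print configuration tables (parameter bounds, the three ARDS
patient datasets, the formula-based strategy settings) and a seeded
generator of ground-truth virtual patients spanning the Berlin severity
spectrum.  Generated patients have known compartment parameters; their
simulated blood gases serve as matching targets with known ground truth, so
the whole matching pipeline is testable without any external data.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .gas_exchange import CirculationConfig, InfeasibleCirculationError
from .matching import PatientDataset, perfusion_resistances
from .mechanics import CompartmentSet, VentilatorSettings, PEXT_BOUNDS
from .patient import (IBW_DEFAULT, SimulationSummary, VirtualPatient,
                      model_outputs, simulate_to_steady_state)

_TABLES_SHA256 = "a1a3105e81d35dfd23ae3e0011d78cecc6b9a12eb3e51eea3e64e4f85da2590c"


@dataclass(frozen=True)
class SeverityClass:
    """Berlin severity class: a label and its P/F ratio interval (mmHg),
    half-open with inclusive upper bound."""

    label: str
    pf_range: tuple


MILD = SeverityClass("mild", (200.0, 300.0))
MODERATE = SeverityClass("moderate", (100.0, 200.0))
SEVERE = SeverityClass("severe", (0.0, 100.0))
NOT_ARDS = SeverityClass("not_ards", (300.0, float("inf")))

_SEVERITIES = {s.label: s for s in (MILD, MODERATE, SEVERE)}


def classify_severity(pf_ratio: float) -> SeverityClass:
    """Berlin classification of a P/F ratio; > 300 mmHg is not ARDS."""
    if pf_ratio <= 0:
        raise ValueError("P/F ratio must be positive")
    if pf_ratio <= 100:
        return SEVERE
    if pf_ratio <= 200:
        return MODERATE
    if pf_ratio <= 300:
        return MILD
    return NOT_ARDS


def table_fixtures() -> dict:
    """The printed configuration tables, verbatim.

    Returns {"datasets": {id: PatientDataset}, "model_fits": {...},
    "table1": bounds, "table3": strategy settings}.  The shipped file's
    integrity is enforced by checksum.
    """
    ref = resources.files("ardsim").joinpath("data/tables.yaml")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLES_SHA256:
        raise RuntimeError("packaged table fixtures are corrupted "
                           f"(sha256 {digest[:12]}... != expected)")
    doc = yaml.safe_load(raw)
    datasets = {}
    model_fits = {}
    for pid, row in doc["table2"].items():
        datasets[pid] = PatientDataset(
            id=pid, CO=row["CO"], FiO2=row["FiO2"], Hb=row["Hb"],
            PVR=row["PVR"], C_dyn=row["C_dyn"], DC=row["DC"], RR=row["RR"],
            targets=dict(row["data"]))
        model_fits[pid] = dict(row["model"])
    return {"datasets": datasets, "model_fits": model_fits,
            "table1": doc["table1"], "table3": doc["table3"]}


#: per-severity generator recipes, calibrated once against the simulator
#: and frozen: fraction of injured (high-TOP, compressed) compartments and
#: the inspired O2 fraction at which the severity band is realised.
SEVERITY_RECIPES = {
    "mild": {"collapsed_fraction": 0.18, "FiO2": 0.30},
    "moderate": {"collapsed_fraction": 0.25, "FiO2": 0.60},
    "severe": {"collapsed_fraction": 0.42, "FiO2": 0.90},
}


@dataclass
class SyntheticPatientSpec:
    """Recipe for one ground-truth virtual patient.

    ``collapsed_fraction`` is the fraction of compartments drawn from the
    injured sub-range (high threshold opening pressure, high extrinsic
    pressure) so that they stay collapsed under baseline ventilation; the
    remaining units are aerated with log-spread stiffness.  All draws stay
    inside the physiological parameter box and are reproducible from
    ``seed``.
    """

    seed: int
    severity: str = "moderate"
    collapsed_fraction: float | None = None
    FiO2: float | None = None
    n: int = 100
    CO: float = 6.0
    Hb: float = 120.0
    PVR: float = 152.0
    VO2: float = 250.0
    VCO2: float = 200.0
    ibw: float = IBW_DEFAULT

    def __post_init__(self) -> None:
        if self.severity not in _SEVERITIES:
            raise ValueError(f"unknown severity '{self.severity}'")
        recipe = SEVERITY_RECIPES[self.severity]
        if self.collapsed_fraction is None:
            self.collapsed_fraction = recipe["collapsed_fraction"]
        if self.FiO2 is None:
            self.FiO2 = recipe["FiO2"]
        if not 0 <= self.collapsed_fraction <= 0.9:
            raise ValueError("collapsed_fraction must lie in [0, 0.9]")


def generate_patient(spec: SyntheticPatientSpec, dt: float = 0.005,
                     verify: bool = True):
    """Draw a ground-truth patient and observe its baseline blood gases.

    Returns (VirtualPatient, SimulationSummary); the summary holds the
    "observed" outputs used as matching targets.  With ``verify`` the
    simulated P/F ratio is checked against the requested severity band
    (a mismatch raises, since the recipes are calibrated).  A spec whose
    metabolic demand exhausts the venous O2 content is reported as
    infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    n_inj = int(round(spec.collapsed_fraction * n))
    injured = np.zeros(n, dtype=bool)
    injured[rng.permutation(n)[:n_inj]] = True
    top = rng.uniform(6.0, 18.0, size=n)
    pext = rng.uniform(-8.0, 4.0, size=n)
    s = np.exp(rng.uniform(np.log(0.02), np.log(0.15), size=n))
    top[injured] = rng.uniform(30.0, 55.0, size=n_inj)
    pext[injured] = rng.uniform(18.0, PEXT_BOUNDS[1], size=n_inj)
    s[injured] = rng.uniform(0.05, 0.3, size=n_inj)
    rvasc = perfusion_resistances(n, spec.PVR, sigma=0.3,
                                  seed=int(rng.integers(2 ** 31)))
    comp = CompartmentSet.from_parameters(top, s, pext, R_vasc=rvasc)
    circ = CirculationConfig(CO=spec.CO, Hb=spec.Hb, PVR=spec.PVR,
                             VO2=spec.VO2, VCO2=spec.VCO2)
    vent = VentilatorSettings(V_T=8.0 * spec.ibw, RR=12.5, DC=0.33,
                              PEEP=5.0, FiO2=spec.FiO2)
    patient = VirtualPatient(compartments=comp, circulation=circ,
                             FiO2=spec.FiO2, vent_baseline=vent,
                             ibw=spec.ibw,
                             id=f"synthetic-{spec.severity}-{spec.seed}")
    patient.reset_state()
    try:
        summary = simulate_to_steady_state(patient, vent, dt=dt)
    except InfeasibleCirculationError as err:
        raise InfeasibleCirculationError(
            f"spec {patient.id} is non-viable: {err}") from err
    if verify:
        got = classify_severity(summary.pf_ratio).label
        if got != spec.severity:
            raise ValueError(
                f"generated patient {patient.id} classifies as {got} "
                f"(P/F {summary.pf_ratio:.1f}) instead of {spec.severity}")
    return patient, summary


def observed_dataset(patient: VirtualPatient, summary: SimulationSummary,
                     c_dyn: float | None = None) -> PatientDataset:
    """Package a generated patient's observed gases as a matching dataset
    (the full-pipeline recovery target with known ground truth)."""
    vent = patient.vent_baseline
    return PatientDataset(
        id=patient.id, CO=patient.circulation.CO, FiO2=patient.FiO2,
        Hb=patient.circulation.Hb, PVR=patient.circulation.PVR,
        C_dyn=c_dyn if c_dyn is not None else summary.c_dyn,
        DC=vent.DC, RR=vent.RR, targets=model_outputs(summary))
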