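"""End-to-end orchestration: match -> plan -> run -> report.

Every artifact is a CSV whose first line is a comment embedding the seed,
the configuration hash and the patient id, so any output can be traced to
the exact run that produced it and deterministic runs reproduce artifacts
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .gas_exchange import VD_ANAT_DEFAULT
from .matching import (GAConfig, MatchResult, MATCHED_OUTPUTS, ParameterVector,
                       PatientDataset, configure_patient, run_ga)
from .patient import VirtualPatient
from .strategies import (StrategyOutcome, StrategyPlan, build_plan_strategy1,
                         build_plan_strategy1_adaptive, build_plan_strategy2,
                         inspiratory_flow, optimize_strategy3, run_strategy)
from .virtual_patients import (SyntheticPatientSpec, generate_patient,
                               observed_dataset, table_fixtures)

log = logging.getLogger("ardsim")

EXIT_OK = 0
EXIT_UNCONVERGED = 2
EXIT_INFEASIBLE = 3


@dataclass
class RunConfig:
    """One run: patient source, strategy kind, GA settings, tolerances."""

    patient: str = "A"            # fixture id, "synthetic:<severity>", or path
    strategy: str = "strategy3"
    seed: int = 0
    n_compartments: int = 100
    dt: float = 0.005
    outdir: str = "ardsim-out"
    params_csv: str | None = None  # matched parameters for fixture patients
    ga: GAConfig = field(default_factory=GAConfig)
    rr_sequence: tuple = (16.0, 24.0, 32.0, 40.0, 48.0)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        ga = GAConfig(**doc.pop("ga", {}))
        cfg = cls(ga=ga, **doc)
        if seed is not None:
            cfg.seed = seed
        cfg.ga.seed = cfg.seed
        return cfg

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded,
        so re-running a config elsewhere reproduces identical artifacts)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _write_frame(df: pd.DataFrame, path: Path, config: RunConfig,
                 patient_id: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (f"# ardsim seed={config.seed} config={config.hash()} "
              f"patient={patient_id}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_meta(path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    return meta


def resolve_dataset(config: RunConfig) -> PatientDataset:
    if config.patient in table_fixtures()["datasets"]:
        return table_fixtures()["datasets"][config.patient]
    p = Path(config.patient)
    if p.exists():
        doc = yaml.safe_load(p.read_text())
        return PatientDataset(**doc)
    raise FileNotFoundError(f"unknown patient source '{config.patient}'")


def resolve_patient(config: RunConfig) -> VirtualPatient:
    """Patient for a strategy run: synthetic recipe, or a fixture dataset
    combined with a matched-parameter CSV."""
    if config.patient.startswith("synthetic:"):
        severity = config.patient.split(":", 1)[1]
        spec = SyntheticPatientSpec(seed=config.seed, severity=severity,
                                    n=config.n_compartments)
        patient, _ = generate_patient(spec, dt=config.dt)
        return patient
    dataset = resolve_dataset(config)
    if not config.params_csv:
        raise ValueError("strategy runs on a fixture patient need params_csv "
                         "(run `ardsim match` first)")
    params = read_params_csv(config.params_csv)
    return configure_patient(dataset, params)


def write_params_csv(result_params: ParameterVector, path, config: RunConfig,
                     patient_id: str) -> None:
    df = pd.DataFrame({"compartment": np.arange(1, result_params.n + 1),
                       "TOP": result_params.TOP, "S": result_params.S,
                       "P_ext": result_params.P_ext})
    _write_frame(df, Path(path), config, patient_id)


def read_params_csv(path) -> ParameterVector:
    df = pd.read_csv(path, comment="#")
    return ParameterVector(np.concatenate([df["TOP"].to_numpy(),
                                           df["S"].to_numpy(),
                                           df["P_ext"].to_numpy()]))


def cmd_match(config: RunConfig) -> int:
    """Match a fixture/file dataset; writes parameter, convergence and
    model-vs-data report CSVs.  Returns the process exit code (2 when the
    GA budget ran out before the termination threshold; best-found
    artifacts are still written)."""
    dataset = resolve_dataset(config)
    log.info("matching patient %s with %d compartments, seed %d",
             dataset.id, config.n_compartments, config.seed)
    result = run_ga(dataset, config.ga, n_compartments=config.n_compartments,
                    dt=config.dt)
    for gen, best, mean in result.history:
        log.info("gen=%d best=%.5f mean=%.3g seed=%d", gen, best, mean,
                 config.ga.seed)
    out = Path(config.outdir)
    write_params_csv(result.params, out / f"match_{dataset.id}_params.csv",
                     config, dataset.id)
    hist = pd.DataFrame(result.history, columns=["generation", "best", "mean"])
    _write_frame(hist, out / f"match_{dataset.id}_history.csv", config,
                 dataset.id)
    report = pd.DataFrame({
        "output": list(MATCHED_OUTPUTS),
        "data": [dataset.targets[k] for k in MATCHED_OUTPUTS],
        "model": [result.outputs[k] for k in MATCHED_OUTPUTS]})
    report["rel_error"] = (report["model"] - report["data"]) / report["data"]
    _write_frame(report, out / f"match_{dataset.id}_report.csv", config,
                 dataset.id)
    for w in result.warnings:
        log.warning("%s", w)
    if not result.converged:
        log.warning("matching unconverged: E_T=%.4f above threshold %.4f",
                    result.cost, config.ga.threshold)
        return EXIT_UNCONVERGED
    return EXIT_OK


def plan_frame(plan: StrategyPlan, vd_anat: float = VD_ANAT_DEFAULT) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(plan.steps, 1):
        rows.append({"step": i, "RR": s.RR, "V_T": s.V_T, "V_D_anat": vd_anat,
                     "M_Valv": s.RR * (s.V_T - vd_anat), "DC": s.DC,
                     "F_insp": inspiratory_flow(s.V_T, s.RR, s.DC),
                     "flag": s.flag})
    cols = ["step", "RR", "V_T", "V_D_anat", "M_Valv", "DC", "F_insp", "flag"]
    return pd.DataFrame(rows, columns=cols)


PANEL_COLUMNS = ["step", "RR", "V_T", "PF", "PaCO2", "Palv", "Cdyn",
                 "Vlung_insp", "Vlung_exp", "strain", "VDphys", "flag"]


def outcome_frame(outcome: StrategyOutcome) -> pd.DataFrame:
    """Figure-panel layout; step 0 is the pre-strategy baseline."""
    rows = []
    records = [(0, None, outcome.baseline)] + [
        (i, st, su) for i, (st, su) in
        enumerate(zip(outcome.steps, outcome.summaries), 1)]
    for i, st, s in records:
        rows.append({"step": i, "RR": s.vent.RR, "V_T": s.vent.V_T,
                     "PF": s.pf_ratio, "PaCO2": s.PaCO2, "Palv": s.palv_peak,
                     "Cdyn": s.c_dyn, "Vlung_insp": s.v_lung_end_insp,
                     "Vlung_exp": s.v_lung_end_exp, "strain": s.strain,
                     "VDphys": s.vd_phys,
                     "flag": (st.flag if st else "") or
                             ("cap-exceeded" if s.cap_exceeded else "")})
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def build_plan(config: RunConfig, patient: VirtualPatient):
    """Build (and for the simulation-guided kinds, execute) the plan.
    Returns (plan, outcome-or-None)."""
    kind = config.strategy
    rr = config.rr_sequence
    if kind == "strategy1":
        return build_plan_strategy1(rr_sequence=rr), None
    if kind == "strategy2":
        return build_plan_strategy2(rr_sequence=rr), None
    if kind == "strategy3":
        plan, outcome = optimize_strategy3(patient, rr_sequence=rr,
                                           dt=config.dt)
        return plan, outcome
    if kind == "strategy1_adaptive":
        return build_plan_strategy1_adaptive(patient, rr_sequence=rr,
                                             dt=config.dt), None
    raise ValueError(f"unknown strategy kind '{kind}'")


def cmd_strategy(config: RunConfig) -> int:
    """Run one strategy on a patient; writes the plan CSV (settings-table
    layout) and the outcome panel CSV (figure-panel layout)."""
    patient = resolve_patient(config)
    out = Path(config.outdir)
    if len(config.rr_sequence) == 0:
        empty = pd.DataFrame(columns=PANEL_COLUMNS)
        _write_frame(pd.DataFrame(columns=plan_frame(
            StrategyPlan(config.strategy, [])).columns),
            out / f"{config.strategy}_{patient.id}_plan.csv", config, patient.id)
        _write_frame(empty, out / f"{config.strategy}_{patient.id}_panel.csv",
                     config, patient.id)
        return EXIT_OK
    plan, outcome = build_plan(config, patient)
    if outcome is None:
        runner = patient.copy()
        runner.reset_state()
        outcome = run_strategy(runner, plan, dt=config.dt, warn=log.warning)
    _write_frame(plan_frame(plan, vd_anat=patient.vd_anat),
                 out / f"{config.strategy}_{patient.id}_plan.csv", config,
                 patient.id)
    _write_frame(outcome_frame(outcome),
                 out / f"{config.strategy}_{patient.id}_panel.csv", config,
                 patient.id)
    infeasible = any("clipped" in (s.flag or "") for s in plan.steps)
    if infeasible:
        log.warning("plan contains clipped/infeasible steps (flagged in CSV)")
        return EXIT_INFEASIBLE
    return EXIT_OK


def cmd_report(panel_paths, out_path=None, config: RunConfig | None = None) -> pd.DataFrame:
    """Cross-strategy comparison summary.

    One row per outcome panel: maximum |PaCO2 - baseline|, the change of
    peak alveolar pressure and of dynamic strain between the last and first
    rate steps, and the V_Dphys-on-V_T regression slope and R^2.  All
    panels must belong to the same patient.
    """
    if not panel_paths:
        raise ValueError("at least one outcome panel is required")
    patients = {_read_meta(p).get("patient", "?") for p in panel_paths}
    if len(patients) > 1:
        raise ValueError(f"mixed-patient inputs rejected: {sorted(patients)}")
    rows = []
    for p in panel_paths:
        df = pd.read_csv(p, comment="#")
        meta = _read_meta(p)
        base = df[df["step"] == 0].iloc[0]
        steps = df[df["step"] > 0]
        name = Path(p).name.split("_")[0]
        row = {"patient": meta.get("patient", "?"), "strategy": name,
               "max_abs_dPaCO2": float((steps["PaCO2"] - base["PaCO2"]).abs().max()),
               "dPalv_last_vs_first": float(steps["Palv"].iloc[-1] - steps["Palv"].iloc[0]),
               "dstrain_last_vs_first": float(steps["strain"].iloc[-1] - steps["strain"].iloc[0])}
        if len(steps) >= 3 and steps["V_T"].nunique() > 1:
            reg = stats.linregress(steps["V_T"], steps["VDphys"])
            row["vdphys_vt_slope"] = float(reg.slope)
            row["vdphys_vt_r2"] = float(reg.rvalue ** 2)
        else:
            row["vdphys_vt_slope"] = float("nan")
            row["vdphys_vt_r2"] = float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)
    if out_path is not None and config is not None:
        _write_frame(out, Path(out_path), config, sorted(patients)[0])
    return out


def cmd_generate(config: RunConfig) -> int:
    """Generate a synthetic ground-truth patient; writes its parameter CSV
    and observed blood gases."""
    severity = (config.patient.split(":", 1)[1]
                if config.patient.startswith("synthetic:") else config.patient)
    spec = SyntheticPatientSpec(seed=config.seed, severity=severity,
                                n=config.n_compartments)
    patient, summary = generate_patient(spec, dt=config.dt)
    out = Path(config.outdir)
    params = ParameterVector(patient.compartments.table_parameters())
    write_params_csv(params, out / f"generate_{patient.id}_params.csv",
                     config, patient.id)
    ds = observed_dataset(patient, summary)
    doc = {"id": ds.id, "CO": ds.CO, "FiO2": ds.FiO2, "Hb": ds.Hb,
           "PVR": ds.PVR, "C_dyn": float(ds.C_dyn), "DC": ds.DC, "RR": ds.RR,
           "targets": {k: float(v) for k, v in ds.targets.items()}}
    out.mkdir(parents=True, exist_ok=True)
    (out / f"generate_{patient.id}_dataset.yaml").write_text(
        f"# ardsim seed={config.seed} config={config.hash()} patient={patient.id}\n"
        + yaml.safe_dump(doc, sort_keys=True))
    return EXIT_OK
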