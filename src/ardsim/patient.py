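"""Virtual patient: a configured lung plus circulation and baseline
ventilation, and the accelerated steady-state evaluation that couples the
mechanics and gas-exchange solvers.

A "20-minute" ventilation step is evaluated by running breaths until the
mechanical pattern settles (a handful of breaths) and then solving the
algebraic gas steady state on the settled breath — orders of magnitude
cheaper than integrating gas transport through the full period, and
equivalent at steady state (the dynamic route is kept as a cross-check in
:mod:`ardsim.gas_exchange`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .gas_exchange import (CirculationConfig, GasSteadyState, VD_ANAT_DEFAULT,
                           steady_state_gas)
from .mechanics import (CompartmentSet, BreathSummary, VentilatorSettings,
                        DT_DEFAULT, PRESSURE_CAP_DEFAULT, dynamic_compliance,
                        dynamic_strain, peak_alveolar_pressure, run_breaths)

IBW_DEFAULT = 70.0


@dataclass
class VirtualPatient:
    """A virtual ARDS patient: compartmental lung, circulation, inspired O2
    and baseline ventilator settings."""

    compartments: CompartmentSet
    circulation: CirculationConfig
    FiO2: float
    vent_baseline: VentilatorSettings
    vd_anat: float = VD_ANAT_DEFAULT
    ibw: float = IBW_DEFAULT
    id: str = ""

    @property
    def n(self) -> int:
        return self.compartments.n

    def copy(self) -> "VirtualPatient":
        return replace(self, compartments=self.compartments.copy())

    def reset_state(self) -> None:
        """Return the lung to a canonical pre-ventilation state: every unit
        open at its static volume for airway pressure = PEEP."""
        self.compartments.equilibrate(self.vent_baseline.PEEP)
        self.compartments.is_open[:] = True


@dataclass
class SimulationSummary:
    """Steady-state outputs of one ventilation step."""

    PaO2: float
    PaCO2: float
    PvO2: float
    PvCO2: float
    shunt_frac: float
    pf_ratio: float
    palv_peak: float
    c_dyn: float
    frc: float
    v_lung_end_insp: float
    v_lung_end_exp: float
    strain: float
    vd_phys: float
    pe_co2: float
    paw_peak: float
    n_breaths: int
    mech_converged: bool
    gas_converged: bool
    cap_exceeded: bool
    vent: VentilatorSettings = None
    gas: GasSteadyState = field(default=None, repr=False)
    breath: BreathSummary = field(default=None, repr=False)


def simulate_to_steady_state(patient: VirtualPatient,
                             vent: VentilatorSettings | None = None,
                             dt: float = DT_DEFAULT,
                             max_time: float = 600.0,
                             settle_tol: float = 0.5,
                             pressure_cap: float = PRESSURE_CAP_DEFAULT,
                             warn=None) -> SimulationSummary:
    """Ventilate the patient at ``vent`` until mechanics settle, then solve
    the gas-exchange steady state.  Advances the patient's lung state in
    place and returns the step summary."""
    vent = vent or patient.vent_baseline
    summary = run_breaths(patient.compartments, vent, duration=max_time,
                          dt=dt, settle_tol=settle_tol,
                          pressure_cap=pressure_cap, min_breaths=3, warn=warn)
    gss = steady_state_gas(summary.dV, patient.compartments.q_frac,
                           patient.circulation, patient.FiO2,
                           v_t=vent.V_T, rr=vent.RR, vd_anat=patient.vd_anat)
    bg = gss.blood
    try:
        c_dyn = dynamic_compliance(summary, vent)
    except ValueError:
        c_dyn = float("nan")
    frc = summary.v_lung_end_exp
    return SimulationSummary(
        PaO2=bg.PaO2, PaCO2=bg.PaCO2, PvO2=bg.PvO2, PvCO2=bg.PvCO2,
        shunt_frac=bg.shunt_frac, pf_ratio=bg.PaO2 / patient.FiO2,
        palv_peak=peak_alveolar_pressure(summary.P_end_insp),
        c_dyn=c_dyn, frc=frc,
        v_lung_end_insp=summary.v_lung_end_insp,
        v_lung_end_exp=summary.v_lung_end_exp,
        strain=dynamic_strain(vent.V_T, frc),
        vd_phys=gss.dead_space.V_D_phys, pe_co2=gss.dead_space.PE_CO2_mixed,
        paw_peak=summary.paw_max, n_breaths=summary.n_breaths,
        mech_converged=summary.converged, gas_converged=gss.converged,
        cap_exceeded=summary.cap_exceeded, vent=vent, gas=gss, breath=summary)


def model_outputs(summary: SimulationSummary) -> dict:
    """The four matched outputs in the units of the patient datasets."""
    return {"PaO2": summary.PaO2, "PvO2": summary.PvO2,
            "PvCO2": summary.PvCO2, "shunt": 100.0 * summary.shunt_frac}
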