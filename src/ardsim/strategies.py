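"""Moderately high-frequency ventilation strategies.

All strategies step the respiratory rate through 16, 24, 32, 40, 48 b/min
(20 simulated minutes per step) while reducing tidal volume, aiming to hold
PaCO2 at its baseline value:

* strategy 1 — formula-based: V_T = M_Valv/RR + V_Danat keeps the nominal
  alveolar minute ventilation M_Valv = RR*(V_T - V_Danat) constant at fixed
  duty cycle;
* strategy 2 — same V_T sequence, but the duty cycle is varied so the
  constant inspiratory flow F_insp = V_T*RR/(60*DC) is held fixed;
* strategy 3 — simulation-in-the-loop: per step, the V_T in [2.5, 8] ml/kg
  that returns the steady-state PaCO2 to target, found by bisection on the
  monotone PaCO2(V_T) response (a 1 ml grid search is kept as an oracle);
* adaptive strategy 1 — as strategy 1 but substituting the measured
  physiological dead space for V_Danat before each rate increment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gas_exchange import InfeasibleCirculationError, VD_ANAT_DEFAULT
from .mechanics import VentilatorSettings
from .patient import SimulationSummary, VirtualPatient, simulate_to_steady_state

RR_SEQUENCE = (16.0, 24.0, 32.0, 40.0, 48.0)
M_VALV_DEFAULT = 5400.0
DC_DEFAULT = 0.33
F_INSP_STRATEGY2 = 337.0
STEP_MINUTES = 20.0

#: strategy-3 tidal volume bounds, ml/kg of ideal body weight
VT_PER_KG_BOUNDS = (2.5, 8.0)
PACO2_TOL = 0.5   # mmHg, acceptable residual at a clipped bound
VT_TOL = 0.5      # ml, bisection bracket tolerance


@dataclass
class PlanStep:
    RR: float
    V_T: float
    DC: float
    duration: float = STEP_MINUTES  # minutes
    flag: str = ""                  # e.g. clipped-at-bound note


@dataclass
class StrategyPlan:
    kind: str
    steps: list

    def __iter__(self):
        return iter(self.steps)

    def __len__(self):
        return len(self.steps)


@dataclass
class StrategyOutcome:
    kind: str
    baseline: SimulationSummary
    steps: list                      # PlanStep per record
    summaries: list                  # SimulationSummary per record

    def paco2_deviations(self) -> np.ndarray:
        """Per-step |PaCO2 - baseline PaCO2|, mmHg."""
        base = self.baseline.PaCO2
        return np.array([abs(s.PaCO2 - base) for s in self.summaries])


def vt_for_constant_mvalv(m_valv: float, rr: float, v_d: float) -> float:
    """Tidal volume keeping alveolar minute ventilation constant:
    V_T = M_Valv/RR + V_D."""
    if rr <= 0:
        raise ValueError("RR must be positive")
    if m_valv < 0:
        raise ValueError("alveolar minute ventilation must be non-negative")
    return m_valv / rr + v_d


def inspiratory_flow(v_t: float, rr: float, dc: float) -> float:
    """Constant inspiratory flow F_insp = V_T*RR/(60*DC), ml/s."""
    if not 0 < dc <= 1:
        raise ValueError("duty cycle must lie in (0, 1]")
    return v_t * rr / (60.0 * dc)


def dc_for_constant_flow(v_t: float, rr: float, f_insp: float) -> float:
    """Duty cycle achieving a given constant inspiratory flow:
    DC = V_T*RR/(60*F_insp).  A result >= 1 means the inspiration would
    outlast the breath cycle and is reported as infeasible."""
    if f_insp <= 0:
        raise ValueError("inspiratory flow must be positive")
    dc = v_t * rr / (60.0 * f_insp)
    if dc >= 1.0:
        raise ValueError(f"infeasible duty cycle {dc:.3f} >= 1 at RR={rr}")
    return dc


def build_plan_strategy1(m_valv: float = M_VALV_DEFAULT,
                         vd_anat: float = VD_ANAT_DEFAULT,
                         dc: float = DC_DEFAULT,
                         rr_sequence=RR_SEQUENCE) -> StrategyPlan:
    """Constant alveolar minute ventilation at fixed duty cycle."""
    steps = [PlanStep(RR=rr, V_T=vt_for_constant_mvalv(m_valv, rr, vd_anat),
                      DC=dc) for rr in rr_sequence]
    return StrategyPlan(kind="strategy1", steps=steps)


def build_plan_strategy2(m_valv: float = M_VALV_DEFAULT,
                         vd_anat: float = VD_ANAT_DEFAULT,
                         f_insp: float = F_INSP_STRATEGY2,
                         rr_sequence=RR_SEQUENCE) -> StrategyPlan:
    """Same tidal volumes as strategy 1, duty cycle varied for constant
    inspiratory flow."""
    steps = []
    for rr in rr_sequence:
        vt = vt_for_constant_mvalv(m_valv, rr, vd_anat)
        steps.append(PlanStep(RR=rr, V_T=vt,
                              DC=dc_for_constant_flow(vt, rr, f_insp)))
    return StrategyPlan(kind="strategy2", steps=steps)


def _step_vent(patient: VirtualPatient, step: PlanStep) -> VentilatorSettings:
    base = patient.vent_baseline
    return VentilatorSettings(V_T=step.V_T, RR=step.RR, DC=step.DC,
                              PEEP=base.PEEP, FiO2=patient.FiO2)


def optimize_strategy3(patient: VirtualPatient, rr_sequence=RR_SEQUENCE,
                       paco2_target: float | None = None,
                       dc: float = DC_DEFAULT, method: str = "bisect",
                       dt: float = 0.005, paco2_tol: float = PACO2_TOL,
                       vt_tol: float = VT_TOL) -> tuple:
    """Per-step tidal volume minimising |PaCO2 - target|.

    The steps are solved sequentially; within a step the lung state is
    frozen at the previous step's end and candidate tidal volumes are
    evaluated from that state (PaCO2 is strictly decreasing in V_T, so the
    1-D problem is solved by bisection; ``method='grid'`` uses an exhaustive
    1 ml grid instead).  Targets unreachable within the 2.5-8 ml/kg bounds
    return the clipped bound, flagged.  The patient state is advanced
    through the committed steps; returns (StrategyPlan, StrategyOutcome).
    """
    if method not in ("bisect", "grid"):
        raise ValueError("method must be 'bisect' or 'grid'")
    lo_vt = VT_PER_KG_BOUNDS[0] * patient.ibw
    hi_vt = VT_PER_KG_BOUNDS[1] * patient.ibw
    baseline = simulate_to_steady_state(patient, patient.vent_baseline, dt=dt)
    target = paco2_target if paco2_target is not None else baseline.PaCO2
    steps, summaries = [], []
    for rr in rr_sequence:
        start = patient.compartments.copy()

        def paco2_at(vt: float) -> float:
            patient.compartments = start.copy()
            vent = _step_vent(patient, PlanStep(RR=rr, V_T=vt, DC=dc))
            try:
                return simulate_to_steady_state(patient, vent, dt=dt).PaCO2
            except InfeasibleCirculationError:
                # hypoventilation so extreme the circulation cannot close:
                # treat as PaCO2 above any reachable target
                return 1.0e3

        flag = ""
        if method == "grid":
            grid = np.arange(lo_vt, hi_vt + 0.5, 1.0)
            dev = np.array([abs(paco2_at(v) - target) for v in grid])
            vt_star = float(grid[int(np.argmin(dev))])
            if vt_star in (grid[0], grid[-1]):
                flag = "at-bound"
        else:
            p_lo = paco2_at(lo_vt)   # highest PaCO2 (smallest V_T)
            p_hi = paco2_at(hi_vt)   # lowest PaCO2
            if p_hi >= target:
                vt_star, flag = hi_vt, (
                    "" if abs(p_hi - target) <= paco2_tol else
                    f"clipped-high:residual={p_hi - target:+.2f}mmHg")
            elif p_lo <= target:
                vt_star, flag = lo_vt, (
                    "" if abs(p_lo - target) <= paco2_tol else
                    f"clipped-low:residual={p_lo - target:+.2f}mmHg")
            else:
                a, b = lo_vt, hi_vt
                while b - a > vt_tol:
                    mid = 0.5 * (a + b)
                    if paco2_at(mid) > target:  # too little ventilation
                        a = mid
                    else:
                        b = mid
                vt_star = 0.5 * (a + b)
        # commit the step from the frozen start state
        patient.compartments = start
        vent = _step_vent(patient, PlanStep(RR=rr, V_T=vt_star, DC=dc))
        s = simulate_to_steady_state(patient, vent, dt=dt)
        step = PlanStep(RR=rr, V_T=vt_star, DC=dc, flag=flag)
        steps.append(step)
        summaries.append(s)
    plan = StrategyPlan(kind="strategy3", steps=steps)
    return plan, StrategyOutcome(kind="strategy3", baseline=baseline,
                                 steps=steps, summaries=summaries)


def build_plan_strategy1_adaptive(patient: VirtualPatient,
                                  m_valv: float | None = None,
                                  dc: float = DC_DEFAULT,
                                  rr_sequence=RR_SEQUENCE,
                                  dt: float = 0.005,
                                  measure=None) -> StrategyPlan:
    """Strategy 1 with the measured physiological dead space.

    Before each rate increment the physiological dead space of the current
    steady state is measured and used in place of V_Danat:
    V_T,next = M_Valv/RR_next + V_Dphys.  By default M_Valv is also
    measured at baseline as RR*(V_T - V_Dphys) — maintaining the nominal
    anatomical-dead-space constant while correcting V_T with the (larger)
    physiological dead space would systematically over-ventilate.  With an
    explicit ``m_valv`` and V_Dphys identically V_Danat this reduces
    exactly to strategy 1.

    ``measure`` may inject an external dead-space measurement (callable
    returning ml); when provided, no simulation is performed during
    planning (``m_valv`` is then required).
    """
    steps = []
    if measure is not None:
        if m_valv is None:
            raise ValueError("m_valv is required with an external measure")
        for rr in rr_sequence:
            vd = float(measure())
            steps.append(PlanStep(RR=rr, V_T=vt_for_constant_mvalv(m_valv, rr, vd),
                                  DC=dc))
        return StrategyPlan(kind="strategy1_adaptive", steps=steps)
    base = patient.vent_baseline
    baseline = simulate_to_steady_state(patient, base, dt=dt)
    vd = baseline.vd_phys
    if m_valv is None:
        m_valv = base.RR * (base.V_T - vd)
    for rr in rr_sequence:
        vt = vt_for_constant_mvalv(m_valv, rr, vd)
        step = PlanStep(RR=rr, V_T=vt, DC=dc)
        s = simulate_to_steady_state(patient, _step_vent(patient, step), dt=dt)
        vd = s.vd_phys
        steps.append(step)
    return StrategyPlan(kind="strategy1_adaptive", steps=steps)


def run_strategy(patient: VirtualPatient, plan: StrategyPlan,
                 dt: float = 0.005, warn=None) -> StrategyOutcome:
    """Execute a plan's steps in order without resetting the patient state.

    Records the full steady-state summary per step; dynamic strain uses the
    end-expiratory volume of that step as FRC.  Safety-cap breaches are
    recorded on the summaries, never silently dropped.
    """
    baseline = simulate_to_steady_state(patient, patient.vent_baseline, dt=dt,
                                        warn=warn)
    summaries = []
    for step in plan.steps:
        vent = _step_vent(patient, step)
        summaries.append(simulate_to_steady_state(patient, vent, dt=dt,
                                                  warn=warn))
    return StrategyOutcome(kind=plan.kind, baseline=baseline,
                           steps=list(plan.steps), summaries=summaries)
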