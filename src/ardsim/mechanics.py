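"""Ventilator-driven mechanics of a parallel multi-compartment lung.

The lung is modelled as ``n`` alveolar compartments behind a shared proximal
airway node.  Each compartment has a quadratic recoil characteristic

    P_i = S_i * V_i**2 + P_ext,i        (cmH2O, V_i in ml above resting)

a bronchiolar resistance R_aw,i, and a threshold opening pressure TOP_i: a
collapsed unit admits no flow until the airway pressure reaches TOP_i, and a
unit whose volume above resting falls to zero collapses.  Breaths are
volume-controlled: constant inspiratory flow for the inspiratory fraction of
the cycle, then passive expiration against PEEP.  Time is advanced with an
explicit, mass-conserving slice update (default 5 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel

# Table-derived physiological bounds for compartment parameters
TOP_BOUNDS = (5.0, 60.0)
S_BOUNDS = (0.005, 0.5)
PEXT_BOUNDS = (-20.0, 28.8)
TOP_NOMINAL = 30.0
S_NOMINAL = 0.05
PEXT_NOMINAL = 28.8

#: total airway resistance of the reference 100-compartment lung,
#: cmH2O.s/ml; per-compartment resistance is this times n (parallel paths).
R_LUNG_TOTAL = 0.015

#: total resting volume of the lung, ml, calibrated so the reference lung
#: holds ~2,000 ml at functional residual capacity with the nominal
#: (fully compressed) parameter set; shared uniformly across compartments.
V_REST_TOTAL = 2000.0

#: number of alveolar units the parameter tables describe
N_REFERENCE = 100

#: default airway pressure safety cap, cmH2O
PRESSURE_CAP_DEFAULT = 120.0

DT_DEFAULT = 0.005
DT_MAX = 0.010


class SimulationError(RuntimeError):
    """Raised when the integrator produces a non-physical state."""


@dataclass
class AlveolarCompartment:
    """Mechanical, vascular and gas state of one alveolar unit."""

    index: int
    TOP: float = TOP_NOMINAL
    S: float = S_NOMINAL
    P_ext: float = PEXT_NOMINAL
    R_aw: float = R_LUNG_TOTAL * 100
    V: float = 0.0
    is_open: bool = True
    q_frac: float = 0.01
    PA_O2: float = 100.0
    PA_CO2: float = 40.0

    def __post_init__(self) -> None:
        if not TOP_BOUNDS[0] <= self.TOP <= TOP_BOUNDS[1]:
            raise ValueError(f"TOP {self.TOP} outside {TOP_BOUNDS}")
        if not S_BOUNDS[0] <= self.S <= S_BOUNDS[1]:
            raise ValueError(f"S {self.S} outside {S_BOUNDS}")
        if not PEXT_BOUNDS[0] <= self.P_ext <= PEXT_BOUNDS[1]:
            raise ValueError(f"P_ext {self.P_ext} outside {PEXT_BOUNDS}")
        if self.R_aw <= 0:
            raise ValueError("R_aw must be positive")
        if self.V < 0:
            raise ValueError("compartment volume must be non-negative")


def compartment_pressure(c) -> float:
    """Recoil pressure S*V**2 + P_ext of a compartment (cmH2O).

    Accepts an :class:`AlveolarCompartment` or any object with S, V and
    P_ext attributes.  A negative volume signals an integrator fault.
    """
    if c.V < 0:
        raise SimulationError(f"negative volume in compartment {getattr(c, 'index', '?')}")
    return c.S * c.V * c.V + c.P_ext


@dataclass
class VentilatorSettings:
    """One ventilator configuration: V_T (ml), RR (b/min), duty cycle,
    PEEP (cmH2O) and inspired O2 fraction."""

    V_T: float
    RR: float
    DC: float = 0.33
    PEEP: float = 5.0
    FiO2: float = 0.21

    def __post_init__(self) -> None:
        if self.V_T <= 0:
            raise ValueError("V_T must be positive")
        if self.RR <= 0:
            raise ValueError("RR must be positive")
        if not 0 < self.DC < 1:
            raise ValueError("duty cycle must lie in (0, 1)")
        if self.PEEP < 0:
            raise ValueError("PEEP must be non-negative")
        if not 0 < self.FiO2 <= 1:
            raise ValueError("FiO2 must lie in (0, 1]")

    @property
    def t_cycle(self) -> float:
        """Breath cycle time, s."""
        return 60.0 / self.RR

    @property
    def t_insp(self) -> float:
        """Inspiratory time DC * 60/RR, s."""
        return self.DC * self.t_cycle

    @property
    def F_insp(self) -> float:
        """Commanded constant inspiratory flow V_T*RR/(60*DC), ml/s."""
        return self.V_T / self.t_insp


@dataclass
class CompartmentSet:
    """Array-of-structs view of all compartments (parameters + state)."""

    TOP: np.ndarray
    S: np.ndarray
    P_ext: np.ndarray
    R_aw: np.ndarray
    V_rest: np.ndarray
    R_vasc: np.ndarray
    V: np.ndarray
    is_open: np.ndarray
    #: stiffness on the per-unit (table) scale, kept for export/round-trips
    S_unit: np.ndarray = None

    @classmethod
    def from_parameters(cls, TOP, S, P_ext, R_aw=None, V_rest=None,
                        R_vasc=None, validate: bool = True,
                        scale_to: int | None = N_REFERENCE) -> "CompartmentSet":
        """Build a lung from per-unit Table-scale parameters.

        With ``scale_to`` (default 100) an ``n``-compartment lung represents
        ``scale_to`` alveolar units lumped into ``n`` parallel groups:
        pressures (TOP, P_ext) are unchanged, the lumped stiffness is
        S*(n/scale_to)**2, resistances scale as n and resting volumes share
        ``V_REST_TOTAL``, so reduced lungs keep the reference lung's
        aggregate mechanics.  ``scale_to=None`` takes the arrays verbatim.
        """
        TOP = np.asarray(TOP, dtype=float).copy()
        S = np.asarray(S, dtype=float).copy()
        P_ext = np.asarray(P_ext, dtype=float).copy()
        n = TOP.size
        if not (S.size == n and P_ext.size == n):
            raise ValueError("parameter arrays must have equal length")
        if validate:
            for name, arr, (lo, hi) in (("TOP", TOP, TOP_BOUNDS),
                                        ("S", S, S_BOUNDS),
                                        ("P_ext", P_ext, PEXT_BOUNDS)):
                if np.any(arr < lo) or np.any(arr > hi):
                    raise ValueError(f"{name} outside allowed range ({lo}, {hi})")
        S_unit = S.copy()
        if scale_to is not None:
            S = S * (n / scale_to) ** 2
        if R_aw is None:
            R_aw = np.full(n, R_LUNG_TOTAL * n)
        else:
            R_aw = np.asarray(R_aw, dtype=float).copy()
        if V_rest is None:
            V_rest = np.full(n, V_REST_TOTAL / n)
        else:
            V_rest = np.asarray(V_rest, dtype=float).copy()
        if R_vasc is None:
            R_vasc = np.ones(n)
        else:
            R_vasc = np.asarray(R_vasc, dtype=float).copy()
        return cls(TOP, S, P_ext, R_aw, V_rest, R_vasc,
                   V=np.zeros(n), is_open=np.ones(n, dtype=bool),
                   S_unit=S_unit)

    @classmethod
    def homogeneous(cls, n: int, TOP=TOP_NOMINAL, S=S_NOMINAL, P_ext=0.0,
                    **kw) -> "CompartmentSet":
        return cls.from_parameters(np.full(n, float(TOP)), np.full(n, float(S)),
                                   np.full(n, float(P_ext)), **kw)

    @property
    def n(self) -> int:
        return self.TOP.size

    @property
    def q_frac(self) -> np.ndarray:
        """Perfusion fractions, proportional to 1/R_vasc, summing to one."""
        w = 1.0 / self.R_vasc
        return w / w.sum()

    def pressures(self) -> np.ndarray:
        return self.S * self.V * self.V + self.P_ext

    @property
    def V_lung(self) -> float:
        """Total lung volume including resting volumes, ml."""
        return float(self.V.sum() + self.V_rest.sum())

    def equilibrate(self, paw: float) -> None:
        """Set every openable compartment to its static volume at ``paw``."""
        with np.errstate(invalid="ignore"):
            v = np.sqrt(np.maximum(paw - self.P_ext, 0.0) / self.S)
        self.V = np.where(v > 0, v, 0.0)
        self.is_open = self.V > 0
        # collapsed units may still be recruitable at paw
        self.is_open |= self.TOP <= paw

    def copy(self) -> "CompartmentSet":
        return CompartmentSet(*(a.copy() for a in
                                (self.TOP, self.S, self.P_ext, self.R_aw,
                                 self.V_rest, self.R_vasc, self.V,
                                 self.is_open)),
                              S_unit=None if self.S_unit is None
                              else self.S_unit.copy())

    def table_parameters(self) -> np.ndarray:
        """Concatenated [TOP, S, P_ext] on the per-unit table scale."""
        s = self.S if self.S_unit is None else self.S_unit
        return np.concatenate([self.TOP, s, self.P_ext])

    def compartment(self, i: int) -> AlveolarCompartment:
        q = self.q_frac
        return AlveolarCompartment(index=i + 1, TOP=self.TOP[i], S=self.S[i],
                                   P_ext=self.P_ext[i], R_aw=self.R_aw[i],
                                   V=self.V[i], is_open=bool(self.is_open[i]),
                                   q_frac=float(q[i]))


@dataclass
class MechanicsState:
    """Lung state at one instant: time, compartments, airway pressure and
    the net flow exchanged during the last slice."""

    t: float
    compartments: CompartmentSet
    P_aw: float = 0.0
    flow_total: float = 0.0

    @property
    def V_lung(self) -> float:
        return self.compartments.V_lung


def step_mechanics(state: MechanicsState, P_aw: float, dt: float) -> MechanicsState:
    """Advance one time slice at imposed airway pressure.

    Open compartments receive flow (P_aw - P_i)/R_aw,i; a unit whose volume
    reaches zero collapses; collapsed units reopen once P_aw >= TOP.
    Returns a new state (the input is not mutated).
    """
    if dt <= 0 or dt > DT_MAX:
        raise ValueError(f"dt must lie in (0, {DT_MAX}] s")
    if P_aw < 0:
        raise ValueError("airway pressure must be non-negative")
    comp = state.compartments.copy()
    flow = _kernel.step_paw(comp.TOP, comp.S, comp.P_ext, comp.R_aw,
                            comp.V, comp.is_open, float(P_aw), float(dt))
    if not np.all(np.isfinite(comp.V)):
        bad = int(np.flatnonzero(~np.isfinite(comp.V))[0])
        raise SimulationError(f"non-finite volume in compartment {bad + 1}")
    return MechanicsState(t=state.t + dt, compartments=comp,
                          P_aw=float(P_aw), flow_total=float(flow))


@dataclass
class BreathSummary:
    """Per-compartment and aggregate record of the last settled breath."""

    dV: np.ndarray              # tidal inflation per compartment, ml
    P_end_insp: np.ndarray      # end-inspiratory recoil pressures, cmH2O
    paw_end_insp: float
    paw_end_exp: float
    v_lung_end_insp: float      # includes resting volumes, ml
    v_lung_end_exp: float
    paw_max: float
    n_breaths: int
    converged: bool
    cap_exceeded: bool
    vent: VentilatorSettings = None


def run_breaths(compartments: CompartmentSet, vent: VentilatorSettings,
                duration: float, dt: float = DT_DEFAULT,
                settle_tol: float = 0.5, pressure_cap: float = PRESSURE_CAP_DEFAULT,
                min_breaths: int | None = None,
                warn=None) -> BreathSummary | None:
    """Run volume-controlled breaths for up to ``duration`` seconds.

    The compartment state is advanced in place.  Breathing stops early once
    the end-expiratory volume settles (see :func:`_kernel.run_breaths`);
    ``duration`` caps the simulated time at whole breath cycles.  Returns the
    summary of the last breath, or None for a zero-duration run (state
    unchanged).  If the airway pressure exceeds ``pressure_cap`` the summary
    is flagged and ``warn`` (a callable) is invoked with a message.
    """
    if dt <= 0 or dt > DT_MAX:
        raise ValueError(f"dt must lie in (0, {DT_MAX}] s")
    max_breaths = int(duration / vent.t_cycle)
    if min_breaths is not None:
        max_breaths = max(max_breaths, min_breaths)
    if max_breaths == 0:
        return None
    c = compartments
    (status, bad, nb, converged, dV, p_ei, paw_ei, v_ei, v_ee,
     paw_max) = _kernel.run_breaths(
        c.TOP, c.S, c.P_ext, c.R_aw, c.V, c.is_open,
        vent.F_insp, vent.t_insp, vent.t_cycle, vent.PEEP, dt,
        max_breaths, settle_tol)
    if status == _kernel.MECH_NONFINITE:
        raise SimulationError(f"non-finite pressure/volume in compartment {bad + 1}")
    cap = paw_max > pressure_cap
    if cap and warn is not None:
        warn(f"airway pressure {paw_max:.1f} cmH2O exceeded safety cap "
             f"{pressure_cap:.1f} cmH2O")
    vrest = float(c.V_rest.sum())
    return BreathSummary(dV=dV, P_end_insp=p_ei, paw_end_insp=float(paw_ei),
                         paw_end_exp=float(vent.PEEP),
                         v_lung_end_insp=float(v_ei) + vrest,
                         v_lung_end_exp=float(v_ee) + vrest,
                         paw_max=float(paw_max), n_breaths=int(nb),
                         converged=bool(converged), cap_exceeded=bool(cap),
                         vent=vent)


def peak_alveolar_pressure(pressures_or_state) -> float:
    """Mean end-inspiratory pressure over the quartile of compartments with
    the highest pressures (the top ceil(n/4) units)."""
    if isinstance(pressures_or_state, MechanicsState):
        p = pressures_or_state.compartments.pressures()
    elif isinstance(pressures_or_state, CompartmentSet):
        p = pressures_or_state.pressures()
    else:
        p = np.asarray(pressures_or_state, dtype=float)
    n = p.size
    if n < 4:
        raise ValueError("peak alveolar pressure needs at least 4 compartments")
    k = math.ceil(n / 4)
    return float(np.sort(p)[-k:].mean())


def dynamic_compliance(summary: BreathSummary, vent: VentilatorSettings | None = None) -> float:
    """Tidal volume over the proximal airway pressure swing of the last
    breath, ml/cmH2O."""
    vent = vent or summary.vent
    swing = summary.paw_end_insp - summary.paw_end_exp
    if abs(swing) < 1e-9:
        raise ValueError("zero airway pressure swing; dynamic compliance undefined")
    return vent.V_T / swing


def dynamic_strain(v_t: float, frc: float) -> float:
    """Dynamic alveolar strain V_T/FRC (dimensionless)."""
    if frc <= 0:
        raise ValueError("FRC must be positive")
    return v_t / frc


def simulate_breaths_dense(compartments: CompartmentSet, vent: VentilatorSettings,
                           n_breaths: int, dt: float = DT_DEFAULT):
    """Slice-by-slice trajectory of ``n_breaths`` breaths (slow path).

    Returns (t, paw, flow, V) where V has shape (n_slices, n_compartments).
    Uses the same per-slice rules as the compiled breath loop; intended for
    trajectory export and cross-checking, not for optimisation loops.
    """
    c = compartments
    rows_t, rows_paw, rows_flow, rows_v, rows_open = [], [], [], [], []
    t = 0.0
    for _ in range(n_breaths):
        tau = 0.0
        while tau < vent.t_insp - 1e-12:
            h = min(dt, vent.t_insp - tau)
            paw = _kernel.solve_paw(c.TOP, c.S, c.P_ext, c.R_aw, c.V,
                                    c.is_open, vent.F_insp)
            flow = _kernel.step_paw(c.TOP, c.S, c.P_ext, c.R_aw, c.V,
                                    c.is_open, paw, h)
            tau += h
            t += h
            rows_t.append(t); rows_paw.append(paw); rows_flow.append(flow)
            rows_v.append(c.V.copy()); rows_open.append(c.is_open.copy())
        t_exp = vent.t_cycle - vent.t_insp
        tau = 0.0
        while tau < t_exp - 1e-12:
            h = min(dt, t_exp - tau)
            flow = _kernel.step_paw(c.TOP, c.S, c.P_ext, c.R_aw, c.V,
                                    c.is_open, vent.PEEP, h)
            tau += h
            t += h
            rows_t.append(t); rows_paw.append(vent.PEEP); rows_flow.append(flow)
            rows_v.append(c.V.copy()); rows_open.append(c.is_open.copy())
    return (np.array(rows_t), np.array(rows_paw), np.array(rows_flow),
            np.array(rows_v), np.array(rows_open))


def trajectory_frame(compartments: CompartmentSet, t, paw, flow, V, is_open):
    """Tidy per-slice trajectory as a pandas DataFrame
    (t, compartment_id, V, P, is_open) for CSV export."""
    import pandas as pd

    c = compartments
    frames = []
    for i in range(c.n):
        frames.append(pd.DataFrame({
            "t": t, "compartment_id": i + 1, "V": V[:, i],
            "P": c.S[i] * V[:, i] ** 2 + c.P_ext[i],
            "is_open": is_open[:, i]}))
    return pd.concat(frames, ignore_index=True)
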