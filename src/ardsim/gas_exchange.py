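"""Species transport and blood-gas closure.

Inspired gas reaches the compartments through a shared anatomical dead
space whose contents (the previous mixed expirate) are re-breathed at the
start of every inspiration.  End-capillary blood equilibrates fully with
alveolar tensions; unventilated or collapsed units pass mixed-venous blood
unchanged and appear as shunt.  The mixed-venous point is closed by the
metabolic Fick balance

    CvO2 = CaO2 - VO2/(10*CO)        CvCO2 = CaCO2 + VCO2/(10*CO)

(contents ml/dl, CO l/min), iterated with under-relaxation to a fixed point.

Two routes compute the same steady state: an algebraic per-compartment
balance solved by bisection (:func:`steady_state_gas`, the fast path used
everywhere) and an explicit time-sliced integration of alveolar stores
(:class:`GasDynamics`), kept as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel, blood
from .mechanics import CompartmentSet

P_BARO = 760.0
P_H2O = 47.0
#: humidified inspired O2 tension is FiO2 * (760 - 47)
P_DRY = P_BARO - P_H2O
#: flux conversion: ml/min STPD = l/min BTPS * mmHg / K_VENT
K_VENT = 0.863

VD_ANAT_DEFAULT = 160.0
VO2_DEFAULT = 250.0
VCO2_DEFAULT = 200.0

#: venous fixed-point iteration constants
VENOUS_RELAX = 0.5
VENOUS_TOL = 0.05
VENOUS_MAX_ITER = 200


class InfeasibleCirculationError(RuntimeError):
    """Metabolic demand exhausts the mixed-venous O2 content."""


@dataclass
class CirculationConfig:
    """Global circulation and metabolism: cardiac output (l/min),
    haemoglobin (g/l), pulmonary vascular resistance (dyn.s.cm-5) and
    whole-body O2 uptake / CO2 output (ml/min STPD)."""

    CO: float
    Hb: float
    PVR: float = 152.0
    VO2: float = VO2_DEFAULT
    VCO2: float = VCO2_DEFAULT

    def __post_init__(self) -> None:
        if self.CO <= 0:
            raise ValueError("cardiac output must be positive")
        if self.Hb <= 0:
            raise ValueError("haemoglobin must be positive")
        if self.VO2 <= 0 or self.VCO2 <= 0:
            raise ValueError("metabolic rates must be positive")


@dataclass
class BloodGas:
    """Arterial and mixed-venous blood gas summary."""

    PaO2: float
    PaCO2: float
    PvO2: float
    PvCO2: float
    SaO2: float
    CaO2: float
    CvO2: float
    CaCO2: float
    CvCO2: float
    shunt_frac: float


@dataclass
class DeadSpaceResult:
    """Anatomical and Bohr-Enghoff physiological dead space for one breath."""

    V_D_anat: float
    V_D_phys: float
    PE_CO2_mixed: float


@dataclass
class GasSteadyState:
    """Full output of the steady-state gas solve."""

    blood: BloodGas
    dead_space: DeadSpaceResult
    PA_O2: np.ndarray
    PA_CO2: np.ndarray
    ventilated: np.ndarray
    converged: bool
    iterations: int


def inspired_po2(fio2: float) -> float:
    """Humidified inspired O2 tension FiO2*(760-47), mmHg."""
    return fio2 * P_DRY


def mixed_venous_update(ca_o2: float, ca_co2: float, circ: CirculationConfig):
    """One exact Fick step: mixed-venous contents implied by arterial
    contents and the metabolic rates.  Returns (CvO2, CvCO2) in ml/dl."""
    if circ.CO <= 0:
        raise ValueError("cardiac output must be positive")
    cv_o2 = ca_o2 - circ.VO2 / (10.0 * circ.CO)
    cv_co2 = ca_co2 + circ.VCO2 / (10.0 * circ.CO)
    if cv_o2 <= 0:
        raise InfeasibleCirculationError(
            "VO2/(10*CO) exceeds arterial O2 content; configuration infeasible")
    return cv_o2, cv_co2


def arterial_mix(cc_o2: np.ndarray, cc_co2: np.ndarray, q_frac: np.ndarray,
                 ventilated: np.ndarray, cv_o2: float, cv_co2: float,
                 hb: float) -> BloodGas:
    """Perfusion-weighted arterial mixing of end-capillary blood.

    Unventilated compartments contribute mixed-venous blood.  Tensions are
    recovered by inverting the content curves; the shunt fraction is the
    venous admixture (Cc'O2 - CaO2)/(Cc'O2 - CvO2) with Cc'O2 the
    perfusion-weighted content over ventilated units.
    """
    q = np.asarray(q_frac, dtype=float)
    vent = np.asarray(ventilated, dtype=bool)
    co = np.where(vent, cc_o2, cv_o2)
    cc = np.where(vent, cc_co2, cv_co2)
    ca_o2 = float(np.dot(q, co))
    ca_co2 = float(np.dot(q, cc))
    qv = q[vent].sum()
    if qv > 0:
        cc_vent = float(np.dot(q[vent], np.asarray(cc_o2)[vent]) / qv)
        if cc_vent - cv_o2 <= 1e-9:
            shunt = float("nan")  # degenerate: ventilated capillary == venous
        else:
            shunt = max((cc_vent - ca_o2) / (cc_vent - cv_o2), 0.0)
    else:
        shunt = 1.0
    pa_o2 = blood.o2_tension(ca_o2, hb)
    pa_co2 = blood.co2_tension(ca_co2)
    return BloodGas(PaO2=pa_o2, PaCO2=pa_co2,
                    PvO2=blood.o2_tension(cv_o2, hb),
                    PvCO2=blood.co2_tension(cv_co2),
                    SaO2=blood.sao2(pa_o2), CaO2=ca_o2, CvO2=cv_o2,
                    CaCO2=ca_co2, CvCO2=cv_co2, shunt_frac=shunt)


def physiological_dead_space(v_t: float, pa_co2: float, pe_co2: float,
                             vd_anat: float = VD_ANAT_DEFAULT) -> DeadSpaceResult:
    """Bohr-Enghoff physiological dead space
    V_Dphys = V_T * (PaCO2 - PECO2)/PaCO2 with PECO2 the volume-weighted
    mixed-expired CO2 tension of the breath."""
    if pa_co2 <= 0:
        raise ValueError("PaCO2 must be positive")
    vd_phys = v_t * (pa_co2 - pe_co2) / pa_co2
    vd_phys = min(max(vd_phys, 0.0), v_t)
    return DeadSpaceResult(V_D_anat=vd_anat, V_D_phys=vd_phys,
                           PE_CO2_mixed=pe_co2)


def steady_state_gas(dV: np.ndarray, q_frac: np.ndarray,
                     circ: CirculationConfig, fio2: float,
                     v_t: float, rr: float,
                     vd_anat: float = VD_ANAT_DEFAULT,
                     relax: float = VENOUS_RELAX, tol: float = VENOUS_TOL,
                     max_iter: int = VENOUS_MAX_ITER) -> GasSteadyState:
    """Steady-state blood and alveolar gases for a settled breath pattern.

    ``dV`` is the per-compartment tidal inflation (ml/breath) from the
    mechanics solution; ``q_frac`` the perfusion fractions.  See the module
    docstring for the model.
    """
    dV = np.ascontiguousarray(dV, dtype=float)
    q = np.ascontiguousarray(q_frac, dtype=float)
    if abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("perfusion fractions must sum to one")
    (status, iters, pa_alv_o2, pa_alv_co2, pa_o2, pa_co2, pv_o2, pv_co2,
     ca_o2, ca_co2, cv_o2, cv_co2, shunt, pe_co2) = _kernel.gas_steady(
        dV, q, circ.CO, circ.Hb, inspired_po2(fio2), circ.VO2, circ.VCO2,
        float(v_t), float(vd_anat), float(rr), relax, tol, max_iter)
    if status == _kernel.GAS_INFEASIBLE:
        raise InfeasibleCirculationError(
            "VO2/(10*CO) exhausts arterial O2 content at this configuration")
    if np.any(pa_alv_o2 < 0) or np.any(pa_alv_co2 < 0):
        bad = int(np.flatnonzero((pa_alv_o2 < 0) | (pa_alv_co2 < 0))[0])
        raise RuntimeError(f"negative partial pressure in compartment {bad + 1}")
    bg = BloodGas(PaO2=pa_o2, PaCO2=pa_co2, PvO2=pv_o2, PvCO2=pv_co2,
                  SaO2=blood.sao2(pa_o2), CaO2=ca_o2, CvO2=cv_o2,
                  CaCO2=ca_co2, CvCO2=cv_co2, shunt_frac=shunt)
    ds = physiological_dead_space(v_t, pa_co2, pe_co2, vd_anat)
    return GasSteadyState(blood=bg, dead_space=ds, PA_O2=pa_alv_o2,
                          PA_CO2=pa_alv_co2,
                          ventilated=dV > _kernel.VENT_EPS,
                          converged=status == _kernel.GAS_OK,
                          iterations=int(iters))


def gas_flux(gss: GasSteadyState, dV: np.ndarray, q_frac: np.ndarray,
             circ: CirculationConfig, rr: float, v_t: float,
             vd_anat: float = VD_ANAT_DEFAULT):
    """Blood-side O2 uptake and CO2 output summed over compartments,
    ml/min STPD (should equal VO2/VCO2 at steady state)."""
    q = np.asarray(q_frac, dtype=float)
    vent = gss.ventilated
    cc_o2 = np.where(vent, blood.o2_content(np.maximum(gss.PA_O2, 1e-6), circ.Hb),
                     gss.blood.CvO2)
    cc_co2 = np.where(vent, blood.co2_content(np.maximum(gss.PA_CO2, 1e-6)),
                      gss.blood.CvCO2)
    vo2 = float(np.sum(10.0 * q * circ.CO * (cc_o2 - gss.blood.CvO2)))
    vco2 = float(np.sum(10.0 * q * circ.CO * (gss.blood.CvCO2 - cc_co2)))
    return vo2, vco2


@dataclass
class GasDynamics:
    """Explicit time-sliced alveolar gas transport (cross-check path).

    Couples with the dense mechanics stepping: call :meth:`step` once per
    mechanics slice with that slice's per-compartment volume changes.  The
    anatomical dead space is a well-mixed buffer of volume ``vd_anat`` that
    is flushed with fresh gas during inspiration and refilled with mixed
    expirate during expiration; mixed-venous blood relaxes toward the Fick
    point with time constant ``tau_venous``.
    """

    compartments: CompartmentSet
    circ: CirculationConfig
    fio2: float
    vd_anat: float = VD_ANAT_DEFAULT
    tau_venous: float = 15.0
    PA_O2: np.ndarray = None
    PA_CO2: np.ndarray = None
    ds_o2: float = None
    ds_co2: float = 0.0
    cv_o2: float = None
    cv_co2: float = None

    def __post_init__(self) -> None:
        n = self.compartments.n
        pio2 = inspired_po2(self.fio2)
        if self.PA_O2 is None:
            self.PA_O2 = np.full(n, max(pio2 - 50.0, 40.0))
        if self.PA_CO2 is None:
            self.PA_CO2 = np.full(n, 40.0)
        if self.ds_o2 is None:
            self.ds_o2 = pio2
        if self.cv_o2 is None:
            self.cv_o2 = blood.o2_content(40.0, self.circ.Hb)
        if self.cv_co2 is None:
            self.cv_co2 = blood.co2_content(46.0)

    def capillary_contents(self):
        """End-capillary contents; unventilated units carry venous blood."""
        vent = self.compartments.is_open
        cc_o2 = np.where(vent, blood.o2_content(np.maximum(self.PA_O2, 1e-6),
                                                self.circ.Hb), self.cv_o2)
        cc_co2 = np.where(vent, blood.co2_content(np.maximum(self.PA_CO2, 1e-6)),
                          self.cv_co2)
        return cc_o2, cc_co2

    def blood_gas(self) -> BloodGas:
        cc_o2, cc_co2 = self.capillary_contents()
        return arterial_mix(cc_o2, cc_co2, self.compartments.q_frac,
                            self.compartments.is_open, self.cv_o2, self.cv_co2,
                            self.circ.Hb)

    def step(self, delta_v: np.ndarray, dt: float) -> None:
        """Advance gas stores one mechanics slice.

        ``delta_v`` is the signed per-compartment volume change (ml) of the
        slice just taken by the mechanics.
        """
        c = self.compartments
        pio2 = inspired_po2(self.fio2)
        vol = c.V_rest + c.V  # alveolar store volumes after the slice, ml
        inflow = np.maximum(delta_v, 0.0)
        outflow = np.maximum(-delta_v, 0.0)
        f_in = inflow.sum()
        f_out = outflow.sum()
        # dead-space buffer: flushed toward fresh gas while gas flows inward,
        # refilled by mixed expirate while gas flows outward
        if f_in > 0:
            a = min(f_in / self.vd_anat, 1.0)
            self.ds_o2 += a * (pio2 - self.ds_o2)
            self.ds_co2 += a * (0.0 - self.ds_co2)
        if f_out > 0:
            mix_o2 = float(np.dot(outflow, self.PA_O2) / f_out)
            mix_co2 = float(np.dot(outflow, self.PA_CO2) / f_out)
            a = min(f_out / self.vd_anat, 1.0)
            self.ds_o2 += a * (mix_o2 - self.ds_o2)
            self.ds_co2 += a * (mix_co2 - self.ds_co2)
        # dilution of each inflating compartment with dead-space gas
        with np.errstate(divide="ignore", invalid="ignore"):
            self.PA_O2 += inflow / vol * (self.ds_o2 - self.PA_O2)
            self.PA_CO2 += inflow / vol * (self.ds_co2 - self.PA_CO2)
        # alveolar-capillary exchange (quasi-equilibrated capillary)
        q = c.q_frac
        cc_o2, cc_co2 = self.capillary_contents()
        open_ = c.is_open
        upt = 10.0 * q * self.circ.CO * (cc_o2 - self.cv_o2) / 60.0   # ml/s STPD
        out = 10.0 * q * self.circ.CO * (self.cv_co2 - cc_co2) / 60.0
        # STPD species flux -> change in alveolar tension at store volume
        dp_o2 = -upt * K_VENT * 1000.0 / np.maximum(vol, 1.0) * dt
        dp_co2 = out * K_VENT * 1000.0 / np.maximum(vol, 1.0) * dt
        self.PA_O2 = np.where(open_, np.maximum(self.PA_O2 + dp_o2, 0.5), self.PA_O2)
        self.PA_CO2 = np.where(open_, np.maximum(self.PA_CO2 + dp_co2, 0.05),
                               self.PA_CO2)
        if np.any(~np.isfinite(self.PA_O2)) or np.any(~np.isfinite(self.PA_CO2)):
            bad = int(np.flatnonzero(~np.isfinite(self.PA_O2 * self.PA_CO2))[0])
            raise RuntimeError(f"non-finite alveolar tension in compartment {bad + 1}")
        # slow mixed-venous relaxation toward the Fick point
        bg = self.blood_gas()
        cv_o2_t, cv_co2_t = mixed_venous_update(bg.CaO2, bg.CaCO2, self.circ)
        a = min(dt / self.tau_venous, 1.0)
        self.cv_o2 += a * (cv_o2_t - self.cv_o2)
        self.cv_co2 += a * (cv_co2_t - self.cv_co2)


def update_alveolar_gases(gas: GasDynamics, delta_v: np.ndarray, dt: float) -> GasDynamics:
    """Functional wrapper over :meth:`GasDynamics.step` (mutates and
    returns ``gas``)."""
    gas.step(np.asarray(delta_v, dtype=float), dt)
    return gas
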