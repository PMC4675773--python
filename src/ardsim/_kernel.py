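"""Compiled inner loops for the time-sliced lung mechanics and the
steady-state gas-exchange balance.

Everything here works on plain float64 arrays; the public modules wrap these
kernels with validated dataclasses.  The mechanics kernel advances parallel
alveolar compartments behind a shared proximal airway node; the gas kernel
solves the coupled alveolar/capillary balance with mixed-venous (Fick)
closure by nested bisection.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .blood import _co2_content, _co2_tension, _o2_content, _o2_tension

# Mechanics status codes
MECH_OK = 0
MECH_NONFINITE = 1

# Gas status codes
GAS_OK = 0
GAS_UNCONVERGED = 1
GAS_INFEASIBLE = 2  # mixed-venous O2 content exhausted

#: conversion between alveolar ventilation (l/min BTPS) x tension (mmHg)
#: and species flux (ml/min STPD): flux = V̇A * P / 0.863
K_FLUX = 0.863

#: per-compartment tidal inflow (ml) below which a unit counts as
#: unventilated when classifying shunt
VENT_EPS = 0.01


@njit(cache=True)
def solve_paw(TOP, S, Pext, Raw, V, isopen, flow):
    """Proximal airway pressure delivering ``flow`` (ml/s) into the open set.

    Opens collapsed compartments whose threshold opening pressure is reached,
    then re-solves; if nothing is open, pressure rises instantly to the
    lowest TOP.  Mutates ``isopen``.
    """
    n = V.shape[0]
    paw = 0.0
    for _ in range(n + 2):
        sinv = 0.0
        spr = 0.0
        nopen = 0
        for i in range(n):
            if isopen[i]:
                p = S[i] * V[i] * V[i] + Pext[i]
                sinv += 1.0 / Raw[i]
                spr += p / Raw[i]
                nopen += 1
        if nopen == 0:
            tmin = TOP[0]
            for i in range(1, n):
                if TOP[i] < tmin:
                    tmin = TOP[i]
            for i in range(n):
                if TOP[i] <= tmin:
                    isopen[i] = True
            continue
        paw = (flow + spr) / sinv
        opened = False
        for i in range(n):
            if not isopen[i] and paw >= TOP[i]:
                isopen[i] = True
                opened = True
        if not opened:
            return paw
    return paw


@njit(cache=True)
def step_paw(TOP, S, Pext, Raw, V, isopen, paw, dt):
    """One explicit time slice at imposed airway pressure ``paw``.

    Recruits collapsed units with TOP <= paw, moves gas through each open
    unit's bronchiolar resistance, clips volumes at zero (collapse) and
    returns the net flow (ml/s) actually exchanged with the airway.
    Mutates ``V`` and ``isopen``.
    """
    n = V.shape[0]
    for i in range(n):
        if not isopen[i] and paw >= TOP[i]:
            isopen[i] = True
    moved = 0.0
    for i in range(n):
        if isopen[i]:
            p = S[i] * V[i] * V[i] + Pext[i]
            dv = (paw - p) / Raw[i] * dt
            if V[i] + dv <= 0.0:
                dv = -V[i]
                V[i] = 0.0
                isopen[i] = False
            else:
                V[i] += dv
            moved += dv
    return moved / dt


@njit(cache=True)
def run_breaths(TOP, S, Pext, Raw, V, isopen,
                f_insp, t_insp, t_cycle, peep, dt,
                max_breaths, settle_tol):
    """Volume-controlled breaths until breath-to-breath settling.

    Constant-flow inspiration of ``f_insp`` for ``t_insp`` seconds (airway
    pressure solved each slice), then passive expiration against ``peep``.
    Stops early once the end-expiratory lung volume changes by less than
    ``settle_tol`` ml between breaths with an unchanged recruitment set.

    Returns (status, bad_index, n_breaths, converged, dV, P_ei, paw_ei,
    vlung_ei, vlung_ee, paw_max) where dV is the per-compartment tidal
    inflation of the last breath and P_ei the end-inspiratory recoil
    pressures.  Volumes exclude compartment resting volumes.
    """
    n = V.shape[0]
    dV = np.zeros(n)
    P_ei = np.zeros(n)
    prev_open = np.empty(n, np.bool_)
    for i in range(n):
        prev_open[i] = isopen[i]
    paw_ei = peep
    vlung_ei = 0.0
    vlung_ee = 0.0
    paw_max = 0.0
    prev_ee = -1.0e30
    t_exp = t_cycle - t_insp
    status = MECH_OK
    bad = -1
    nb = 0
    converged = False
    for b in range(max_breaths):
        nb = b + 1
        vstart = V.copy()
        # --- inspiration: constant delivered flow ---
        t = 0.0
        paw = peep
        while t < t_insp - 1e-12:
            h = t_insp - t
            if h > dt:
                h = dt
            paw = solve_paw(TOP, S, Pext, Raw, V, isopen, f_insp)
            if not np.isfinite(paw):
                status = MECH_NONFINITE
                for i in range(n):
                    if not np.isfinite(V[i]):
                        bad = i
                        break
                return (status, bad, nb, converged, dV, P_ei, paw_ei,
                        vlung_ei, vlung_ee, paw_max)
            if paw > paw_max:
                paw_max = paw
            for i in range(n):
                if isopen[i]:
                    p = S[i] * V[i] * V[i] + Pext[i]
                    dv = (paw - p) / Raw[i] * h
                    if V[i] + dv <= 0.0:
                        V[i] = 0.0
                        isopen[i] = False
                    else:
                        V[i] += dv
            t += h
        paw_ei = paw
        vlung_ei = 0.0
        for i in range(n):
            P_ei[i] = S[i] * V[i] * V[i] + Pext[i]
            dV[i] = V[i] - vstart[i]
            vlung_ei += V[i]
        # --- passive expiration against PEEP ---
        t = 0.0
        while t < t_exp - 1e-12:
            h = t_exp - t
            if h > dt:
                h = dt
            for i in range(n):
                if not isopen[i] and peep >= TOP[i]:
                    isopen[i] = True
            for i in range(n):
                if isopen[i]:
                    p = S[i] * V[i] * V[i] + Pext[i]
                    dv = (peep - p) / Raw[i] * h
                    if V[i] + dv <= 0.0:
                        V[i] = 0.0
                        isopen[i] = False
                    else:
                        V[i] += dv
            t += h
        vlung_ee = 0.0
        for i in range(n):
            vlung_ee += V[i]
        same = True
        for i in range(n):
            if isopen[i] != prev_open[i]:
                same = False
                break
        if same and b >= 1 and abs(vlung_ee - prev_ee) < settle_tol:
            converged = True
            break
        prev_ee = vlung_ee
        for i in range(n):
            prev_open[i] = isopen[i]
    return (status, bad, nb, converged, dV, P_ei, paw_ei,
            vlung_ei, vlung_ee, paw_max)


@njit(cache=True)
def gas_steady(dV, q, co, hb, pio2, vo2, vco2, vt, vd_anat, rr,
               relax, tol, max_iter):
    """Steady-state alveolar and blood gases for one ventilation pattern.

    Each compartment receives a tidal inflow dV[i] (ml/breath); the first
    ``vd_anat``/``vt`` fraction of every inflow re-breathes mixed expirate
    from the shared anatomical dead space, the rest is humidified fresh gas
    at inspired O2 tension ``pio2``.  End-capillary blood equilibrates fully
    with alveolar tensions; unventilated units pass mixed-venous blood
    unchanged (shunt).  Mixed-venous composition is closed by metabolic
    Fick balance with under-relaxation.

    Returns (status, iters, PAO2, PACO2, pa_o2, pa_co2, pv_o2, pv_co2,
    ca_o2, ca_co2, cv_o2, cv_co2, shunt, pe_co2).
    """
    n = dV.shape[0]
    r = vd_anat / vt
    if r < 0.0:
        r = 0.0
    if r > 0.99:
        r = 0.99
    PAO2 = np.empty(n)
    PACO2 = np.empty(n)
    init_o2 = pio2 - 50.0
    if init_o2 < 40.0:
        init_o2 = 40.0
    for i in range(n):
        PAO2[i] = init_o2
        PACO2[i] = 40.0
    pv_o2 = 40.0
    pv_co2 = 46.0
    cv_o2 = _o2_content(pv_o2, hb)
    cv_co2 = _co2_content(pv_co2)
    sum_dv = 0.0
    for i in range(n):
        if dV[i] > 0.0:
            sum_dv += dV[i]
    status = GAS_UNCONVERGED
    iters = 0
    ca_o2 = 0.0
    ca_co2 = 0.0
    for it in range(max_iter):
        iters = it + 1
        # mixed alveolar expirate (ventilation-weighted), re-breathed from
        # the dead space at the start of the next inspiration
        mo = 0.0
        mc = 0.0
        if sum_dv > 0.0:
            for i in range(n):
                if dV[i] > 0.0:
                    mo += dV[i] * PAO2[i]
                    mc += dV[i] * PACO2[i]
            mo /= sum_dv
            mc /= sum_dv
        for i in range(n):
            d = dV[i]
            if d < 0.0:
                d = 0.0
            va = rr * d / 1000.0          # l/min BTPS
            qf = 10.0 * q[i] * co         # dl/min of blood
            if va <= 1e-9 or qf <= 0.0:
                PAO2[i] = pv_o2
                PACO2[i] = pv_co2
                continue
            pi_eff = (1.0 - r) * pio2 + r * mo
            # O2 balance: va*(pi_eff-P)/K = qf*(c(P)-cv_o2), decreasing in P
            lo = 0.2
            hi = pi_eff
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                g = va * (pi_eff - mid) / K_FLUX - qf * (_o2_content(mid, hb) - cv_o2)
                if g > 0.0:
                    lo = mid
                else:
                    hi = mid
            PAO2[i] = 0.5 * (lo + hi)
            # CO2 balance: va*(P - r*mc)/K = qf*(cv_co2-c(P)), increasing in P
            lo = 0.05
            hi = 150.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                g = va * (mid - r * mc) / K_FLUX - qf * (cv_co2 - _co2_content(mid))
                if g < 0.0:
                    lo = mid
                else:
                    hi = mid
            PACO2[i] = 0.5 * (lo + hi)
        # perfusion-weighted arterial mixing
        ca_o2 = 0.0
        ca_co2 = 0.0
        for i in range(n):
            if dV[i] > VENT_EPS:
                ca_o2 += q[i] * _o2_content(PAO2[i], hb)
                ca_co2 += q[i] * _co2_content(PACO2[i])
            else:
                ca_o2 += q[i] * cv_o2
                ca_co2 += q[i] * cv_co2
        # Fick closure with under-relaxation
        cv_o2_t = ca_o2 - vo2 / (10.0 * co)
        cv_co2_t = ca_co2 + vco2 / (10.0 * co)
        if cv_o2_t <= 0.05:
            status = GAS_INFEASIBLE
            break
        cv_o2_new = cv_o2 + relax * (cv_o2_t - cv_o2)
        cv_co2_new = cv_co2 + relax * (cv_co2_t - cv_co2)
        pv_o2_new = _o2_tension(cv_o2_new, hb)
        pv_co2_new = _co2_tension(cv_co2_new)
        done = (abs(pv_co2_new - pv_co2) < tol) and (abs(pv_o2_new - pv_o2) < tol)
        cv_o2 = cv_o2_new
        cv_co2 = cv_co2_new
        pv_o2 = pv_o2_new
        pv_co2 = pv_co2_new
        if done and it > 2:
            status = GAS_OK
            break
    pa_o2 = _o2_tension(ca_o2, hb)
    pa_co2 = _co2_tension(ca_co2)
    # venous admixture: perfusion-weighted ventilated end-capillary content
    qv = 0.0
    cc_vent = 0.0
    for i in range(n):
        if dV[i] > VENT_EPS:
            qv += q[i]
            cc_vent += q[i] * _o2_content(PAO2[i], hb)
    if qv > 0.0 and cc_vent / qv - cv_o2 > 1e-9:
        shunt = (cc_vent / qv - ca_o2) / (cc_vent / qv - cv_o2)
    elif qv == 0.0:
        shunt = 1.0
    else:
        shunt = np.nan  # degenerate: ventilated capillary equals venous
    if shunt < 0.0:
        shunt = 0.0
    # mixed-expired CO2: dead-space gas (fresh, CO2-free) then alveolar gas
    pe_co2 = (1.0 - r) * mc
    return (status, iters, PAO2, PACO2, pa_o2, pa_co2, pv_o2, pv_co2,
            ca_o2, ca_co2, cv_o2, cv_co2, shunt, pe_co2)
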