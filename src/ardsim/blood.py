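"""Blood gas content relations.

Oxygen is carried bound to haemoglobin plus a dissolved fraction; carbon
dioxide content follows a single frozen empirical curve for whole blood.
Both curves are deliberately simple, monotone and analytically invertible:
the simulator only ever needs content <-> tension round trips, never pH or
temperature corrections (see the methods note).  The constants below are
frozen; tests pin the curves themselves, not external physiology tables.

Units: tensions in mmHg, haemoglobin in g/l, contents in ml(STPD)/dl.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Hüfner constant, ml O2 per g Hb at full saturation.
O2_CAPACITY = 1.34
#: Dissolved O2 solubility, ml/dl per mmHg.
O2_SOLUBILITY = 0.003
#: O2 tension at half saturation, mmHg.
P50 = 26.6
#: Hill cooperativity exponent of the saturation curve.
HILL_N = 2.7

#: CO2 content curve anchor: content (ml/dl) at PCO2 = 40 mmHg.
CO2_C40 = 48.0
#: CO2 content curve exponent (power-law, Douglas-style single-term fit).
CO2_EXP = 0.57


@njit(cache=True)
def _sao2(po2: float) -> float:
    r = (po2 / P50) ** HILL_N
    return r / (1.0 + r)


@njit(cache=True)
def _o2_content(po2: float, hb: float) -> float:
    return O2_CAPACITY * (hb / 10.0) * _sao2(po2) + O2_SOLUBILITY * po2


@njit(cache=True)
def _o2_tension(content: float, hb: float) -> float:
    # o2_content is strictly increasing in PO2; invert by bisection.
    lo, hi = 1e-6, 4000.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _o2_content(mid, hb) < content:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=True)
def _co2_content(pco2: float) -> float:
    return CO2_C40 * (pco2 / 40.0) ** CO2_EXP


@njit(cache=True)
def _co2_tension(content: float) -> float:
    return 40.0 * (content / CO2_C40) ** (1.0 / CO2_EXP)


def sao2(po2):
    """Fractional haemoglobin O2 saturation (Hill curve, P50 = 26.6 mmHg)."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 <= 0):
        raise ValueError("PO2 must be positive")
    r = (po2 / P50) ** HILL_N
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def o2_content(po2, hb):
    """O2 content of blood, ml/dl, for tension ``po2`` (mmHg) and Hb (g/l).

    ``1.34 * (Hb/10) * SaO2(PO2) + 0.003 * PO2``; Hb may be zero
    (dissolved-only limit) but the tension must be positive.
    """
    if hb < 0:
        raise ValueError("haemoglobin must be non-negative")
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 <= 0):
        raise ValueError("PO2 must be positive")
    out = O2_CAPACITY * (hb / 10.0) * sao2(po2) + O2_SOLUBILITY * po2
    return float(out) if np.ndim(out) == 0 else out


def o2_tension(content, hb):
    """Invert :func:`o2_content` for a given haemoglobin concentration."""
    content = np.asarray(content, dtype=float)
    if np.any(content <= 0):
        raise ValueError("O2 content must be positive")
    if content.ndim == 0:
        return _o2_tension(float(content), float(hb))
    return np.array([_o2_tension(float(c), float(hb)) for c in content.ravel()]).reshape(content.shape)


def co2_content(pco2):
    """CO2 content of blood, ml/dl (frozen power-law curve, monotone)."""
    pco2 = np.asarray(pco2, dtype=float)
    if np.any(pco2 <= 0):
        raise ValueError("PCO2 must be positive")
    out = CO2_C40 * (pco2 / 40.0) ** CO2_EXP
    return float(out) if out.ndim == 0 else out


def co2_tension(content):
    """Invert :func:`co2_content` (exact, power-law)."""
    content = np.asarray(content, dtype=float)
    if np.any(content <= 0):
        raise ValueError("CO2 content must be positive")
    out = 40.0 * (content / CO2_C40) ** (1.0 / CO2_EXP)
    return float(out) if out.ndim == 0 else out
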