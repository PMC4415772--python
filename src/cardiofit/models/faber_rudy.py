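"""Flagship guinea-pig ventricular model (Faber–Rudy / Luo–Rudy-dynamic lineage).

A 14-state ventricular myocyte model with the standard dynamic-Luo–Rudy
current complement used for guinea pig: fast Na+ current (m3·h·j), L-type
Ca2+ current with GHK driving force and Ca-dependent inactivation, T-type
Ca2+ current, rapid and slow delayed rectifiers (I_Kr, I_Ks with two
activation gates and Ca-sensitive conductance), inward rectifier I_K1,
plateau K+ current, Na/Ca exchange, Na/K pump, sarcolemmal Ca2+ pump,
background Ca2+/Na+ currents, and a two-pool sarcoplasmic reticulum
(junctional release pool + network uptake pool) with a simplified
Ca-induced-Ca-release flux gated by the L-type channel.

Intra/extracellular ion concentrations are fixed to the experimental
solutions (K+o 5.4, Ca2+o 2.0, Na+o 139.4, Na+i 10, K+i 136 mmol/l) and only
the calcium pools evolve.  The nine scalable parameters multiply the maximal
conductances of I_Na, I_CaL, I_CaT, I_K1, I_Kr, I_Ks, I_Kp, I_pCa and the
maximal SERCA uptake flux.

Same fixed-step Rush–Larsen integration as the reduced model; native step
0.01 ms.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from numba import njit

from .base import IonicModel, ModelState, SolverError

KO, CAO, NAO = 5.4, 2.0, 139.4
NAI, KI = 10.0, 136.0
T_KELVIN = 308.0
RTF = 8314.0 * T_KELVIN / 96485.0
F_CONST = 96485.0

ENA = RTF * np.log(NAO / NAI)
EK = RTF * np.log(KO / KI)
PNAK = 0.01833
EKS = RTF * np.log((KO + PNAK * NAO) / (KI + PNAK * NAI))

G_NA = 16.0
P_CA, P_K, P_NA = 5.4e-4, 1.93e-7, 6.75e-7  # cm/s
GAMMA_CAI, GAMMA_CAO = 1.0, 0.341
GAMMA_KI, GAMMA_KO = 0.75, 0.75
GAMMA_NAI, GAMMA_NAO = 0.75, 0.75
KM_FCA = 6.0e-4
G_CAT = 0.05
G_KR = 0.02614 * np.sqrt(KO / 5.4)
G_KS_BASE = 0.433
G_K1 = 0.75 * np.sqrt(KO / 5.4)
G_KP = 5.52e-3
C1_NACA = 2.5e-4
C2_OVER_C1 = 0.4
GAMMA_NACA = 0.15
IBAR_NAK = 2.25
KM_NAI, KM_KO = 10.0, 1.5
IBAR_PCA = 1.15
KM_PCA = 5.0e-4
G_CAB = 3.016e-3
G_NAB = 1.41e-3

IBAR_UP = 8.75e-3
KM_UP = 9.2e-4
CA_NSR_MAX = 15.0
K_LEAK = IBAR_UP / CA_NSR_MAX
TAU_TR = 120.0
G_REL = 12.0  # 1/ms, simplified CICR gain

# Cell geometry (dynamic-Luo-Rudy).
V_MYO = 25.84e-6  # uL
V_JSR = 0.182e-6
V_NSR = 2.098e-6
A_CAP = 1.534e-4  # cm^2
KCONV = A_CAP / (2.0 * F_CONST * V_MYO)  # A/F -> mM/ms (divalent, myoplasm)

B_TRPN, KM_TRPN = 0.07, 5.0e-4
B_CMDN, KM_CMDN = 0.05, 2.38e-3
B_CSQN, KM_CSQN = 10.0, 0.8

# GHK prefactors: Ibar = K * x * (gi*Ci*exp(x) - go*Co)/(exp(x)-1), x = zV/RTF,
# concentrations in mM, result in A/F (Cm = 1 uF/cm^2).
K_CAL = P_CA * 2.0 * F_CONST * 1.0e-6 * 1.0e6
K_CAK = P_K * 1.0 * F_CONST * 1.0e-6 * 1.0e6
K_CANA = P_NA * 1.0 * F_CONST * 1.0e-6 * 1.0e6

STATE_NAMES = (
    "V", "m", "h", "j", "d", "f", "b", "g", "xr", "xs1", "xs2",
    "Cai", "CaJSR", "CaNSR",
)
CURRENT_NAMES = (
    "I_Na", "I_CaL", "I_CaT", "I_K1", "I_Kr", "I_Ks",
    "I_Kp", "I_pCa", "I_NaCa", "I_NaK", "I_Cab", "I_Nab",
)

# Quiescent state at the fixed ionic conditions (settled by long rest runs).
_INITIAL = np.array([
    -84.21231, 1.761849e-03, 9.820132e-01, 9.887359e-01, 6.838111e-06,
    9.992679e-01, 1.499481e-03, 9.869210e-01, 2.336096e-04, 5.867437e-03,
    5.867828e-03, 6.921304e-05, 1.044091, 1.050866,
])


def _sexp(x):
    return np.exp(np.clip(x, -500.0, 500.0))


def _ratefrac(coef, x, slope):
    """coef * x / (1 - exp(-slope*x)) with the removable singularity at x=0."""
    small = np.abs(x) < 1e-6
    denom = np.where(small, 1.0, 1.0 - _sexp(-slope * x))
    return np.where(small, coef / slope, coef * x / denom)


# -- I_Na gates (Luo-Rudy 1991 formulations) --------------------------------

def _alpha_m(v):
    return _ratefrac(0.32, v + 47.13, 0.1)


def _beta_m(v):
    return 0.08 * _sexp(-v / 11.0)


def _alpha_h(v):
    return np.where(v < -40.0, 0.135 * _sexp(-(80.0 + v) / 6.8), 0.0)


def _beta_h(v):
    return np.where(
        v < -40.0,
        3.56 * _sexp(0.079 * v) + 3.1e5 * _sexp(0.35 * v),
        1.0 / (0.13 * (1.0 + _sexp(-(v + 10.66) / 11.1))),
    )


def _alpha_j(v):
    return np.where(
        v < -40.0,
        (-1.2714e5 * _sexp(0.2444 * v) - 3.474e-5 * _sexp(-0.04391 * v))
        * (v + 37.78) / (1.0 + _sexp(0.311 * (v + 79.23))),
        0.0,
    )


def _beta_j(v):
    return np.where(
        v < -40.0,
        0.1212 * _sexp(-0.01052 * v) / (1.0 + _sexp(-0.1378 * (v + 40.14))),
        0.3 * _sexp(-2.535e-7 * v) / (1.0 + _sexp(-0.1 * (v + 32.0))),
    )


# -- I_CaL gates ------------------------------------------------------------

def d_inf(v):
    return 1.0 / (1.0 + _sexp(-(v + 10.0) / 6.24))


def tau_d(v):
    di = d_inf(v)
    x = v + 10.0
    small = np.abs(x) < 1e-6
    denom = np.where(small, 1.0, 0.035 * x)
    return np.where(
        small,
        di / (6.24 * 0.035),
        di * (1.0 - _sexp(-x / 6.24)) / denom,
    )


def f_inf(v):
    return 1.0 / (1.0 + _sexp((v + 32.0) / 8.0)) + 0.6 / (1.0 + _sexp((50.0 - v) / 20.0))


def tau_f(v):
    return 1.0 / (0.0197 * _sexp(-((0.0337 * (v + 10.0)) ** 2)) + 0.02)


# -- I_CaT gates ------------------------------------------------------------

def b_inf(v):
    return 1.0 / (1.0 + _sexp(-(v + 14.0) / 10.8))


def tau_b(v):
    return 3.7 + 6.1 / (1.0 + _sexp((v + 25.0) / 4.5))


def g_inf(v):
    return 1.0 / (1.0 + _sexp((v + 60.0) / 5.6))


def tau_g(v):
    return np.where(v <= 0.0, -0.875 * v + 12.0, 12.0)


# -- delayed rectifiers ------------------------------------------------------

def xr_inf(v):
    return 1.0 / (1.0 + _sexp(-(v + 21.5) / 7.5))


def tau_xr(v):
    a = _ratefrac(0.00138, v + 14.2, 0.123)
    b = _ratefrac(0.00061, -(v + 38.9), 0.145)
    return 1.0 / (a + b)


def kr_rect(v):
    return 1.0 / (1.0 + _sexp((v + 9.0) / 22.4))


def xs_inf(v):
    return 1.0 / (1.0 + _sexp(-(v - 1.5) / 16.7))


def tau_xs1(v):
    a = _ratefrac(7.19e-5, v + 30.0, 0.148)
    b = _ratefrac(1.31e-4, -(v + 30.0), 0.0687)
    return 1.0 / (a + b)


def k1_inf(v):
    ak = 1.02 / (1.0 + _sexp(0.2385 * (v - EK - 59.215)))
    bk = (
        0.49124 * _sexp(0.08032 * (v - EK + 5.476))
        + _sexp(0.06175 * (v - EK - 594.31))
    ) / (1.0 + _sexp(-0.5143 * (v - EK + 4.753)))
    return ak / (ak + bk)


def kp_act(v):
    return 1.0 / (1.0 + _sexp((7.488 - v) / 5.98))


def nak_current(v):
    sigma = (np.exp(NAO / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (
        1.0 + 0.1245 * _sexp(-0.1 * v / RTF) + 0.0365 * sigma * _sexp(-v / RTF)
    )
    return IBAR_NAK * fnak / (1.0 + (KM_NAI / NAI) ** 1.5) * KO / (KO + KM_KO)


def naca_factors(v):
    e1 = _sexp((GAMMA_NACA - 1.0) * v / RTF)
    e2 = e1 * _sexp(v / RTF)
    a = C1_NACA * e2 * NAI ** 3 * CAO
    b = C1_NACA * e1 * NAO ** 3
    return a, b


def _ghk_pair(v, z, kfac, gi, go, co):
    """A, B with Ibar = A*Ci - B (GHK, fixed outside concentration)."""
    x = z * v / RTF
    ex = _sexp(x)
    small = np.abs(x) < 1e-9
    frac = np.where(small, 1.0, x / np.where(small, 1.0, ex - 1.0))
    a = kfac * frac * gi * ex
    b = kfac * frac * go * co
    return a, b


def ghk_fixed(v, z, kfac, gi, ci, go, co):
    a, b = _ghk_pair(v, z, kfac, gi, go, co)
    return a * ci - b


# ---------------------------------------------------------------------------
# Lookup table

VMIN, VMAX, DV = -160.0, 90.0, 0.05
NV = int(round((VMAX - VMIN) / DV)) + 1
_VGRID = VMIN + DV * np.arange(NV)

(C_MI, C_ME, C_HI, C_HE, C_JI, C_JE, C_DI, C_DE, C_FI, C_FE,
 C_BI, C_BE, C_GI, C_GE, C_XRI, C_XRE, C_XSI, C_XS1E, C_XS2E,
 C_K1, C_KR, C_KP, C_KS, C_NAK, C_NCA, C_NCB,
 C_CAA, C_CAB, C_CAK, C_CANA) = range(30)

_TABLE_CACHE: dict = {}


def rate_table(dt: float) -> np.ndarray:
    key = round(float(dt), 12)
    tab = _TABLE_CACHE.get(key)
    if tab is not None:
        return tab
    v = _VGRID
    tab = np.empty((NV, 30))

    def ab_gate(ci, ce, alpha, beta):
        a, b = alpha(v), beta(v)
        tab[:, ci] = a / (a + b)
        tab[:, ce] = np.exp(-dt * (a + b))

    ab_gate(C_MI, C_ME, _alpha_m, _beta_m)
    ab_gate(C_HI, C_HE, _alpha_h, _beta_h)
    ab_gate(C_JI, C_JE, _alpha_j, _beta_j)
    for ci, ce, finf, ftau in (
        (C_DI, C_DE, d_inf, tau_d),
        (C_FI, C_FE, f_inf, tau_f),
        (C_BI, C_BE, b_inf, tau_b),
        (C_GI, C_GE, g_inf, tau_g),
        (C_XRI, C_XRE, xr_inf, tau_xr),
    ):
        tab[:, ci] = finf(v)
        tab[:, ce] = np.exp(-dt / ftau(v))
    tab[:, C_XSI] = xs_inf(v)
    tab[:, C_XS1E] = np.exp(-dt / tau_xs1(v))
    tab[:, C_XS2E] = np.exp(-dt / (4.0 * tau_xs1(v)))

    tab[:, C_K1] = k1_inf(v) * (v - EK)
    tab[:, C_KR] = kr_rect(v) * (v - EK)
    tab[:, C_KP] = kp_act(v) * (v - EK)
    tab[:, C_KS] = v - EKS
    tab[:, C_NAK] = nak_current(v)
    a, b = naca_factors(v)
    tab[:, C_NCA] = a
    tab[:, C_NCB] = b
    a, b = _ghk_pair(v, 2.0, K_CAL, GAMMA_CAI, GAMMA_CAO, CAO)
    tab[:, C_CAA] = a
    tab[:, C_CAB] = b
    tab[:, C_CAK] = ghk_fixed(v, 1.0, K_CAK, GAMMA_KI, KI, GAMMA_KO, KO)
    tab[:, C_CANA] = ghk_fixed(v, 1.0, K_CANA, GAMMA_NAI, NAI, GAMMA_NAO, NAO)
    tab = np.ascontiguousarray(tab)
    _TABLE_CACHE[key] = tab
    return tab


# ---------------------------------------------------------------------------
# Kernels

@njit(cache=True)
def _lerp(tab, i0, w, c):
    return tab[i0, c] + w * (tab[i0 + 1, c] - tab[i0, c])


@njit(cache=True)
def _currents(tab, pos, s, v, y):
    i0 = int(pos)
    w = pos - i0
    m, h, j, d, f, b, g, xr, xs1, xs2, cai = (
        y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8], y[9], y[10], y[11]
    )
    fca = 1.0 / (1.0 + cai / KM_FCA)
    df = d * f * fca
    ibarca = _lerp(tab, i0, w, C_CAA) * cai - _lerp(tab, i0, w, C_CAB)
    ical = s[1] * df * (ibarca + _lerp(tab, i0, w, C_CAK) + _lerp(tab, i0, w, C_CANA))
    ical_ca = s[1] * df * ibarca
    eca = 0.5 * RTF * np.log(CAO / cai)
    ina = s[0] * G_NA * m * m * m * h * j * (v - ENA)
    icat = s[2] * G_CAT * b * b * g * (v - eca)
    ik1 = s[3] * G_K1 * _lerp(tab, i0, w, C_K1)
    ikr = s[4] * G_KR * xr * _lerp(tab, i0, w, C_KR)
    gks = G_KS_BASE * (1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4))
    iks = s[5] * gks * xs1 * xs2 * _lerp(tab, i0, w, C_KS)
    ikp = s[6] * G_KP * _lerp(tab, i0, w, C_KP)
    ipca = s[7] * IBAR_PCA * cai / (KM_PCA + cai)
    nca = _lerp(tab, i0, w, C_NCA)
    ncb = _lerp(tab, i0, w, C_NCB)
    inaca = (nca - ncb * cai) / (1.0 + C2_OVER_C1 * (nca + ncb * cai))
    inak = _lerp(tab, i0, w, C_NAK)
    icab = G_CAB * (v - eca)
    inab = G_NAB * (v - ENA)
    return ina, ical, icat, ik1, ikr, iks, ikp, ipca, inaca, inak, icab, inab, ical_ca


@njit(cache=True)
def _advance(tab, pos, dt, s, y, ical_ca, icat, ipca, icab, inaca):
    i0 = int(pos)
    w = pos - i0
    y[1] = _lerp(tab, i0, w, C_MI) + (y[1] - _lerp(tab, i0, w, C_MI)) * _lerp(tab, i0, w, C_ME)
    y[2] = _lerp(tab, i0, w, C_HI) + (y[2] - _lerp(tab, i0, w, C_HI)) * _lerp(tab, i0, w, C_HE)
    y[3] = _lerp(tab, i0, w, C_JI) + (y[3] - _lerp(tab, i0, w, C_JI)) * _lerp(tab, i0, w, C_JE)
    y[4] = _lerp(tab, i0, w, C_DI) + (y[4] - _lerp(tab, i0, w, C_DI)) * _lerp(tab, i0, w, C_DE)
    y[5] = _lerp(tab, i0, w, C_FI) + (y[5] - _lerp(tab, i0, w, C_FI)) * _lerp(tab, i0, w, C_FE)
    y[6] = _lerp(tab, i0, w, C_BI) + (y[6] - _lerp(tab, i0, w, C_BI)) * _lerp(tab, i0, w, C_BE)
    y[7] = _lerp(tab, i0, w, C_GI) + (y[7] - _lerp(tab, i0, w, C_GI)) * _lerp(tab, i0, w, C_GE)
    y[8] = _lerp(tab, i0, w, C_XRI) + (y[8] - _lerp(tab, i0, w, C_XRI)) * _lerp(tab, i0, w, C_XRE)
    xsi = _lerp(tab, i0, w, C_XSI)
    y[9] = xsi + (y[9] - xsi) * _lerp(tab, i0, w, C_XS1E)
    y[10] = xsi + (y[10] - xsi) * _lerp(tab, i0, w, C_XS2E)

    cai, cajsr, cansr = y[11], y[12], y[13]
    fca = 1.0 / (1.0 + cai / KM_FCA)
    jup = s[8] * IBAR_UP * cai / (cai + KM_UP)
    jleak = K_LEAK * cansr
    jtr = (cansr - cajsr) / TAU_TR
    jrel = G_REL * y[4] * y[5] * fca * (cajsr - cai)
    bt = KM_TRPN + cai
    bc = KM_CMDN + cai
    beta = 1.0 / (1.0 + B_TRPN * KM_TRPN / (bt * bt) + B_CMDN * KM_CMDN / (bc * bc))
    bs = KM_CSQN + cajsr
    beta_jsr = 1.0 / (1.0 + B_CSQN * KM_CSQN / (bs * bs))
    dcai = beta * (
        -(ical_ca + icat + ipca + icab - 2.0 * inaca) * KCONV
        + (jleak - jup) * (V_NSR / V_MYO)
        + jrel * (V_JSR / V_MYO)
    )
    y[11] = cai + dt * dcai
    y[12] = cajsr + dt * beta_jsr * (jtr - jrel)
    y[13] = cansr + dt * (jup - jleak - jtr * (V_JSR / V_NSR))


@njit(cache=True)
def _clip_pos(v):
    pos = (v - VMIN) / DV
    if pos < 0.0:
        pos = 0.0
    elif pos > NV - 1.001:
        pos = NV - 1.001
    return pos


@njit(cache=True)
def _cc_kernel(y, s, tab, dt, stride, n_total, rec0, onsets, amp, width,
               vout, caout, record_ca):
    n_on = onsets.shape[0]
    k = 0
    iout = 0
    for step in range(n_total + 1):
        if step >= rec0 and (step - rec0) % stride == 0:
            vout[iout] = y[0]
            if record_ca:
                caout[iout] = y[11]
            iout += 1
        if step == n_total:
            break
        t = step * dt
        while k < n_on and t >= onsets[k] + width:
            k += 1
        istim = amp if (k < n_on and t >= onsets[k]) else 0.0
        v = y[0]
        pos = _clip_pos(v)
        (ina, ical, icat, ik1, ikr, iks, ikp, ipca, inaca, inak, icab, inab,
         ical_ca) = _currents(tab, pos, s, v, y)
        iion = (ina + ical + icat + ik1 + ikr + iks + ikp + ipca + inaca + inak
                + icab + inab)
        _advance(tab, pos, dt, s, y, ical_ca, icat, ipca, icab, inaca)
        y[0] = v - dt * (iion + istim)
        if not (y[0] == y[0]) or not (y[11] == y[11]):
            return step
    return -1


@njit(cache=True)
def _vc_kernel(y, s, tab, dt, stride, seg_steps, seg_v, rec0,
               itot_out, cur_out, record_currents, caout, record_ca):
    gstep = 0
    iout = 0
    v = seg_v[0]
    for seg in range(seg_steps.shape[0]):
        v = seg_v[seg]
        y[0] = v
        for _ in range(seg_steps[seg]):
            pos = _clip_pos(v)
            (ina, ical, icat, ik1, ikr, iks, ikp, ipca, inaca, inak, icab,
             inab, ical_ca) = _currents(tab, pos, s, v, y)
            iion = (ina + ical + icat + ik1 + ikr + iks + ikp + ipca + inaca
                    + inak + icab + inab)
            if gstep >= rec0 and (gstep - rec0) % stride == 0:
                itot_out[iout] = iion
                if record_currents:
                    cur_out[0, iout] = ina
                    cur_out[1, iout] = ical
                    cur_out[2, iout] = icat
                    cur_out[3, iout] = ik1
                    cur_out[4, iout] = ikr
                    cur_out[5, iout] = iks
                    cur_out[6, iout] = ikp
                    cur_out[7, iout] = ipca
                    cur_out[8, iout] = inaca
                    cur_out[9, iout] = inak
                    cur_out[10, iout] = icab
                    cur_out[11, iout] = inab
                if record_ca:
                    caout[iout] = y[11]
                iout += 1
            _advance(tab, pos, dt, s, y, ical_ca, icat, ipca, icab, inaca)
            if not (y[11] == y[11]):
                return gstep
            gstep += 1
    pos = _clip_pos(v)
    (ina, ical, icat, ik1, ikr, iks, ikp, ipca, inaca, inak, icab, inab,
     ical_ca) = _currents(tab, pos, s, v, y)
    iion = (ina + ical + icat + ik1 + ikr + iks + ikp + ipca + inaca + inak
            + icab + inab)
    if gstep >= rec0 and (gstep - rec0) % stride == 0:
        itot_out[iout] = iion
        if record_currents:
            cur_out[0, iout] = ina
            cur_out[1, iout] = ical
            cur_out[2, iout] = icat
            cur_out[3, iout] = ik1
            cur_out[4, iout] = ikr
            cur_out[5, iout] = iks
            cur_out[6, iout] = ikp
            cur_out[7, iout] = ipca
            cur_out[8, iout] = inaca
            cur_out[9, iout] = inak
            cur_out[10, iout] = icab
            cur_out[11, iout] = inab
        if record_ca:
            caout[iout] = y[11]
    return -1


class FaberRudyModel(IonicModel):
    name = "faber-rudy"
    state_names = STATE_NAMES
    current_names = CURRENT_NAMES
    default_dt = 0.01

    def initial_state(self) -> ModelState:
        return self.make_state(_INITIAL.copy())

    def run_current_clamp(self, scalings, state, onsets, amplitude, width,
                          duration, record_start, dt, out_dt, record_ca=False):
        stride = int(round(out_dt / dt))
        rec0 = int(round(record_start / dt))
        n_total = int(round(duration / dt))
        n_out = (n_total - rec0) // stride + 1
        vout = np.empty(n_out)
        caout = np.empty(n_out if record_ca else 1)
        y = np.asarray(state, dtype=np.float64).copy()
        tab = rate_table(dt)
        fail = _cc_kernel(
            y, np.asarray(scalings, np.float64), tab, dt, stride, n_total, rec0,
            np.asarray(onsets, np.float64), float(amplitude), float(width),
            vout, caout, record_ca,
        )
        if fail >= 0:
            raise SolverError(self.name, fail * dt, "V/Cai")
        times = out_dt * np.arange(n_out)
        return times, vout, (caout if record_ca else None), y

    def run_voltage_clamp(self, scalings, state, durations, potentials,
                          prehold_duration, prehold_potential, dt, out_dt,
                          record_currents=False, record_ca=False):
        stride = int(round(out_dt / dt))
        seg_steps = [int(round(d / dt)) for d in durations]
        seg_v = list(potentials)
        rec0 = 0
        if prehold_duration and prehold_duration > 0:
            seg_steps.insert(0, int(round(prehold_duration / dt)))
            seg_v.insert(0, prehold_potential)
            rec0 = seg_steps[0]
        seg_steps = np.asarray(seg_steps, dtype=np.int64)
        seg_v = np.asarray(seg_v, dtype=np.float64)
        n_total = int(seg_steps.sum())
        n_out = (n_total - rec0) // stride + 1
        itot = np.empty(n_out)
        cur = np.empty((len(CURRENT_NAMES), n_out) if record_currents else (1, 1))
        caout = np.empty(n_out if record_ca else 1)
        y = np.asarray(state, dtype=np.float64).copy()
        tab = rate_table(dt)
        fail = _vc_kernel(
            y, np.asarray(scalings, np.float64), tab, dt, stride, seg_steps,
            seg_v, rec0, itot, cur, record_currents, caout, record_ca,
        )
        if fail >= 0:
            raise SolverError(self.name, fail * dt, "Cai")
        times = out_dt * np.arange(n_out)
        return (times, itot, (cur if record_currents else None),
                (caout if record_ca else None), y)

    def currents_at(self, state, scalings) -> Dict[str, float]:
        y = np.asarray(state, np.float64)
        s = np.asarray(scalings, np.float64)
        v, cai = y[0], y[11]
        m, h, j, d, f, b, g, xr, xs1, xs2 = y[1:11]
        fca = 1.0 / (1.0 + cai / KM_FCA)
        df = d * f * fca
        ibarca = float(ghk_fixed(np.float64(v), 2.0, K_CAL, GAMMA_CAI, cai,
                                 GAMMA_CAO, CAO))
        icak = float(ghk_fixed(np.float64(v), 1.0, K_CAK, GAMMA_KI, KI,
                               GAMMA_KO, KO))
        icana = float(ghk_fixed(np.float64(v), 1.0, K_CANA, GAMMA_NAI, NAI,
                                GAMMA_NAO, NAO))
        eca = 0.5 * RTF * np.log(CAO / cai)
        a, bb = naca_factors(np.float64(v))
        gks = G_KS_BASE * (1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4))
        out = {
            "I_Na": s[0] * G_NA * m ** 3 * h * j * (v - ENA),
            "I_CaL": s[1] * df * (ibarca + icak + icana),
            "I_CaT": s[2] * G_CAT * b ** 2 * g * (v - eca),
            "I_K1": s[3] * G_K1 * float(k1_inf(v)) * (v - EK),
            "I_Kr": s[4] * G_KR * xr * float(kr_rect(v)) * (v - EK),
            "I_Ks": s[5] * gks * xs1 * xs2 * (v - EKS),
            "I_Kp": s[6] * G_KP * float(kp_act(v)) * (v - EK),
            "I_pCa": s[7] * IBAR_PCA * cai / (KM_PCA + cai),
            "I_NaCa": float((a - bb * cai) / (1.0 + C2_OVER_C1 * (a + bb * cai))),
            "I_NaK": float(nak_current(np.float64(v))),
            "I_Cab": G_CAB * (v - eca),
            "I_Nab": G_NAB * (v - ENA),
        }
        return {k: float(vv) for k, vv in out.items()}
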