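"""Fast reduced guinea-pig-like ventricular model.

A compact (10-state) Hodgkin–Huxley-type ventricular myocyte model carrying
the same nine scalable currents/fluxes as the flagship model: I_Na, I_CaL,
I_CaT, I_K1, I_Kr, I_Ks, I_Kp, I_pCa and the SERCA uptake flux, plus
unscaled Na/Ca exchange, Na/K pump and background currents, and a single-pool
sarcoplasmic reticulum with calcium-induced calcium release.  Rate constants
are in the Luo–Rudy lineage but simplified (merged Na inactivation, single
delayed-rectifier activation gates, linear Ca driving force) so that a full
stochastic-pacing + voltage-clamp evaluation runs in milliseconds.

The model is the workhorse for the in-silico parameter-recovery studies and
the test suite; it is its own ground truth there (targets and candidates are
integrated identically), so conclusions transfer to any model honouring the
same contract.

Integration: fixed-step Rush–Larsen for the seven gates (voltage-dependent
steady states and exponential decay factors pre-tabulated on a 0.05 mV grid),
forward Euler for membrane potential and the two calcium pools.  Native step
0.05 ms.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from numba import njit

from .base import IonicModel, ModelState, SolverError

# Fixed ionic conditions (mmol/l) and temperature: experimental solutions.
KO, CAO, NAO = 5.4, 2.0, 139.4
NAI, KI = 10.0, 136.0
T_KELVIN = 308.0
RTF = 8314.0 * T_KELVIN / 96485.0  # mV

ENA = RTF * np.log(NAO / NAI)
EK = RTF * np.log(KO / KI)
PNAK = 0.01833
EKS = RTF * np.log((KO + PNAK * NAO) / (KI + PNAK * NAI))
ECAL = 60.0  # effective Ca-channel reversal (mV), linear driving force
ECAB = 120.0

# Maximal conductances (mS/uF) and fluxes (mM/ms), baseline (scaling = 1).
G_NA = 14.0
G_CAL = 0.175
G_CAT = 0.05
G_K1 = 0.6
G_KR = 0.04
G_KS = 0.055
G_KP = 0.008
IBAR_PCA = 1.15
KM_PCA = 5.0e-4
KM_FCA = 6.0e-4
C1_NACA = 2.5e-4
C2_OVER_C1 = 0.4
GAMMA_NACA = 0.15
IBAR_NAK = 1.0
KM_NAI, KM_KO = 10.0, 1.5
G_CAB = 2.2e-3
G_NAB = 1.41e-3

# Calcium subsystem.
IBAR_UP = 7.5e-3  # mM/ms
KM_UP = 9.2e-4
K_LEAK = IBAR_UP / 30.0
G_REL = 5.0e-3  # 1/ms
KCONV = 1.534e-4 / (2.0 * 96485.0 * 25.84e-6)  # A/F -> mM/ms (myoplasm)
B_TRPN, KM_TRPN = 0.07, 5.0e-4
B_CMDN, KM_CMDN = 0.05, 2.38e-3
B_CSQN, KM_CSQN = 10.0, 0.8
V_SR_RATIO = 0.06

STATE_NAMES = ("V", "m", "h", "d", "f", "g", "xr", "xs", "Cai", "CaSR")
CURRENT_NAMES = (
    "I_Na", "I_CaL", "I_CaT", "I_K1", "I_Kr", "I_Ks",
    "I_Kp", "I_pCa", "I_NaCa", "I_NaK", "I_Cab", "I_Nab",
)

# Resting state at the fixed ionic conditions (settled by >60 s quiescent
# integration at the native step).
_INITIAL = np.array([
    -84.01700, 1.819949e-03, 7.100245e-01, 7.055533e-06, 9.988091e-01,
    9.614806e-01, 2.397690e-04, 5.935933e-03, 5.376886e-05, 1.656285,
])

# ---------------------------------------------------------------------------
# Voltage-dependent rate functions (numpy, vectorized; single source for the
# lookup tables, the instantaneous-current evaluator and the test oracles).

def _sexp(x):
    return np.exp(np.clip(x, -500.0, 500.0))


def _ratefrac(coef, x, slope):
    """coef * x / (1 - exp(-slope*x)) with the removable singularity at x=0."""
    small = np.abs(x) < 1e-6
    denom = np.where(small, 1.0, 1.0 - _sexp(-slope * x))
    return np.where(small, coef / slope, coef * x / denom)


def _alpha_m(v):
    return _ratefrac(0.32, v + 47.13, 0.1)


def m_inf(v):
    am = _alpha_m(v)
    bm = 0.08 * _sexp(-v / 11.0)
    return am / (am + bm)


def tau_m(v):
    am = _alpha_m(v)
    bm = 0.08 * _sexp(-v / 11.0)
    return 1.0 / (am + bm)


def h_inf(v):
    return 1.0 / (1.0 + _sexp((v + 71.55) / 7.43)) ** 2


def tau_h(v):
    return 0.5 + 6.5 * _sexp(-(((v + 75.0) / 14.0) ** 2))


def d_inf(v):
    return 1.0 / (1.0 + _sexp(-(v + 10.0) / 6.24))


def tau_d(v):
    return 0.6 + 2.4 * _sexp(-(((v + 15.0) / 25.0) ** 2))


def f_inf(v):
    return 1.0 / (1.0 + _sexp((v + 32.0) / 8.0)) + 0.25 / (1.0 + _sexp((50.0 - v) / 20.0))


def tau_f(v):
    return 18.0 + 95.0 * _sexp(-(((v + 25.0) / 40.0) ** 2))


def b_inf(v):
    return 1.0 / (1.0 + _sexp(-(v + 48.0) / 5.4))


def g_inf(v):
    return 1.0 / (1.0 + _sexp((v + 66.0) / 5.6))


def tau_g(v):
    return 8.0 + 30.0 / (1.0 + _sexp((v + 60.0) / 6.0))


def xr_inf(v):
    return 1.0 / (1.0 + _sexp(-(v + 21.5) / 7.5))


def tau_xr(v):
    a = _ratefrac(0.00138, v + 14.2, 0.123)
    b = _ratefrac(0.00061, -(v + 38.9), 0.145)
    return 1.0 / (a + b)


def xs_inf(v):
    return 1.0 / (1.0 + _sexp(-(v - 1.5) / 16.7))


def tau_xs(v):
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


def kr_rect(v):
    return 1.0 / (1.0 + _sexp((v + 9.0) / 22.4))


def kp_act(v):
    return 1.0 / (1.0 + _sexp((7.488 - v) / 5.98))


def nak_current(v):
    sigma = (np.exp(NAO / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (
        1.0 + 0.1245 * _sexp(-0.1 * v / RTF) + 0.0365 * sigma * _sexp(-v / RTF)
    )
    return (
        IBAR_NAK * fnak / (1.0 + (KM_NAI / NAI) ** 2) * KO / (KO + KM_KO)
    )


def naca_factors(v):
    """V-dependent factors A, B with I_NaCa = (A - B*Cai) / (1 + 0.4*(A + B*Cai))."""
    e1 = _sexp((GAMMA_NACA - 1.0) * v / RTF)
    e2 = e1 * _sexp(v / RTF)
    a = C1_NACA * e2 * NAI ** 3 * CAO
    b = C1_NACA * e1 * NAO ** 3
    return a, b


# ---------------------------------------------------------------------------
# Lookup tables

VMIN, VMAX, DV = -160.0, 90.0, 0.05
NV = int(round((VMAX - VMIN) / DV)) + 1
_VGRID = VMIN + DV * np.arange(NV)

# Column layout (gates: steady state, exp(-dt/tau) pairs; then drive terms).
(C_MI, C_ME, C_HI, C_HE, C_DI, C_DE, C_FI, C_FE, C_GI, C_GE,
 C_XRI, C_XRE, C_XSI, C_XSE, C_B2, C_K1, C_KR, C_KP, C_KS, C_NAK,
 C_NCA, C_NCB) = range(22)

_TABLE_CACHE: dict = {}


def rate_table(dt: float) -> np.ndarray:
    """Tabulated gate steady states / decay factors and V-dependent drives."""
    key = round(float(dt), 12)
    tab = _TABLE_CACHE.get(key)
    if tab is not None:
        return tab
    v = _VGRID
    tab = np.empty((NV, 22))
    for ci, ce, finf, ftau in (
        (C_MI, C_ME, m_inf, tau_m),
        (C_HI, C_HE, h_inf, tau_h),
        (C_DI, C_DE, d_inf, tau_d),
        (C_FI, C_FE, f_inf, tau_f),
        (C_GI, C_GE, g_inf, tau_g),
        (C_XRI, C_XRE, xr_inf, tau_xr),
        (C_XSI, C_XSE, xs_inf, tau_xs),
    ):
        tab[:, ci] = finf(v)
        tab[:, ce] = np.exp(-dt / ftau(v))
    tab[:, C_B2] = b_inf(v) ** 2
    tab[:, C_K1] = k1_inf(v) * (v - EK)
    tab[:, C_KR] = kr_rect(v) * (v - EK)
    tab[:, C_KP] = kp_act(v) * (v - EK)
    tab[:, C_KS] = v - EKS
    tab[:, C_NAK] = nak_current(v)
    a, b = naca_factors(v)
    tab[:, C_NCA] = a
    tab[:, C_NCB] = b
    tab = np.ascontiguousarray(tab)
    _TABLE_CACHE[key] = tab
    return tab


# ---------------------------------------------------------------------------
# Kernels

@njit(cache=True)
def _currents(tab, pos, s, v, m, h, d, f, g, xr, xs, cai):
    i0 = int(pos)
    w = pos - i0
    r0 = tab[i0]
    r1 = tab[i0 + 1]
    b2 = r0[C_B2] + w * (r1[C_B2] - r0[C_B2])
    k1d = r0[C_K1] + w * (r1[C_K1] - r0[C_K1])
    krd = r0[C_KR] + w * (r1[C_KR] - r0[C_KR])
    kpd = r0[C_KP] + w * (r1[C_KP] - r0[C_KP])
    ksd = r0[C_KS] + w * (r1[C_KS] - r0[C_KS])
    inak = r0[C_NAK] + w * (r1[C_NAK] - r0[C_NAK])
    nca = r0[C_NCA] + w * (r1[C_NCA] - r0[C_NCA])
    ncb = r0[C_NCB] + w * (r1[C_NCB] - r0[C_NCB])

    fca = 1.0 / (1.0 + cai / KM_FCA)
    ina = s[0] * G_NA * m * m * m * h * (v - ENA)
    ical = s[1] * G_CAL * d * f * fca * (v - ECAL)
    icat = s[2] * G_CAT * b2 * g * (v - ECAL)
    ik1 = s[3] * G_K1 * k1d
    ikr = s[4] * G_KR * xr * krd
    iks = s[5] * G_KS * xs * xs * ksd
    ikp = s[6] * G_KP * kpd
    ipca = s[7] * IBAR_PCA * cai / (KM_PCA + cai)
    inaca = (nca - ncb * cai) / (1.0 + C2_OVER_C1 * (nca + ncb * cai))
    icab = G_CAB * (v - ECAB)
    inab = G_NAB * (v - ENA)
    return ina, ical, icat, ik1, ikr, iks, ikp, ipca, inaca, inak, icab, inab


@njit(cache=True)
def _advance(tab, pos, dt, s, m, h, d, f, g, xr, xs, cai, casr, ical, icat, ipca, icab, inaca):
    """One Rush-Larsen / Euler step for gates and calcium; returns new values."""
    i0 = int(pos)
    w = pos - i0
    r0 = tab[i0]
    r1 = tab[i0 + 1]

    mi = r0[C_MI] + w * (r1[C_MI] - r0[C_MI])
    me = r0[C_ME] + w * (r1[C_ME] - r0[C_ME])
    hi = r0[C_HI] + w * (r1[C_HI] - r0[C_HI])
    he = r0[C_HE] + w * (r1[C_HE] - r0[C_HE])
    di = r0[C_DI] + w * (r1[C_DI] - r0[C_DI])
    de = r0[C_DE] + w * (r1[C_DE] - r0[C_DE])
    fi = r0[C_FI] + w * (r1[C_FI] - r0[C_FI])
    fe = r0[C_FE] + w * (r1[C_FE] - r0[C_FE])
    gi = r0[C_GI] + w * (r1[C_GI] - r0[C_GI])
    ge = r0[C_GE] + w * (r1[C_GE] - r0[C_GE])
    xri = r0[C_XRI] + w * (r1[C_XRI] - r0[C_XRI])
    xre = r0[C_XRE] + w * (r1[C_XRE] - r0[C_XRE])
    xsi = r0[C_XSI] + w * (r1[C_XSI] - r0[C_XSI])
    xse = r0[C_XSE] + w * (r1[C_XSE] - r0[C_XSE])

    m = mi + (m - mi) * me
    h = hi + (h - hi) * he
    dg = di + (d - di) * de
    f = fi + (f - fi) * fe
    g = gi + (g - gi) * ge
    xr = xri + (xr - xri) * xre
    xs = xsi + (xs - xsi) * xse

    jup = s[8] * IBAR_UP * cai / (cai + KM_UP)
    jleak = K_LEAK * casr
    jrel = G_REL * dg * f * (casr - cai)
    bt = KM_TRPN + cai
    bc = KM_CMDN + cai
    beta = 1.0 / (1.0 + B_TRPN * KM_TRPN / (bt * bt) + B_CMDN * KM_CMDN / (bc * bc))
    bs = KM_CSQN + casr
    beta_sr = 1.0 / (1.0 + B_CSQN * KM_CSQN / (bs * bs))
    dcai = beta * (
        -(ical + icat + ipca + icab - 2.0 * inaca) * KCONV + jrel + jleak - jup
    )
    dcasr = beta_sr * (jup - jrel - jleak) / V_SR_RATIO
    cai += dt * dcai
    casr += dt * dcasr
    return m, h, dg, f, g, xr, xs, cai, casr


@njit(cache=True)
def _clip_pos(v):
    pos = (v - VMIN) / DV
    if pos < 0.0:
        pos = 0.0
    elif pos > NV - 1.001:
        pos = NV - 1.001
    return pos


@njit(cache=True)
def _cc_kernel(state, s, tab, dt, stride, n_total, rec0, onsets, amp, width,
               vout, caout, record_ca):
    v = state[0]
    m, h, d, f, g, xr, xs, cai, casr = (
        state[1], state[2], state[3], state[4], state[5],
        state[6], state[7], state[8], state[9],
    )
    n_on = onsets.shape[0]
    k = 0
    iout = 0
    for step in range(n_total + 1):
        if step >= rec0 and (step - rec0) % stride == 0:
            vout[iout] = v
            if record_ca:
                caout[iout] = cai
            iout += 1
        if step == n_total:
            break
        t = step * dt
        while k < n_on and t >= onsets[k] + width:
            k += 1
        istim = amp if (k < n_on and t >= onsets[k]) else 0.0
        pos = _clip_pos(v)
        ina, ical, icat, ik1, ikr, iks, ikp, ipca, inaca, inak, icab, inab = _currents(
            tab, pos, s, v, m, h, d, f, g, xr, xs, cai
        )
        iion = (ina + ical + icat + ik1 + ikr + iks + ikp + ipca + inaca + inak
                + icab + inab)
        m, h, d, f, g, xr, xs, cai, casr = _advance(
            tab, pos, dt, s, m, h, d, f, g, xr, xs, cai, casr,
            ical, icat, ipca, icab, inaca,
        )
        v = v - dt * (iion + istim)
        if not (v == v) or not (cai == cai):
            return step
    state[0] = v
    state[1], state[2], state[3], state[4], state[5] = m, h, d, f, g
    state[6], state[7], state[8], state[9] = xr, xs, cai, casr
    return -1


@njit(cache=True)
def _vc_kernel(state, s, tab, dt, stride, seg_steps, seg_v, rec0,
               itot_out, cur_out, record_currents, caout, record_ca):
    m, h, d, f, g, xr, xs, cai, casr = (
        state[1], state[2], state[3], state[4], state[5],
        state[6], state[7], state[8], state[9],
    )
    n_total = 0
    for i in range(seg_steps.shape[0]):
        n_total += seg_steps[i]
    gstep = 0
    iout = 0
    v = seg_v[0]
    for seg in range(seg_steps.shape[0]):
        v = seg_v[seg]
        for _ in range(seg_steps[seg]):
            pos = _clip_pos(v)
            ina, ical, icat, ik1, ikr, iks, ikp, ipca, inaca, inak, icab, inab = _currents(
                tab, pos, s, v, m, h, d, f, g, xr, xs, cai
            )
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
                    caout[iout] = cai
                iout += 1
            m, h, d, f, g, xr, xs, cai, casr = _advance(
                tab, pos, dt, s, m, h, d, f, g, xr, xs, cai, casr,
                ical, icat, ipca, icab, inaca,
            )
            if not (cai == cai):
                return gstep
            gstep += 1
    # final sample at the end of the last step
    pos = _clip_pos(v)
    ina, ical, icat, ik1, ikr, iks, ikp, ipca, inaca, inak, icab, inab = _currents(
        tab, pos, s, v, m, h, d, f, g, xr, xs, cai
    )
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
            caout[iout] = cai
    state[0] = v
    state[1], state[2], state[3], state[4], state[5] = m, h, d, f, g
    state[6], state[7], state[8], state[9] = xr, xs, cai, casr
    return -1


# ---------------------------------------------------------------------------

class ReducedModel(IonicModel):
    name = "reduced"
    state_names = STATE_NAMES
    current_names = CURRENT_NAMES
    default_dt = 0.05

    def initial_state(self) -> ModelState:
        return self.make_state(_INITIAL.copy())

    # -- runners ---------------------------------------------------------
    def run_current_clamp(self, scalings, state, onsets, amplitude, width,
                          duration, record_start, dt, out_dt, record_ca=False):
        stride = int(round(out_dt / dt))
        rec0 = int(round(record_start / dt))
        n_total = int(round(duration / dt))
        n_out = (n_total - rec0) // stride + 1
        vout = np.empty(n_out)
        caout = np.empty(n_out if record_ca else 1)
        st = np.asarray(state, dtype=np.float64).copy()
        tab = rate_table(dt)
        fail = _cc_kernel(
            st, np.asarray(scalings, np.float64), tab, dt, stride, n_total, rec0,
            np.asarray(onsets, np.float64), float(amplitude), float(width),
            vout, caout, record_ca,
        )
        if fail >= 0:
            raise SolverError(self.name, fail * dt, "V/Cai")
        times = out_dt * np.arange(n_out)
        return times, vout, (caout if record_ca else None), st

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
        st = np.asarray(state, dtype=np.float64).copy()
        tab = rate_table(dt)
        fail = _vc_kernel(
            st, np.asarray(scalings, np.float64), tab, dt, stride, seg_steps,
            seg_v, rec0, itot, cur, record_currents, caout, record_ca,
        )
        if fail >= 0:
            raise SolverError(self.name, fail * dt, "Cai")
        times = out_dt * np.arange(n_out)
        return (times, itot, (cur if record_currents else None),
                (caout if record_ca else None), st)

    # -- diagnostics ------------------------------------------------------
    def currents_at(self, state, scalings) -> Dict[str, float]:
        v, m, h, d, f, g, xr, xs, cai = (
            state[0], state[1], state[2], state[3], state[4], state[5],
            state[6], state[7], state[8],
        )
        s = np.asarray(scalings, np.float64)
        fca = 1.0 / (1.0 + cai / KM_FCA)
        a, b = naca_factors(np.float64(v))
        out = {
            "I_Na": s[0] * G_NA * m ** 3 * h * (v - ENA),
            "I_CaL": s[1] * G_CAL * d * f * fca * (v - ECAL),
            "I_CaT": s[2] * G_CAT * float(b_inf(v)) ** 2 * g * (v - ECAL),
            "I_K1": s[3] * G_K1 * float(k1_inf(v)) * (v - EK),
            "I_Kr": s[4] * G_KR * xr * float(kr_rect(v)) * (v - EK),
            "I_Ks": s[5] * G_KS * xs ** 2 * (v - EKS),
            "I_Kp": s[6] * G_KP * float(kp_act(v)) * (v - EK),
            "I_pCa": s[7] * IBAR_PCA * cai / (KM_PCA + cai),
            "I_NaCa": float((a - b * cai) / (1.0 + C2_OVER_C1 * (a + b * cai))),
            "I_NaK": float(nak_current(np.float64(v))),
            "I_Cab": G_CAB * (v - ECAB),
            "I_Nab": G_NAB * (v - ENA),
        }
        return {k: float(vv) for k, vv in out.items()}

    def rhs(self, t, y, scalings, istim=0.0):
        """Plain-Python right-hand side (same equations; used by test oracles)."""
        v, m, h, d, f, g, xr, xs, cai, casr = y
        s = np.asarray(scalings, np.float64)
        cur = self.currents_at(y, s)
        iion = sum(cur.values())
        jup = s[8] * IBAR_UP * cai / (cai + KM_UP)
        jleak = K_LEAK * casr
        jrel = G_REL * d * f * (casr - cai)
        beta = 1.0 / (
            1.0
            + B_TRPN * KM_TRPN / (KM_TRPN + cai) ** 2
            + B_CMDN * KM_CMDN / (KM_CMDN + cai) ** 2
        )
        beta_sr = 1.0 / (1.0 + B_CSQN * KM_CSQN / (KM_CSQN + casr) ** 2)
        dcai = beta * (
            -(cur["I_CaL"] + cur["I_CaT"] + cur["I_pCa"] + cur["I_Cab"]
              - 2.0 * cur["I_NaCa"]) * KCONV
            + jrel + jleak - jup
        )
        dcasr = beta_sr * (jup - jrel - jleak) / V_SR_RATIO
        return np.array([
            -(iion + istim),
            (m_inf(v) - m) / tau_m(v),
            (h_inf(v) - h) / tau_h(v),
            (d_inf(v) - d) / tau_d(v),
            (f_inf(v) - f) / tau_f(v),
            (g_inf(v) - g) / tau_g(v),
            (xr_inf(v) - xr) / tau_xr(v),
            (xs_inf(v) - xs) / tau_xs(v),
            dcai,
            dcasr,
        ])
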