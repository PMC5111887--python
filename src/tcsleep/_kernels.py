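"""Numba time-stepping kernel for the thalamocortical network.

Numerical scheme
----------------
* Voltage-dependent gating variables advance by exact exponential relaxation
  toward their steady state, with (x_inf, exp(-dt/tau)) read from
  voltage-indexed lookup tables built once per run (0.1 mV resolution,
  linear interpolation).
* Membrane voltages advance by an implicit-Euler step in which every current
  is written as g*(V - E) with conductances frozen at the current gates:
  V_new = (Cm/dt * V + sum g*E + I_inj) / (Cm/dt + sum g).  Unconditionally
  stable.
* Slow states (Ca pools, the Ca-gated h-current scheme, GABA-B cascade,
  depression recovery) advance by forward Euler (their time constants are
  orders of magnitude above dt).
* The zero-capacitance somatic compartment of cortical cells is solved
  exactly each step: with gates frozen all somatic currents are linear in
  Vs, so the current balance g_cs(Vd - Vs) = -(I_Na + I_K + I_Nap) has the
  closed-form root implemented in ``_solve_vs``.

Evoked synapses keep one open-fraction state per presynaptic cell and
synapse type (all edges from one source share kinetics); per-edge miniature
PSPs are aggregated per target cell as quantal jumps with exact exponential
decay.  A single numba RNG stream drives mini release (fixed loop order =>
bit-reproducible runs for a fixed seed).
"""

import math

import numpy as np
from numba import njit

from . import constants as C
from .cells import (
    CX_VD, CX_VS, CX_MNA_D, CX_HNA_D, CX_MNAP_D, CX_MCA, CX_HCA, CX_MKCA,
    CX_MKM, CX_CA, CX_MNA_S, CX_HNA_S, CX_NK_S, CX_MNAP_S,
    TC_V, TC_MNA, TC_HNA, TC_NK, TC_MT, TC_HT, TC_CA, TC_O, TC_P1, TC_OL,
    RE_V, RE_MNA, RE_HNA, RE_NK, RE_MT, RE_HT, RE_CA,
    na_rates, k_rates, nap_m_inf, km_rates, hva_rates,
    tc_t_gates, re_t_gates, h_inf, ih_tau_s,
)
from .synapses import mini_quantum

# ---------------------------------------------------------------------------
# Lookup tables
# ---------------------------------------------------------------------------
V_MIN, V_MAX, DV = -150.0, 60.0, 0.1
N_ROW = int(round((V_MAX - V_MIN) / DV)) + 1
INV_DV = 1.0 / DV

# cortical table columns
(CT_MNA_I, CT_MNA_F, CT_HNA_I, CT_HNA_F, CT_NK_I, CT_NK_F, CT_MNAP_I,
 CT_MKM_I, CT_MKM_F, CT_MCA_I, CT_MCA_F, CT_HCA_I, CT_HCA_F, CT_FM) = range(14)
# thalamic table columns (TC adds the h-current columns)
(TT_MNA_I, TT_MNA_F, TT_HNA_I, TT_HNA_F, TT_NK_I, TT_NK_F, TT_MT_I, TT_MT_F,
 TT_HT_I, TT_HT_F, TT_HINF0, TT_TAUS) = range(12)

# packed parameter-vector slots (see cells.cx_param_vector / tc_param_vector)
(PG_KL, PG_CL, PE_CL, PG_NA_D, PG_NAP_D, PG_CA_D, PG_KCA_D, PG_KM_D,
 PG_NA_S, PG_K_S, PG_NAP_S, PCM, PS_DEND, PS_SOMA, PG_CS, PEXT,
 PCA_TAU) = range(17)
(TG_LEAK, TE_LEAK, TG_KL, TG_NA, TG_K, TG_T, TG_H, TCM, TAREA,
 TIH_K, TIH_K1, TIH_K2, TIH_K3, TIH_K4, TE_H) = range(15)


def build_tables(dt: float):
    """(cx_table, tc_table, re_table) of per-gate (inf, exp(-dt/tau))."""
    v = V_MIN + DV * np.arange(N_ROW)
    cx = np.empty((N_ROW, 14))
    tc = np.empty((N_ROW, 12))
    re = np.empty((N_ROW, 10))
    for i, vi in enumerate(v):
        am, bm, ah, bh = na_rates(vi, C.VTR_CX)
        cx[i, CT_MNA_I], cx[i, CT_MNA_F] = am / (am + bm), math.exp(-dt * (am + bm))
        cx[i, CT_HNA_I], cx[i, CT_HNA_F] = ah / (ah + bh), math.exp(-dt * (ah + bh))
        an, bn = k_rates(vi, C.VTR_CX)
        an, bn = an / C.CX_NK_SLOW, bn / C.CX_NK_SLOW
        cx[i, CT_NK_I], cx[i, CT_NK_F] = an / (an + bn), math.exp(-dt * (an + bn))
        cx[i, CT_MNAP_I] = nap_m_inf(vi)
        a, b = km_rates(vi)
        cx[i, CT_MKM_I], cx[i, CT_MKM_F] = a / (a + b), math.exp(-dt * (a + b))
        am, bm, ah, bh = hva_rates(vi)
        cx[i, CT_MCA_I], cx[i, CT_MCA_F] = am / (am + bm), math.exp(-dt * (am + bm))
        cx[i, CT_HCA_I], cx[i, CT_HCA_F] = ah / (ah + bh), math.exp(-dt * (ah + bh))
        cx[i, CT_FM] = 1.0 / (1.0 + math.exp(-(vi - C.NMDA_MG_V0) / C.NMDA_MG_SLOPE))

        am, bm, ah, bh = na_rates(vi, C.VTR_TC)
        tc[i, TT_MNA_I], tc[i, TT_MNA_F] = am / (am + bm), math.exp(-dt * (am + bm))
        tc[i, TT_HNA_I], tc[i, TT_HNA_F] = ah / (ah + bh), math.exp(-dt * (ah + bh))
        an, bn = k_rates(vi, C.VTR_TC)
        tc[i, TT_NK_I], tc[i, TT_NK_F] = an / (an + bn), math.exp(-dt * (an + bn))
        am, bm, ah, bh = na_rates(vi, C.VTR_RE)
        re[i, TT_MNA_I], re[i, TT_MNA_F] = am / (am + bm), math.exp(-dt * (am + bm))
        re[i, TT_HNA_I], re[i, TT_HNA_F] = ah / (ah + bh), math.exp(-dt * (ah + bh))
        an, bn = k_rates(vi, C.VTR_RE)
        re[i, TT_NK_I], re[i, TT_NK_F] = an / (an + bn), math.exp(-dt * (an + bn))
        mi, tm, hi, th = tc_t_gates(vi)
        tc[i, TT_MT_I], tc[i, TT_MT_F] = mi, math.exp(-dt / tm)
        tc[i, TT_HT_I], tc[i, TT_HT_F] = hi, math.exp(-dt / th)
        tc[i, TT_HINF0] = h_inf(vi, 0.0)
        tc[i, TT_TAUS] = ih_tau_s(vi)
        mi, tm, hi, th = re_t_gates(vi)
        re[i, TT_MT_I], re[i, TT_MT_F] = mi, math.exp(-dt / tm)
        re[i, TT_HT_I], re[i, TT_HT_F] = hi, math.exp(-dt / th)
    return cx, tc, re


@njit(inline="always", cache=True)
def _row(v):
    x = (v - V_MIN) * INV_DV
    if x < 0.0:
        x = 0.0
    elif x > N_ROW - 1.001:
        x = N_ROW - 1.001
    i = int(x)
    return i, x - i


@njit(inline="always", cache=True)
def _lk(tab, i, f, col):
    return tab[i, col] * (1.0 - f) + tab[i + 1, col] * f


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(inline="always", cache=True)
def _gather(indptr, src, invfan, val, out, n_post):
    for j in range(n_post):
        s = 0.0
        for k in range(indptr[j], indptr[j + 1]):
            s += val[src[k]]
        out[j] = s * invfan[j]


# quantal mini increments (per-edge peak open fraction)
_Q_AMPA = mini_quantum(C.AMPA_ALPHA, C.AMPA_BETA, t_dur=C.MINI_T_DUR)
_Q_GABA = mini_quantum(C.GABAA_ALPHA, C.GABAA_BETA, t_dur=C.MINI_T_DUR)

_E_NA, _E_K, _E_H = C.E_NA, C.E_K, C.E_H
_E_AMPA, _E_GA, _E_GB = C.E_AMPA, C.E_GABAA, C.E_GABAB
_E_GA_CX = C.E_GABAA_CX
_CAF, _CAA, _CAD = C.CA_INF, C.CA_A, C.CA_D
_CAD_CX = C.CA_D_CX
_RT2F, _CAO = C.RT_2F, C.CA_O
_GBK1, _GBK2, _GBK3, _GBK4, _GBKD = (C.GABAB["k1"], C.GABAB["k2"],
                                     C.GABAB["k3"], C.GABAB["k4"],
                                     C.GABAB["kd"])
_T_MAX, _T_DUR = C.T_MAX, C.T_DUR
_DEP_U, _DEP_TAU = C.DEPRESSION_U, C.DEPRESSION_TAU
_MINI_MAX, _MINI_TAU = C.MINI_RATE_MAX, C.MINI_RATE_TAU
_AM_A, _AM_B = C.AMPA_ALPHA, C.AMPA_BETA
_NM_A, _NM_B = C.NMDA_ALPHA, C.NMDA_BETA
_GA_A, _GA_B = C.GABAA_ALPHA, C.GABAA_BETA


@njit(inline="always", cache=True)
def _eca(ca):
    if ca < 1e-8:
        ca = 1e-8
    return _RT2F * math.log(_CAO / ca)


@njit(cache=True)
def _update_cx(st, p, tab, g_ampa, g_nmda, g_gaba, i_inj, ach, dt, n, nap_fac):
    """One step of a cortical population. g_* in uS per cell; i_inj in nA."""
    s_d = p[PS_DEND]
    s_s = p[PS_SOMA]
    us2d = 1.0e-3 / s_d              # uS -> mS/cm^2 (dendrite)
    g_cs_d = p[PG_CS] * 1.0e-3 / s_d
    g_cs_s = p[PG_CS] * 1.0e-3 / s_s
    ext = ach if p[PEXT] > 0.5 else 1.0
    cmdt = p[PCM] / dt
    for i in range(n):
        vd = st[i, CX_VD]
        vs = st[i, CX_VS]
        ca = st[i, CX_CA]
        eca = _eca(ca)
        # dendritic conductances (mS/cm^2) and their reversals
        g_kl = ach * p[PG_KL]
        g_cl = p[PG_CL]
        g_na = p[PG_NA_D] * st[i, CX_MNA_D] ** 3 * st[i, CX_HNA_D]
        g_nap = ext * p[PG_NAP_D] * st[i, CX_MNAP_D]
        g_ca = p[PG_CA_D] * st[i, CX_MCA] ** 2 * st[i, CX_HCA]
        g_kca = ext * p[PG_KCA_D] * st[i, CX_MKCA]
        g_km = ext * p[PG_KM_D] * st[i, CX_MKM]
        ia, fa = _row(vd)
        fm = _lk(tab, ia, fa, CT_FM)
        g_sa = g_ampa[i] * us2d
        g_sn = g_nmda[i] * fm * us2d
        g_sg = g_gaba[i] * us2d
        gsum = (g_kl + g_cl + g_na + g_nap + g_ca + g_kca + g_km + g_cs_d
                + g_sa + g_sn + g_sg)
        gesum = (g_kl * _E_K + g_cl * p[PE_CL] + (g_na + g_nap) * _E_NA
                 + g_ca * eca + (g_kca + g_km) * _E_K + g_cs_d * vs
                 + (g_sa + g_sn) * _E_AMPA + g_sg * _E_GA_CX)
        i_ext = i_inj[i] * 1.0e-3 / s_d          # nA -> uA/cm^2, inward +
        vd_new = (cmdt * vd + gesum + i_ext) / (cmdt + gsum)
        st[i, CX_VD] = vd_new
        # calcium pool driven by the HVA current at the old voltage
        i_ca = g_ca * (vd - eca)
        influx = -_CAA * i_ca / _CAD_CX if i_ca < 0.0 else 0.0
        ca += dt * (influx + (_CAF - ca) / p[PCA_TAU])
        st[i, CX_CA] = ca if ca > 0.0 else 0.0
        # dendritic gates (exponential relaxation via table at old vd)
        st[i, CX_MNA_D] = _relax(st[i, CX_MNA_D], tab, ia, fa, CT_MNA_I, CT_MNA_F)
        st[i, CX_HNA_D] = _relax(st[i, CX_HNA_D], tab, ia, fa, CT_HNA_I, CT_HNA_F)
        st[i, CX_MNAP_D] += (1.0 - nap_fac) * (_lk(tab, ia, fa, CT_MNAP_I)
                                               - st[i, CX_MNAP_D])
        st[i, CX_MCA] = _relax(st[i, CX_MCA], tab, ia, fa, CT_MCA_I, CT_MCA_F)
        st[i, CX_HCA] = _relax(st[i, CX_HCA], tab, ia, fa, CT_HCA_I, CT_HCA_F)
        st[i, CX_MKM] = _relax(st[i, CX_MKM], tab, ia, fa, CT_MKM_I, CT_MKM_F)
        a = C.KCA_ALPHA * ca * ca
        st[i, CX_MKCA] += dt * (a * (1.0 - st[i, CX_MKCA])
                                - C.KCA_BETA * st[i, CX_MKCA])
        # somatic gates at old vs, then the algebraic somatic voltage
        is_, fs = _row(vs)
        st[i, CX_MNA_S] = _relax(st[i, CX_MNA_S], tab, is_, fs, CT_MNA_I, CT_MNA_F)
        st[i, CX_HNA_S] = _relax(st[i, CX_HNA_S], tab, is_, fs, CT_HNA_I, CT_HNA_F)
        st[i, CX_NK_S] = _relax(st[i, CX_NK_S], tab, is_, fs, CT_NK_I, CT_NK_F)
        st[i, CX_MNAP_S] += (1.0 - nap_fac) * (_lk(tab, is_, fs, CT_MNAP_I)
                                               - st[i, CX_MNAP_S])
        g_na_s = p[PG_NA_S] * st[i, CX_MNA_S] ** 3 * st[i, CX_HNA_S]
        g_k_s = p[PG_K_S] * st[i, CX_NK_S] ** 2
        g_nap_s = p[PG_NAP_S] * st[i, CX_MNAP_S]
        st[i, CX_VS] = ((g_cs_s * vd_new + (g_na_s + g_nap_s) * _E_NA
                         + g_k_s * _E_K)
                        / (g_cs_s + g_na_s + g_k_s + g_nap_s))


@njit(inline="always", cache=True)
def _relax(x, tab, i, f, ci, cf):
    inf = _lk(tab, i, f, ci)
    fac = _lk(tab, i, f, cf)
    return inf + (x - inf) * fac


@njit(cache=True)
def _update_tc(st, p, tab, g_ampa, g_gaba, g_gabab, i_inj, ach, shift, dt, n):
    area = p[TAREA]
    us2d = 1.0e-3 / area
    cmdt = p[TCM] / dt
    for i in range(n):
        v = st[i, TC_V]
        ca = st[i, TC_CA]
        eca = _eca(ca)
        g_kl = ach * p[TG_KL]
        g_lk = p[TG_LEAK]
        g_na = p[TG_NA] * st[i, TC_MNA] ** 3 * st[i, TC_HNA]
        g_k = p[TG_K] * st[i, TC_NK] ** 4
        g_t = p[TG_T] * st[i, TC_MT] ** 2 * st[i, TC_HT]
        g_h = p[TG_H] * (st[i, TC_O] + p[TIH_K] * st[i, TC_OL])
        g_sa = g_ampa[i] * us2d
        g_sg = g_gaba[i] * us2d
        g_sb = g_gabab[i] * us2d
        gsum = g_kl + g_lk + g_na + g_k + g_t + g_h + g_sa + g_sg + g_sb
        gesum = (g_kl * _E_K + g_lk * p[TE_LEAK] + g_na * _E_NA
                 + g_k * _E_K + g_t * eca + g_h * p[TE_H]
                 + g_sa * _E_AMPA + g_sg * _E_GA + g_sb * _E_GB)
        i_ext = i_inj[i] * 1.0e-3 / area
        v_new = (cmdt * v + gesum + i_ext) / (cmdt + gsum)
        st[i, TC_V] = v_new
        # calcium from the T current at the old voltage
        i_t = g_t * (v - eca)
        influx = -_CAA * i_t / _CAD if i_t < 0.0 else 0.0
        ca += dt * (influx + (_CAF - ca) / C.CA_TAU_TH)
        st[i, TC_CA] = ca if ca > 0.0 else 0.0
        ia, fa = _row(v)
        st[i, TC_MNA] = _relax(st[i, TC_MNA], tab, ia, fa, TT_MNA_I, TT_MNA_F)
        st[i, TC_HNA] = _relax(st[i, TC_HNA], tab, ia, fa, TT_HNA_I, TT_HNA_F)
        st[i, TC_NK] = _relax(st[i, TC_NK], tab, ia, fa, TT_NK_I, TT_NK_F)
        st[i, TC_MT] = _relax(st[i, TC_MT], tab, ia, fa, TT_MT_I, TT_MT_F)
        st[i, TC_HT] = _relax(st[i, TC_HT], tab, ia, fa, TT_HT_I, TT_HT_F)
        # Ca-gated h-current: voltage gate shifted by the HA level
        ish, fsh = _row(v + shift)
        hinf = _lk(tab, ish, fsh, TT_HINF0)
        taus = _lk(tab, ia, fa, TT_TAUS)
        o = st[i, TC_O]
        p1 = st[i, TC_P1]
        ol = st[i, TC_OL]
        alpha = hinf / taus
        beta = (1.0 - hinf) / taus
        do = (alpha * (1.0 - o - ol) - beta * o
              - p[TIH_K3] * o * p1 + p[TIH_K4] * ol)
        dp1 = p[TIH_K1] * ca ** 4 * (1.0 - p1) - p[TIH_K2] * p1
        dol = p[TIH_K3] * o * p1 - p[TIH_K4] * ol
        o += dt * do
        p1 += dt * dp1
        ol += dt * dol
        o = min(max(o, 0.0), 1.0)
        p1 = min(max(p1, 0.0), 1.0)
        ol = min(max(ol, 0.0), 1.0 - o)
        st[i, TC_O], st[i, TC_P1], st[i, TC_OL] = o, p1, ol


@njit(cache=True)
def _update_re(st, p, tab, g_ampa, g_gaba, i_inj, ach, dt, n):
    area = p[TAREA]
    us2d = 1.0e-3 / area
    cmdt = p[TCM] / dt
    for i in range(n):
        v = st[i, RE_V]
        ca = st[i, RE_CA]
        eca = _eca(ca)
        g_kl = ach * p[TG_KL]
        g_lk = p[TG_LEAK]
        g_na = p[TG_NA] * st[i, RE_MNA] ** 3 * st[i, RE_HNA]
        g_k = p[TG_K] * st[i, RE_NK] ** 4
        g_t = p[TG_T] * st[i, RE_MT] ** 2 * st[i, RE_HT]
        g_sa = g_ampa[i] * us2d
        g_sg = g_gaba[i] * us2d
        gsum = g_kl + g_lk + g_na + g_k + g_t + g_sa + g_sg
        gesum = (g_kl * _E_K + g_lk * p[TE_LEAK] + g_na * _E_NA
                 + g_k * _E_K + g_t * eca + g_sa * _E_AMPA + g_sg * _E_GA)
        i_ext = i_inj[i] * 1.0e-3 / area
        st[i, RE_V] = (cmdt * v + gesum + i_ext) / (cmdt + gsum)
        i_t = g_t * (v - eca)
        influx = -_CAA * i_t / _CAD if i_t < 0.0 else 0.0
        ca += dt * (influx + (_CAF - ca) / C.CA_TAU_TH)
        st[i, RE_CA] = ca if ca > 0.0 else 0.0
        ia, fa = _row(v)
        st[i, RE_MNA] = _relax(st[i, RE_MNA], tab, ia, fa, TT_MNA_I, TT_MNA_F)
        st[i, RE_HNA] = _relax(st[i, RE_HNA], tab, ia, fa, TT_HNA_I, TT_HNA_F)
        st[i, RE_NK] = _relax(st[i, RE_NK], tab, ia, fa, TT_NK_I, TT_NK_F)
        st[i, RE_MT] = _relax(st[i, RE_MT], tab, ia, fa, TT_MT_I, TT_MT_F)
        st[i, RE_HT] = _relax(st[i, RE_HT], tab, ia, fa, TT_HT_I, TT_HT_F)


@njit(cache=True)
def run_chunk(n_steps, dt, t_start, steps_per_ms,
              dep_u, dep_tau,
              scal, stim,
              py, inn, tc, re,
              pyp, inp, tcp, rep,
              cx_tab, tc_tab, re_tab, nap_fac,
              projs, minis, gvec,
              o_ampa_py, o_nmda_py, dep_py, o_gabaa_in, o_ampa_tc,
              o_gabaa_re, gb_r, gb_g,
              pulse_py, pulse_in, pulse_tc, pulse_re,
              t0_py, t0_in, ls_py, ls_in, ls_tc, ls_re,
              rec_py, rec_mean, rec_col,
              spk_t, spk_id, spk_n_in):
    """Advance the whole network ``n_steps`` from ``t_start`` (ms).

    Returns (n_spikes_total, err_code, err_cell, err_time); err_code 1 means
    a non-finite voltage was detected at a record boundary.
    """
    n_py, n_in, n_tc, n_re = py.shape[0], inn.shape[0], tc.shape[0], re.shape[0]
    (pp_ip, pp_s, pp_w) = projs[0]
    (pi_ip, pi_s, pi_w) = projs[1]
    (ip_ip, ip_s, ip_w) = projs[2]
    (tp_ip, tp_s, tp_w) = projs[3]
    (ti_ip, ti_s, ti_w) = projs[4]
    (pt_ip, pt_s, pt_w) = projs[5]
    (pr_ip, pr_s, pr_w) = projs[6]
    (tr_ip, tr_s, tr_w) = projs[7]
    (rt_ip, rt_s, rt_w) = projs[8]
    (rr_ip, rr_s, rr_w) = projs[9]
    (mpp_s, mpp_d, mpp_w, mpp_next, mpp_agg) = minis[0]
    (mpi_s, mpi_d, mpi_w, mpi_next, mpi_agg) = minis[1]
    (mip_s, mip_d, mip_w, mip_next, mip_agg) = minis[2]

    # scratch
    val_py = np.empty(n_py)
    g_ampa_py = np.empty(n_py)
    g_nmda_py = np.empty(n_py)
    g_gaba_py = np.empty(n_py)
    g_ampa_in = np.empty(n_in)
    g_nmda_in = np.empty(n_in)
    g_gaba_in = np.empty(n_in)
    g_ampa_tc = np.empty(n_tc)
    g_gaba_tc = np.empty(n_tc)
    g_gabab_tc = np.empty(n_tc)
    g_ampa_re = np.empty(n_re)
    g_gaba_re = np.empty(n_re)
    tmp_post = np.empty(max(max(n_py, n_in), max(n_tc, n_re)))
    sgb = np.empty(n_re)
    i_inj_py = np.zeros(n_py)
    i_inj_in = np.zeros(n_in)
    i_inj_tc = np.zeros(n_tc)
    i_inj_re = np.zeros(n_re)

    dep_rec = 1.0 - math.exp(-dt / dep_tau)
    f_ampa = math.exp(-_AM_B * dt)
    f_nmda = math.exp(-_NM_B * dt)
    spk_n = spk_n_in
    cap = spk_t.shape[0]
    err_code, err_cell, err_time = 0, -1, -1.0
    im_prev = -1
    ga_b = _GA_B
    f_gabaa = math.exp(-ga_b * dt)
    n_ms_total = scal.shape[0]

    for step in range(n_steps):
        t = t_start + step * dt
        im = int(t)
        if im >= n_ms_total:
            im = n_ms_total - 1
        if im != im_prev:
            # per-ms bookkeeping: modulator-dependent rates, minis, recording
            ga_b = _GA_B / scal[im, 8]
            f_gabaa = math.exp(-ga_b * dt)
            tms = float(im)
            _mini_events(mpp_s, mpp_d, mpp_w, mpp_next, mpp_agg, t0_py,
                         tms, _Q_AMPA)
            _mini_events(mpi_s, mpi_d, mpi_w, mpi_next, mpi_agg, t0_py,
                         tms, _Q_AMPA)
            _mini_events(mip_s, mip_d, mip_w, mip_next, mip_agg, t0_in,
                         tms, _Q_GABA)
            # stimulation (nA per cell, inward positive)
            for i in range(n_py):
                i_inj_py[i] = stim[im, 0]
            for i in range(n_in):
                i_inj_in[i] = stim[im, 1]
            for i in range(n_tc):
                i_inj_tc[i] = stim[im, 2]
            for i in range(n_re):
                i_inj_re[i] = stim[im, 3]
            # recording + health check at 1 kHz
            r = im - int(t_start)
            if 0 <= r < rec_py.shape[0]:
                m = 0.0
                for i in range(n_py):
                    rec_py[r, i] = py[i, rec_col]
                    m += py[i, CX_VD]
                rec_mean[r, 0] = m / n_py
                m = 0.0
                for i in range(n_in):
                    m += inn[i, CX_VD]
                rec_mean[r, 1] = m / n_in
                m = 0.0
                for i in range(n_tc):
                    m += tc[i, TC_V]
                rec_mean[r, 2] = m / n_tc
                m = 0.0
                for i in range(n_re):
                    m += re[i, RE_V]
                rec_mean[r, 3] = m / n_re
                if not (math.isfinite(rec_mean[r, 0])
                        and math.isfinite(rec_mean[r, 2])
                        and math.isfinite(rec_mean[r, 3])):
                    for i in range(n_py):
                        if not math.isfinite(py[i, CX_VD]):
                            err_cell = i
                    err_code = 1
                    err_time = t
                    return spk_n, err_code, err_cell, err_time
            im_prev = im

        achpy, achtc, achre = scal[im, 0], scal[im, 1], scal[im, 2]
        lach, lgaba_cx, lgaba_th = scal[im, 3], scal[im, 4], scal[im, 5]
        shift, tonic = scal[im, 6], scal[im, 7]

        # --- synaptic conductance sums per target (uS) ---
        for i in range(n_py):
            val_py[i] = o_ampa_py[i] * dep_py[i]
        _gather(pp_ip, pp_s, pp_w, val_py, g_ampa_py, n_py)
        _gather(pi_ip, pi_s, pi_w, val_py, g_ampa_in, n_in)
        for i in range(n_py):
            val_py[i] = o_nmda_py[i] * dep_py[i]
        _gather(pp_ip, pp_s, pp_w, val_py, tmp_post, n_py)
        for j in range(n_py):
            g_nmda_py[j] = gvec[1] * tmp_post[j]
        _gather(pi_ip, pi_s, pi_w, val_py, tmp_post, n_in)
        for j in range(n_in):
            g_nmda_in[j] = gvec[3] * tmp_post[j]
        _gather(tp_ip, tp_s, tp_w, o_ampa_tc, tmp_post, n_py)
        for j in range(n_py):
            g_ampa_py[j] = (lach * (gvec[0] * g_ampa_py[j]
                                    + gvec[5] * tmp_post[j]
                                    + gvec[13] * mpp_agg[j]))
        _gather(ti_ip, ti_s, ti_w, o_ampa_tc, tmp_post, n_in)
        for j in range(n_in):
            g_ampa_in[j] = (gvec[2] * g_ampa_in[j] + gvec[14] * mpi_agg[j]
                            + lach * gvec[6] * tmp_post[j])
        _gather(ip_ip, ip_s, ip_w, o_gabaa_in, tmp_post, n_py)
        for j in range(n_py):
            g_gaba_py[j] = (lgaba_cx * gvec[4] * tmp_post[j]
                            + tonic * gvec[15] * mip_agg[j])
        for j in range(n_in):
            g_gaba_in[j] = 0.0
        _gather(pt_ip, pt_s, pt_w, o_ampa_py, tmp_post, n_tc)
        for j in range(n_tc):
            g_ampa_tc[j] = gvec[7] * tmp_post[j]
        _gather(rt_ip, rt_s, rt_w, o_gabaa_re, tmp_post, n_tc)
        for j in range(n_tc):
            g_gaba_tc[j] = lgaba_th * gvec[10] * tmp_post[j]
        for i in range(n_re):
            g4 = gb_g[i] ** 4
            sgb[i] = g4 / (g4 + _GBKD)
        _gather(rt_ip, rt_s, rt_w, sgb, tmp_post, n_tc)
        for j in range(n_tc):
            g_gabab_tc[j] = lgaba_th * gvec[11] * tmp_post[j]
        _gather(pr_ip, pr_s, pr_w, o_ampa_py, tmp_post, n_re)
        for j in range(n_re):
            g_ampa_re[j] = gvec[8] * tmp_post[j]
        _gather(tr_ip, tr_s, tr_w, o_ampa_tc, tmp_post, n_re)
        for j in range(n_re):
            g_ampa_re[j] += gvec[9] * tmp_post[j]
        _gather(rr_ip, rr_s, rr_w, o_gabaa_re, tmp_post, n_re)
        for j in range(n_re):
            g_gaba_re[j] = lgaba_th * gvec[12] * tmp_post[j]

        # --- membrane updates ---
        _update_cx(py, pyp, cx_tab, g_ampa_py, g_nmda_py, g_gaba_py,
                   i_inj_py, achpy, dt, n_py, nap_fac)
        _update_cx(inn, inp, cx_tab, g_ampa_in, g_nmda_in, g_gaba_in,
                   i_inj_in, achpy, dt, n_in, nap_fac)
        _update_tc(tc, tcp, tc_tab, g_ampa_tc, g_gaba_tc, g_gabab_tc,
                   i_inj_tc, achtc, shift, dt, n_tc)
        _update_re(re, rep, re_tab, g_ampa_re, g_gaba_re,
                   i_inj_re, achre, dt, n_re)

        # --- spike detection (somatic upward crossing of 0 mV) ---
        tn = t + dt
        for i in range(n_py):
            if py[i, CX_VS] >= 0.0 and tn - ls_py[i] > 2.0:
                ls_py[i] = tn
                pulse_py[i] = tn + _T_DUR
                dep_py[i] *= (1.0 - dep_u)
                t0_py[i] = tn
                if spk_n < cap:
                    spk_t[spk_n] = tn
                    spk_id[spk_n] = i
                    spk_n += 1
        for i in range(n_in):
            if inn[i, CX_VS] >= 0.0 and tn - ls_in[i] > 2.0:
                ls_in[i] = tn
                pulse_in[i] = tn + _T_DUR
                t0_in[i] = tn
                if spk_n < cap:
                    spk_t[spk_n] = tn
                    spk_id[spk_n] = n_py + i
                    spk_n += 1
        for i in range(n_tc):
            if tc[i, TC_V] >= 0.0 and tn - ls_tc[i] > 2.0:
                ls_tc[i] = tn
                pulse_tc[i] = tn + _T_DUR
                if spk_n < cap:
                    spk_t[spk_n] = tn
                    spk_id[spk_n] = n_py + n_in + i
                    spk_n += 1
        for i in range(n_re):
            if re[i, RE_V] >= 0.0 and tn - ls_re[i] > 2.0:
                ls_re[i] = tn
                pulse_re[i] = tn + _T_DUR
                if spk_n < cap:
                    spk_t[spk_n] = tn
                    spk_id[spk_n] = n_py + n_in + n_tc + i
                    spk_n += 1

        # --- synapse state updates ---
        oa_inf = _AM_A * _T_MAX / (_AM_A * _T_MAX + _AM_B)
        oa_fac = math.exp(-(_AM_A * _T_MAX + _AM_B) * dt)
        on_inf = _NM_A * _T_MAX / (_NM_A * _T_MAX + _NM_B)
        on_fac = math.exp(-(_NM_A * _T_MAX + _NM_B) * dt)
        og_inf = _GA_A * _T_MAX / (_GA_A * _T_MAX + ga_b)
        og_fac = math.exp(-(_GA_A * _T_MAX + ga_b) * dt)
        for i in range(n_py):
            if tn < pulse_py[i]:
                o_ampa_py[i] = oa_inf + (o_ampa_py[i] - oa_inf) * oa_fac
                o_nmda_py[i] = on_inf + (o_nmda_py[i] - on_inf) * on_fac
            else:
                o_ampa_py[i] *= f_ampa
                o_nmda_py[i] *= f_nmda
            dep_py[i] += (1.0 - dep_py[i]) * dep_rec
        for i in range(n_in):
            if tn < pulse_in[i]:
                o_gabaa_in[i] = og_inf + (o_gabaa_in[i] - og_inf) * og_fac
            else:
                o_gabaa_in[i] *= f_gabaa
        for i in range(n_tc):
            if tn < pulse_tc[i]:
                o_ampa_tc[i] = oa_inf + (o_ampa_tc[i] - oa_inf) * oa_fac
            else:
                o_ampa_tc[i] *= f_ampa
        for i in range(n_re):
            if tn < pulse_re[i]:
                o_gabaa_re[i] = og_inf + (o_gabaa_re[i] - og_inf) * og_fac
                tr_conc = _T_MAX
            else:
                o_gabaa_re[i] *= f_gabaa
                tr_conc = 0.0
            r = gb_r[i]
            gb_r[i] = r + dt * (_GBK1 * tr_conc * (1.0 - r) - _GBK2 * r)
            gb_g[i] += dt * (_GBK3 * r - _GBK4 * gb_g[i])
        # mini aggregate decay
        for j in range(n_py):
            mpp_agg[j] *= f_ampa
            mip_agg[j] *= f_gabaa
        for j in range(n_in):
            mpi_agg[j] *= f_ampa

    return spk_n, err_code, err_cell, err_time


@njit(cache=True)
def _mini_events(src, dst, w, next_cand, agg, t0, tms, q):
    """Release miniature PSPs due in the last 1 ms (thinning sampler)."""
    n = src.shape[0]
    for e in range(n):
        while next_cand[e] <= tms:
            tc_ = next_cand[e]
            if tc_ > tms - 1.0:
                delta = tc_ - t0[src[e]]
                if delta < 0.0:
                    delta = 0.0
                rate = (2.0 / (1.0 + math.exp(-delta / _MINI_TAU)) - 1.0) \
                    * _MINI_MAX
                if np.random.random() < rate / _MINI_MAX:
                    agg[dst[e]] += q * w[e]
            next_cand[e] += np.random.exponential(1.0 / _MINI_MAX)
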