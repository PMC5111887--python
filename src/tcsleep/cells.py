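"""Ionic-current kinetics and single-cell dynamics for PY, IN, TC and RE cells.

Cortical pyramidal (PY) and inhibitory (IN) neurons are reduced two-compartment
models: an active dendrite integrating synaptic input and a zero-capacitance
axo-somatic compartment whose voltage satisfies the algebraic current balance

    g_cs (Vd - Vs) = -(I_Na,s + I_K,s + I_Nap,s).

Thalamic relay (TC) and reticular (RE) neurons are single compartments.  The
relay cell carries a calcium-gated h-current whose voltage activation curve is
shifted by the histamine level (``shift_ha``, mV).

The rate functions below are ``numba.njit``-compiled scalars so that the exact
same code is executed by the vectorised network kernel and by the plain-Python
reference paths used in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import constants as C

__all__ = [
    "h_inf", "ih_tau_s", "ChannelKinetics", "CorticalCellParams",
    "ThalamicCellParams", "IhParams", "CellState", "cell_derivatives",
    "ih_kinetics_step", "calcium_step", "cx_param_vector",
    "tc_param_vector", "re_param_vector",
]

# ---------------------------------------------------------------------------
# Elementary rate helpers
# ---------------------------------------------------------------------------


@njit(cache=True)
def _vtrap(x, y):
    """x / (exp(x/y) - 1), continuous through x = 0 (limit y - x/2)."""
    r = x / y
    if abs(r) < 1e-6:
        return y * (1.0 - r / 2.0)
    return x / (math.expm1(r))


@njit(cache=True)
def h_inf(v, shift):
    """Steady-state activation of the h-current.

    h_inf(V) = 1 / (1 + exp((V + 75 + shift)/5.5)).  ``shift`` (mV) encodes
    the histamine level; a more negative shift moves the half-activation
    voltage (-75 - shift) toward depolarised values, strengthening Ih at rest.
    Strictly decreasing in both V and shift.
    """
    return 1.0 / (1.0 + math.exp((v + 75.0 + shift) / 5.5))


@njit(cache=True)
def ih_tau_s(v):
    """Voltage-gating time constant of the h-current (ms, 36 C)."""
    return 20.0 + 1000.0 / (math.exp((v + 71.5) / 14.2)
                            + math.exp(-(v + 89.0) / 11.6))


# --- Traub-type spike currents (rates at shifted voltage v2 = v - vtr) -----

@njit(cache=True)
def na_rates(v, vtr):
    v2 = v - vtr
    am = 0.32 * _vtrap(13.0 - v2, 4.0)
    bm = 0.28 * _vtrap(v2 - 40.0, 5.0)
    ah = 0.128 * math.exp((17.0 - v2) / 18.0)
    bh = 4.0 / (1.0 + math.exp((40.0 - v2) / 5.0))
    return am, bm, ah, bh


@njit(cache=True)
def k_rates(v, vtr):
    v2 = v - vtr
    an = 0.032 * _vtrap(15.0 - v2, 5.0)
    bn = 0.5 * math.exp((10.0 - v2) / 40.0)
    return an, bn


@njit(cache=True)
def nap_m_inf(v):
    """Persistent Na+ activation (tau = NAP_TAU).

    Sigmoid fit after Alzheimer et al. (1993) as used in the prior-model
    lineage: the activation saturates at 0.02, so the printed maximal
    conductances (2.0 dendritic, 15 somatic mS/cm^2) yield effective peak
    densities of 0.04 and 0.3 mS/cm^2.
    """
    return 0.02 / (1.0 + math.exp(-(v + 42.0) / 5.0))


@njit(cache=True)
def _ratio_pos(x):
    """x / (1 - exp(-x/9)), continuous through 0 (limit 9 + x/2)."""
    if abs(x) < 1e-5:
        return 9.0 + x / 2.0
    return x / (1.0 - math.exp(-x / 9.0))


@njit(cache=True)
def _ratio_neg(x):
    """-x / (1 - exp(x/9)), continuous through 0 (limit 9 - x/2)."""
    if abs(x) < 1e-5:
        return 9.0 - x / 2.0
    return -x / (1.0 - math.exp(x / 9.0))


@njit(cache=True)
def km_rates(v):
    """Slow non-inactivating K+ (M) current rates, Mainen & Sejnowski form."""
    x = v + 30.0
    return 0.001 * _ratio_pos(x), 0.001 * _ratio_neg(x)


@njit(cache=True)
def hva_rates(v):
    """High-voltage-activated Ca2+ current (m^2 h), Reuveni et al. (1993).

    Activation is shifted 12 mV hyperpolarised relative to the published
    fit so that the reduced dendrite supports the Ca-spike burst firing
    characteristic of this cell class.
    """
    vm = v + 12.0
    am = 0.055 * _vtrap(-27.0 - vm, 3.8)
    bm = 0.94 * math.exp((-75.0 - vm) / 17.0)
    ah = 0.000457 * math.exp((-13.0 - v) / 50.0)
    bh = 0.0065 / (math.exp((-15.0 - v) / 28.0) + 1.0)
    return am, bm, ah, bh


@njit(cache=True)
def kca_rates(ca):
    a = C.KCA_ALPHA * ca * ca
    return a, C.KCA_BETA


# --- T-type Ca2+ currents ---------------------------------------------------

_PHI_M_T = 6.9    # Q10=5, 24->36 C
_PHI_H_T = 3.73   # Q10=3, 24->36 C


@njit(cache=True)
def tc_t_gates(v):
    """Relay-cell T current: (m_inf, tau_m, h_inf, tau_h) at 36 C."""
    minf = 1.0 / (1.0 + math.exp(-(v + 59.0) / 6.2))
    hinf = 1.0 / (1.0 + math.exp((v + 85.0) / 4.0))
    taum = (0.612 + 1.0 / (math.exp(-(v + 131.6) / 16.7)
                           + math.exp((v + 16.8) / 18.2))) / _PHI_M_T
    if v < -80.0:
        tauh = math.exp((v + 467.0) / 66.6) / _PHI_H_T
    else:
        tauh = (28.0 + math.exp(-(v + 21.88) / 10.52)) / _PHI_H_T
    return minf, taum, hinf, tauh


@njit(cache=True)
def re_t_gates(v):
    """Reticular-cell T current: (m_inf, tau_m, h_inf, tau_h) at 36 C."""
    minf = 1.0 / (1.0 + math.exp(-(v + 52.0) / 7.4))
    hinf = 1.0 / (1.0 + math.exp((v + 84.0) / 5.0))
    taum = 0.44 + 0.15 / (math.exp((v + 27.0) / 10.0)
                          + math.exp(-(v + 102.0) / 15.0))
    tauh = 22.7 + 0.27 / (math.exp((v + 48.0) / 4.0)
                          + math.exp(-(v + 407.0) / 50.0))
    return minf, taum, hinf, tauh


@njit(cache=True)
def e_ca(ca):
    """Ca2+ Nernst potential (mV) for extracellular CA_O."""
    if ca < 1e-8:
        ca = 1e-8
    return C.RT_2F * math.log(C.CA_O / ca)


# ---------------------------------------------------------------------------
# State-vector layouts shared with the network kernel
# ---------------------------------------------------------------------------
# Cortical (PY/IN), 14 slots
CX_VD, CX_VS, CX_MNA_D, CX_HNA_D, CX_MNAP_D, CX_MCA, CX_HCA, CX_MKCA, \
    CX_MKM, CX_CA, CX_MNA_S, CX_HNA_S, CX_NK_S, CX_MNAP_S = range(14)
NCX_STATE = 14
# Relay (TC), 10 slots
TC_V, TC_MNA, TC_HNA, TC_NK, TC_MT, TC_HT, TC_CA, TC_O, TC_P1, TC_OL = range(10)
NTC_STATE = 10
# Reticular (RE), 7 slots
RE_V, RE_MNA, RE_HNA, RE_NK, RE_MT, RE_HT, RE_CA = range(7)
NRE_STATE = 7

CX_STATE_NAMES = ["Vd", "Vs", "mNa_d", "hNa_d", "mNap_d", "mCaHVA", "hCaHVA",
                  "mKCa", "mKm", "Ca", "mNa_s", "hNa_s", "nK_s", "mNap_s"]
TC_STATE_NAMES = ["V", "mNa", "hNa", "nK", "mT", "hT", "Ca", "O", "P1", "OL"]
RE_STATE_NAMES = ["V", "mNa", "hNa", "nK", "mT", "hT", "Ca"]

_GATE_SLOTS = {
    "PY": [i for i in range(NCX_STATE) if i not in (CX_VD, CX_VS, CX_CA)],
    "IN": [i for i in range(NCX_STATE) if i not in (CX_VD, CX_VS, CX_CA)],
    "TC": [i for i in range(NTC_STATE) if i not in (TC_V, TC_CA)],
    "RE": [i for i in range(NRE_STATE) if i not in (RE_V, RE_CA)],
}
STATE_NAMES = {"PY": CX_STATE_NAMES, "IN": CX_STATE_NAMES,
               "TC": TC_STATE_NAMES, "RE": RE_STATE_NAMES}


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ChannelKinetics:
    """A single current: density, reversal, and an optional Q10 factor."""
    g_max: float            # mS/cm^2
    e_rev: float            # mV
    q10: float = 1.0

    def __post_init__(self):
        if self.g_max < 0:
            raise ValueError("maximal conductance must be >= 0")


@dataclass
class IhParams:
    """Calcium-gated h-current of the relay cell."""
    g_h: float = C.TC["g_h"]
    e_h: float = C.E_H
    k: float = C.IH["k"]            # weight of the Ca-locked open state
    k1: float = C.IH_K1
    k2: float = C.IH["k2"]
    k3: float = C.IH["k3"]
    k4: float = C.IH["k4"]
    v_half_offset: float = C.IH["v_half"]
    slope: float = C.IH["slope"]
    shift_ha: float = 0.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        for name in ("k1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CorticalCellParams:
    """Two-compartment cortical cell (PY or IN)."""
    kind: str = "PY"
    cm: float = C.CM_CX
    g_kl: float = C.PY["g_kl"]
    g_cl: float = C.PY["g_cl"]
    e_cl: float = C.E_CL_CX
    g_na_d: float = C.PY["g_na_d"]
    g_nap_d: float = C.PY["g_nap_d"]
    g_ca_d: float = C.PY["g_ca_d"]
    g_kca_d: float = C.PY["g_kca_d"]
    g_km_d: float = C.PY["g_km_d"]
    g_na_s: float = C.PY["g_na_s"]
    g_k_s: float = C.PY["g_k_s"]
    g_nap_s: float = C.PY["g_nap_s"]
    s_soma: float = C.S_CX_SOMA
    rho: float = C.RHO_PY
    g_cs: float = C.G_CS_US     # coupling conductance between compartments, uS
    ca_tau: float = C.CA_TAU_CX  # dendritic Ca pool decay (ms)
    extended: bool = False      # ACh also scales gKCa, gKm, gNap

    @classmethod
    def interneuron(cls) -> "CorticalCellParams":
        return cls(kind="IN", g_kl=C.IN["g_kl"], g_cl=C.IN["g_cl"],
                   g_nap_d=0.0, g_na_s=C.IN["g_na_s"], g_nap_s=0.0,
                   rho=C.RHO_IN)

    @property
    def s_dend(self) -> float:
        return self.s_soma * self.rho

    def __post_init__(self):
        if self.cm <= 0 or self.g_cs <= 0:
            raise ValueError("Cm and g_cs must be > 0")
        for name in ("g_kl", "g_cl", "g_na_d", "g_nap_d", "g_ca_d",
                     "g_kca_d", "g_km_d", "g_na_s", "g_k_s", "g_nap_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ThalamicCellParams:
    """Single-compartment thalamic cell (TC or RE)."""
    kind: str = "TC"
    cm: float = C.CM_TH
    area: float = C.S_TC
    g_leak: float = C.TC["g_leak"]
    e_leak: float = C.E_LEAK_TC
    g_kl: float = C.TC["g_kl"]
    g_na: float = C.TC["g_na"]
    g_k: float = C.TC["g_k"]
    g_t: float = C.TC["g_t"]
    ih: IhParams | None = field(default_factory=IhParams)

    @classmethod
    def reticular(cls) -> "ThalamicCellParams":
        return cls(kind="RE", area=C.S_RE, g_leak=C.RE["g_leak"],
                   e_leak=C.E_LEAK_RE, g_kl=C.RE["g_kl"], g_na=C.RE["g_na"],
                   g_k=C.RE["g_k"], g_t=C.RE["g_t"], ih=None)

    def __post_init__(self):
        for name in ("g_leak", "g_kl", "g_na", "g_k", "g_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kind == "RE":
            self.ih = None
        elif self.ih is None:
            self.ih = IhParams()


@dataclass
class CellState:
    """Flat state vector for one cell, with named access.

    ``vec`` follows the layout constants of this module (CX_*, TC_*, RE_*).
    """
    kind: str
    vec: np.ndarray

    @classmethod
    def resting(cls, kind: str) -> "CellState":
        vec = resting_state(kind)
        return cls(kind=kind, vec=vec)

    def __getitem__(self, name: str) -> float:
        return float(self.vec[STATE_NAMES[self.kind].index(name)])

    def validate(self) -> None:
        names = STATE_NAMES[self.kind]
        for i, x in enumerate(self.vec):
            if not np.isfinite(x):
                raise ValueError(f"non-finite state variable {names[i]!r}")
        for i in _GATE_SLOTS[self.kind]:
            if not (0.0 <= self.vec[i] <= 1.0):
                raise ValueError(f"gating variable {names[i]!r} outside [0,1]")
        if self.kind == "TC" and self.vec[TC_O] + self.vec[TC_OL] > 1.0 + 1e-9:
            raise ValueError("Ih open fractions O + OL exceed 1")
        ca = self.vec[TC_CA if self.kind == "TC" else
                      RE_CA if self.kind == "RE" else CX_CA]
        if ca < 0:
            raise ValueError("Ca must be >= 0")


def resting_state(kind: str, v: float = -68.0) -> np.ndarray:
    """Initial state: all gates at steady state for voltage ``v``."""
    if kind in ("PY", "IN"):
        s = np.zeros(NCX_STATE)
        s[CX_VD] = s[CX_VS] = v
        am, bm, ah, bh = na_rates(v, C.VTR_CX)
        s[CX_MNA_D], s[CX_HNA_D] = am / (am + bm), ah / (ah + bh)
        s[CX_MNA_S], s[CX_HNA_S] = am / (am + bm), ah / (ah + bh)
        an, bn = k_rates(v, C.VTR_CX)
        s[CX_NK_S] = an / (an + bn)
        s[CX_MNAP_D] = s[CX_MNAP_S] = nap_m_inf(v)
        am, bm, ah, bh = hva_rates(v)
        s[CX_MCA], s[CX_HCA] = am / (am + bm), ah / (ah + bh)
        a, b = kca_rates(C.CA_INF)
        s[CX_MKCA] = a / (a + b)
        a, b = km_rates(v)
        s[CX_MKM] = a / (a + b)
        s[CX_CA] = C.CA_INF
        return s
    if kind == "TC":
        s = np.zeros(NTC_STATE)
        s[TC_V] = v
        am, bm, ah, bh = na_rates(v, C.VTR_TC)
        s[TC_MNA], s[TC_HNA] = am / (am + bm), ah / (ah + bh)
        an, bn = k_rates(v, C.VTR_TC)
        s[TC_NK] = an / (an + bn)
        minf, _, hinf, _ = tc_t_gates(v)
        s[TC_MT], s[TC_HT] = minf, hinf
        s[TC_CA] = C.CA_INF
        s[TC_O] = h_inf(v, 0.0)
        s[TC_P1] = 0.0
        s[TC_OL] = 0.0
        return s
    if kind == "RE":
        s = np.zeros(NRE_STATE)
        s[RE_V] = v
        am, bm, ah, bh = na_rates(v, C.VTR_RE)
        s[RE_MNA], s[RE_HNA] = am / (am + bm), ah / (ah + bh)
        an, bn = k_rates(v, C.VTR_RE)
        s[RE_NK] = an / (an + bn)
        minf, _, hinf, _ = re_t_gates(v)
        s[RE_MT], s[RE_HT] = minf, hinf
        s[RE_CA] = C.CA_INF
        return s
    raise ValueError(f"unknown cell kind {kind!r}")


# ---------------------------------------------------------------------------
# Reference derivative evaluation (plain Python; mirrors the network kernel)
# ---------------------------------------------------------------------------


def solve_vs(vd: float, s: np.ndarray, p: CorticalCellParams) -> float:
    """Somatic voltage from the zero-capacitance algebraic balance.

    With gating variables held fixed, every somatic current is linear in Vs,
    so g_cs(Vd - Vs) = -(I_Na,s + I_K,s + I_Nap,s) has the closed-form root

        Vs = (g_cs Vd + sum_i g_i E_i) / (g_cs + sum_i g_i).
    """
    g_cs = p.g_cs / p.s_soma * 1e-3          # uS -> mS/cm^2 of soma
    g_na = p.g_na_s * s[CX_MNA_S] ** 3 * s[CX_HNA_S]
    g_k = p.g_k_s * s[CX_NK_S] ** 2
    g_nap = p.g_nap_s * s[CX_MNAP_S]
    num = g_cs * vd + g_na * C.E_NA + g_k * C.E_K + g_nap * C.E_NA
    den = g_cs + g_na + g_k + g_nap
    return num / den


def cell_derivatives(kind: str, state: CellState | np.ndarray, params=None,
                     modulators=None, i_syn_nA: float = 0.0) -> np.ndarray:
    """Time derivatives of the full state vector (algebraic Vs slot -> value).

    ``modulators`` supplies the cell-type ACh scalar (K+-leak multiplier) and,
    for TC cells, the histamine shift of the h-current activation curve.
    ``i_syn_nA`` is the total synaptic (+ injected) current in nA, positive
    outward.  For cortical kinds the returned vector carries dVs/dt = 0 and
    the solved somatic voltage is written back into the state copy used; use
    :func:`solve_vs` to obtain it explicitly.
    """
    if isinstance(state, CellState):
        state.validate()
        s = state.vec
    else:
        s = np.asarray(state, dtype=float)
        if not np.all(np.isfinite(s)):
            names = STATE_NAMES[kind]
            bad = names[int(np.flatnonzero(~np.isfinite(s))[0])]
            raise ValueError(f"non-finite state variable {bad!r}")
    mods = dict(ach_scale=1.0, shift_ha=0.0)
    if modulators:
        mods.update(modulators)
    if mods["ach_scale"] <= 0:
        raise ValueError("modulator scalars must be > 0")

    d = np.zeros_like(s)
    if kind in ("PY", "IN"):
        p = params or (CorticalCellParams() if kind == "PY"
                       else CorticalCellParams.interneuron())
        vd = s[CX_VD]
        vs = solve_vs(vd, s, p)
        ext = 1.0 if not p.extended else mods["ach_scale"]
        # dendritic currents (uA/cm^2, outward positive)
        i_kl = mods["ach_scale"] * p.g_kl * (vd - C.E_K)
        i_cl = p.g_cl * (vd - p.e_cl)
        i_na = p.g_na_d * s[CX_MNA_D] ** 3 * s[CX_HNA_D] * (vd - C.E_NA)
        i_nap = ext * p.g_nap_d * s[CX_MNAP_D] * (vd - C.E_NA)
        eca = e_ca(s[CX_CA])
        i_ca = p.g_ca_d * s[CX_MCA] ** 2 * s[CX_HCA] * (vd - eca)
        i_kca = ext * p.g_kca_d * s[CX_MKCA] * (vd - C.E_K)
        i_km = ext * p.g_km_d * s[CX_MKM] * (vd - C.E_K)
        i_cpl = p.g_cs * (vd - vs) / p.s_dend * 1e-3  # uS*mV -> uA/cm^2
        i_syn = i_syn_nA * 1e-3 / p.s_dend
        d[CX_VD] = -(i_kl + i_cl + i_na + i_nap + i_ca + i_kca + i_km
                     + i_cpl + i_syn) / p.cm
        # dendritic gates
        am, bm, ah, bh = na_rates(vd, C.VTR_CX)
        d[CX_MNA_D] = am * (1 - s[CX_MNA_D]) - bm * s[CX_MNA_D]
        d[CX_HNA_D] = ah * (1 - s[CX_HNA_D]) - bh * s[CX_HNA_D]
        d[CX_MNAP_D] = (nap_m_inf(vd) - s[CX_MNAP_D]) / C.NAP_TAU
        am, bm, ah, bh = hva_rates(vd)
        d[CX_MCA] = am * (1 - s[CX_MCA]) - bm * s[CX_MCA]
        d[CX_HCA] = ah * (1 - s[CX_HCA]) - bh * s[CX_HCA]
        a, b = kca_rates(s[CX_CA])
        d[CX_MKCA] = a * (1 - s[CX_MKCA]) - b * s[CX_MKCA]
        a, b = km_rates(vd)
        d[CX_MKM] = a * (1 - s[CX_MKM]) - b * s[CX_MKM]
        d[CX_CA] = calcium_derivative(s[CX_CA], i_ca, tau=p.ca_tau,
                                      depth=C.CA_D_CX)
        # somatic gates relax at the solved somatic voltage
        am, bm, ah, bh = na_rates(vs, C.VTR_CX)
        d[CX_MNA_S] = am * (1 - s[CX_MNA_S]) - bm * s[CX_MNA_S]
        d[CX_HNA_S] = ah * (1 - s[CX_HNA_S]) - bh * s[CX_HNA_S]
        an, bn = k_rates(vs, C.VTR_CX)
        d[CX_NK_S] = an * (1 - s[CX_NK_S]) - bn * s[CX_NK_S]
        d[CX_MNAP_S] = (nap_m_inf(vs) - s[CX_MNAP_S]) / C.NAP_TAU
        return d

    if kind == "TC":
        p = params or ThalamicCellParams()
        v = s[TC_V]
        i_kl = mods["ach_scale"] * p.g_kl * (v - C.E_K)
        i_leak = p.g_leak * (v - p.e_leak)
        i_na = p.g_na * s[TC_MNA] ** 3 * s[TC_HNA] * (v - C.E_NA)
        i_k = p.g_k * s[TC_NK] ** 4 * (v - C.E_K)
        i_t = p.g_t * s[TC_MT] ** 2 * s[TC_HT] * (v - e_ca(s[TC_CA]))
        ih = p.ih
        i_h = ih.g_h * (s[TC_O] + ih.k * s[TC_OL]) * (v - ih.e_h)
        i_syn = i_syn_nA * 1e-3 / p.area
        d[TC_V] = -(i_kl + i_leak + i_na + i_k + i_t + i_h + i_syn) / p.cm
        am, bm, ah, bh = na_rates(v, C.VTR_TC)
        d[TC_MNA] = am * (1 - s[TC_MNA]) - bm * s[TC_MNA]
        d[TC_HNA] = ah * (1 - s[TC_HNA]) - bh * s[TC_HNA]
        an, bn = k_rates(v, C.VTR_TC)
        d[TC_NK] = an * (1 - s[TC_NK]) - bn * s[TC_NK]
        minf, taum, hinf, tauh = tc_t_gates(v)
        d[TC_MT] = (minf - s[TC_MT]) / taum
        d[TC_HT] = (hinf - s[TC_HT]) / tauh
        d[TC_CA] = calcium_derivative(s[TC_CA], i_t, tau=C.CA_TAU_TH)
        do, dp1, dol = ih_derivatives(s[TC_O], s[TC_P1], s[TC_OL],
                                      s[TC_CA], v, ih)
        d[TC_O], d[TC_P1], d[TC_OL] = do, dp1, dol
        return d

    if kind == "RE":
        p = params or ThalamicCellParams.reticular()
        v = s[RE_V]
        i_kl = mods["ach_scale"] * p.g_kl * (v - C.E_K)
        i_leak = p.g_leak * (v - p.e_leak)
        i_na = p.g_na * s[RE_MNA] ** 3 * s[RE_HNA] * (v - C.E_NA)
        i_k = p.g_k * s[RE_NK] ** 4 * (v - C.E_K)
        i_t = p.g_t * s[RE_MT] ** 2 * s[RE_HT] * (v - e_ca(s[RE_CA]))
        i_syn = i_syn_nA * 1e-3 / p.area
        d[RE_V] = -(i_kl + i_leak + i_na + i_k + i_t + i_syn) / p.cm
        am, bm, ah, bh = na_rates(v, C.VTR_RE)
        d[RE_MNA] = am * (1 - s[RE_MNA]) - bm * s[RE_MNA]
        d[RE_HNA] = ah * (1 - s[RE_HNA]) - bh * s[RE_HNA]
        an, bn = k_rates(v, C.VTR_RE)
        d[RE_NK] = an * (1 - s[RE_NK]) - bn * s[RE_NK]
        minf, taum, hinf, tauh = re_t_gates(v)
        d[RE_MT] = (minf - s[RE_MT]) / taum
        d[RE_HT] = (hinf - s[RE_HT]) / tauh
        d[RE_CA] = calcium_derivative(s[RE_CA], i_t, tau=C.CA_TAU_TH)
        return d

    raise ValueError(f"unknown cell kind {kind!r}")


# ---------------------------------------------------------------------------
# h-current kinetics and the calcium pool
# ---------------------------------------------------------------------------


def ih_derivatives(o, p1, ol, ca, v, ih: IhParams):
    """Derivatives of the five-state Ca-gated h-current scheme.

    C <-> O with voltage rates alpha = h_inf/tau_s, beta = (1-h_inf)/tau_s;
    the Ca sensor P0 + 4Ca <-> P1 (rates k1*Ca^4, k2); binding of P1 locks the
    open channel, O + P1 <-> OL (rates k3, k4).  C = 1 - O - OL.
    """
    hi = h_inf(v, ih.shift_ha)
    ts = ih_tau_s(v)
    alpha, beta = hi / ts, (1.0 - hi) / ts
    c = 1.0 - o - ol
    do = alpha * c - beta * o - ih.k3 * o * p1 + ih.k4 * ol
    dp1 = ih.k1 * ca ** 4 * (1.0 - p1) - ih.k2 * p1
    dol = ih.k3 * o * p1 - ih.k4 * ol
    return do, dp1, dol


def ih_kinetics_step(o, p1, ol, ca, v, ih: IhParams, dt: float):
    """Advance the h-current state one explicit step; fractions stay in [0,1]."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    for name, x in (("O", o), ("P1", p1), ("OL", ol)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"Ih fraction {name} outside [0,1]")
    do, dp1, dol = ih_derivatives(o, p1, ol, ca, v, ih)
    o = min(max(o + dt * do, 0.0), 1.0)
    p1 = min(max(p1 + dt * dp1, 0.0), 1.0)
    ol = min(max(ol + dt * dol, 0.0), 1.0 - o)
    return o, p1, ol


def calcium_derivative(ca, i_ca, tau=C.CA_TAU_TH, a=C.CA_A, depth=C.CA_D,
                       floor=C.CA_INF):
    """First-order Ca pool: influx from inward Ca current, decay to floor."""
    influx = -a * i_ca / depth if i_ca < 0.0 else 0.0
    return influx + (floor - ca) / tau


def calcium_step(ca, i_ca, dt, **kw):
    """One explicit step of the Ca pool; never goes negative."""
    if ca < 0:
        raise ValueError("Ca must be >= 0")
    return max(ca + dt * calcium_derivative(ca, i_ca, **kw), 0.0)


# ---------------------------------------------------------------------------
# Packed parameter vectors consumed by the network kernel
# ---------------------------------------------------------------------------

# index constants for the packed vectors
CXP = dict(G_KL=0, G_CL=1, E_CL=2, G_NA_D=3, G_NAP_D=4, G_CA_D=5, G_KCA_D=6,
           G_KM_D=7, G_NA_S=8, G_K_S=9, G_NAP_S=10, CM=11, S_DEND=12,
           S_SOMA=13, G_CS=14, EXTENDED=15, CA_TAU=16)
THP = dict(G_LEAK=0, E_LEAK=1, G_KL=2, G_NA=3, G_K=4, G_T=5, G_H=6, CM=7,
           AREA=8, IH_K=9, IH_K1=10, IH_K2=11, IH_K3=12, IH_K4=13, E_H=14)


def cx_param_vector(p: CorticalCellParams) -> np.ndarray:
    v = np.zeros(17)
    v[CXP["CA_TAU"]] = p.ca_tau
    v[CXP["G_KL"]], v[CXP["G_CL"]], v[CXP["E_CL"]] = p.g_kl, p.g_cl, p.e_cl
    v[CXP["G_NA_D"]], v[CXP["G_NAP_D"]] = p.g_na_d, p.g_nap_d
    v[CXP["G_CA_D"]], v[CXP["G_KCA_D"]], v[CXP["G_KM_D"]] = \
        p.g_ca_d, p.g_kca_d, p.g_km_d
    v[CXP["G_NA_S"]], v[CXP["G_K_S"]], v[CXP["G_NAP_S"]] = \
        p.g_na_s, p.g_k_s, p.g_nap_s
    v[CXP["CM"]], v[CXP["S_DEND"]], v[CXP["S_SOMA"]] = p.cm, p.s_dend, p.s_soma
    v[CXP["G_CS"]] = p.g_cs
    v[CXP["EXTENDED"]] = 1.0 if p.extended else 0.0
    return v


def tc_param_vector(p: ThalamicCellParams) -> np.ndarray:
    ih = p.ih or IhParams(g_h=0.0)
    v = np.zeros(15)
    v[THP["G_LEAK"]], v[THP["E_LEAK"]], v[THP["G_KL"]] = \
        p.g_leak, p.e_leak, p.g_kl
    v[THP["G_NA"]], v[THP["G_K"]], v[THP["G_T"]] = p.g_na, p.g_k, p.g_t
    v[THP["G_H"]] = ih.g_h if p.ih is not None else 0.0
    v[THP["CM"]], v[THP["AREA"]] = p.cm, p.area
    v[THP["IH_K"]], v[THP["IH_K1"]], v[THP["IH_K2"]] = ih.k, ih.k1, ih.k2
    v[THP["IH_K3"]], v[THP["IH_K4"]], v[THP["E_H"]] = ih.k3, ih.k4, ih.e_h
    return v


def re_param_vector(p: ThalamicCellParams) -> np.ndarray:
    return tc_param_vector(p)
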