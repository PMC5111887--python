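"""Kinetic synapse models: AMPA, NMDA, GABA-A, GABA-B, miniature PSPs and
short-term depression.

Evoked transmission follows first-order activation schemes: a presynaptic
spike releases a transmitter pulse of ``T_MAX`` mM for ``T_DUR`` ms and the
open fraction obeys dO/dt = alpha*T*(1-O) - beta*O.  GABA-B adds a
second-order G-protein cascade with a quartic activation nonlinearity.
Miniature PSPs (the model's only noise source) are Poisson events whose
hazard is suppressed after each presynaptic spike and recovers sigmoidally.

Sign convention: outward currents are positive; synaptic currents are
``L * g * E_dep * [O] * (V_post - E_rev)`` and enter the membrane equations
with a minus sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as C

__all__ = [
    "SynapseParams", "SynapseState", "MiniProcess", "synaptic_current",
    "mini_rate", "sample_mini_times", "open_fraction_step", "gabab_step",
    "depression_step", "mini_quantum",
]

_KINETICS = {
    "AMPA": (C.AMPA_ALPHA, C.AMPA_BETA, C.E_AMPA),
    "NMDA": (C.NMDA_ALPHA, C.NMDA_BETA, C.E_AMPA),
    "GABAA": (C.GABAA_ALPHA, C.GABAA_BETA, C.E_GABAA),
    "GABAB": (C.GABAB["k1"], C.GABAB["k2"], C.E_GABAB),
}


@dataclass
class SynapseParams:
    """Parameters of one synapse type on one projection."""
    type: str                      # AMPA | NMDA | GABAA | GABAB
    g_syn: float                   # maximal conductance (uS)
    e_rev: float | None = None     # reversal potential (mV)
    alpha: float | None = None     # opening rate (mM^-1 ms^-1)
    beta: float | None = None      # closing rate (ms^-1)
    decay_scale: float = 1.0       # GABA-A decay-time multiplier (propofol)
    depression_u: float = 0.0      # use fraction (0 = no depression)
    depression_tau: float = C.DEPRESSION_TAU

    def __post_init__(self):
        if self.type not in _KINETICS:
            raise ValueError(f"unknown synapse type {self.type!r}")
        if self.g_syn < 0:
            raise ValueError("g_syn must be >= 0")
        a, b, e = _KINETICS[self.type]
        self.alpha = a if self.alpha is None else self.alpha
        self.beta = b if self.beta is None else self.beta
        self.e_rev = e if self.e_rev is None else self.e_rev
        if self.decay_scale < 1.0:
            raise ValueError("decay_scale < 1 is not meaningful")

    @property
    def beta_eff(self) -> float:
        """Closing rate after the propofol decay-time scaling."""
        return self.beta / self.decay_scale


@dataclass
class SynapseState:
    """Dynamic state of one synapse."""
    open_fraction: float = 0.0     # [O]
    efficacy: float = 1.0          # short-term depression factor
    g_protein_r: float = 0.0       # GABA-B receptor fraction R
    g_protein: float = 0.0         # GABA-B G-protein concentration G
    t_last_spike: float = -1e9     # last presynaptic spike (ms)

    def validate(self):
        if not 0.0 <= self.open_fraction <= 1.0:
            raise ValueError("[O] outside [0,1]")
        if not 0.0 < self.efficacy <= 1.0:
            raise ValueError("efficacy outside (0,1]")


def synaptic_current(state: SynapseState, params: SynapseParams,
                     v_post: float, l_scale: float = 1.0) -> float:
    """Instantaneous synaptic current (nA, outward positive).

    current = L * g_syn * efficacy * [O] * (V_post - E_rev), with the NMDA
    magnesium-block sigmoid applied for NMDA synapses and the quartic
    G-protein activation G^4/(G^4+Kd) replacing [O] for GABA-B.
    """
    if l_scale <= 0:
        raise ValueError("L_scale must be > 0")
    if params.type == "GABAB":
        g4 = state.g_protein ** C.GABAB["n"]
        gate = g4 / (g4 + C.GABAB["kd"])
    else:
        gate = state.open_fraction
        if params.type == "NMDA":
            gate *= 1.0 / (1.0 + math.exp(-(v_post - C.NMDA_MG_V0)
                                          / C.NMDA_MG_SLOPE))
    return l_scale * params.g_syn * state.efficacy * gate \
        * (v_post - params.e_rev)


def open_fraction_step(o: float, pulse_on: bool, dt: float,
                       alpha: float, beta: float, t_conc: float = C.T_MAX):
    """Exact exponential update of the first-order open fraction over dt."""
    if pulse_on:
        k = alpha * t_conc + beta
        o_inf = alpha * t_conc / k
        return o_inf + (o - o_inf) * math.exp(-k * dt)
    return o * math.exp(-beta * dt)


def gabab_step(state: SynapseState, pulse_on: bool, dt: float) -> float:
    """Advance the GABA-B G-protein cascade one step.

    Returns the K+-channel activation s = G^4/(G^4 + Kd) in [0,1].  The slow
    cascade gives GABA-B its characteristic late peak relative to GABA-A.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    k1, k2, k3, k4 = (C.GABAB[k] for k in ("k1", "k2", "k3", "k4"))
    t = C.T_MAX if pulse_on else 0.0
    r = state.g_protein_r
    state.g_protein_r = r + dt * (k1 * t * (1.0 - r) - k2 * r)
    state.g_protein += dt * (k3 * r - k4 * state.g_protein)
    g4 = state.g_protein ** C.GABAB["n"]
    return g4 / (g4 + C.GABAB["kd"])


def depression_step(efficacy: float, spike: bool, dt: float,
                    u: float = C.DEPRESSION_U,
                    tau: float = C.DEPRESSION_TAU) -> float:
    """Short-term depression: multiplicative drop on a spike, recovery to 1."""
    if not 0.0 < efficacy <= 1.0:
        raise ValueError("efficacy outside (0,1]")
    efficacy = 1.0 - (1.0 - efficacy) * math.exp(-dt / tau)
    if spike:
        efficacy *= (1.0 - u)
    return efficacy


# ---------------------------------------------------------------------------
# Miniature PSPs
# ---------------------------------------------------------------------------


def mini_rate(delta_t):
    """Instantaneous mini release hazard (per ms) at ``delta_t`` ms after the
    last presynaptic spike: (2/(1+exp(-dt/20)) - 1)/250.

    Zero immediately after a spike, saturating at 1/250 per ms.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t < 0):
        raise ValueError("delta_t must be >= 0")
    r = (2.0 / (1.0 + np.exp(-delta_t / C.MINI_RATE_TAU)) - 1.0) \
        / (1.0 / C.MINI_RATE_MAX)
    return r if r.ndim else float(r)


def sample_mini_times(t_start: float, t_stop: float, t0: float,
                      rng: np.random.Generator) -> list[float]:
    """Release times in [t_start, t_stop) of one connection by thinning.

    ``t0`` is the last presynaptic spike time; candidates are drawn from a
    homogeneous process at the saturating bound 1/250 per ms and accepted
    with probability mini_rate(t - t0) / (1/250).
    """
    out = []
    t = t_start
    while True:
        t += rng.exponential(1.0 / C.MINI_RATE_MAX)
        if t >= t_stop:
            return out
        if rng.random() < mini_rate(max(t - t0, 0.0)) / C.MINI_RATE_MAX:
            out.append(t)


def mini_quantum(alpha: float = C.AMPA_ALPHA, beta: float = C.AMPA_BETA,
                 t_dur: float = C.MINI_T_DUR, t_conc: float = C.T_MAX) -> float:
    """Peak open fraction reached by a single transmitter pulse from O=0.

    Used as the quantal increment of the aggregated mini conductance in the
    network kernel (minis are modelled as jump-and-exponential-decay events).
    """
    k = alpha * t_conc + beta
    return alpha * t_conc / k * (1.0 - math.exp(-k * t_dur))


@dataclass
class MiniProcess:
    """Miniature-PSP generator for one connection."""
    g_mini: float                      # quantal conductance (uS)
    rng: np.random.Generator
    t0: float = -1e9                   # last presynaptic spike
    next_candidate: float = 0.0

    def step(self, t: float, dt: float) -> bool:
        """Advance to time t+dt; True if a mini is released in (t, t+dt]."""
        released = False
        while self.next_candidate <= t + dt:
            delta = max(self.next_candidate - self.t0, 0.0)
            if self.next_candidate > t and \
                    self.rng.random() < mini_rate(delta) / C.MINI_RATE_MAX:
                released = True
            self.next_candidate += self.rng.exponential(1.0 / C.MINI_RATE_MAX)
        return released

    def on_presynaptic_spike(self, t: float):
        self.t0 = t
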