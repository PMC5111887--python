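"""Neuromodulator levels -> model parameter scalars.

Three exogenous drives parameterise the model: acetylcholine (ACh), histamine
(HA) and GABA, each expressed as a percentage of the awake level.  They map to
eight concrete scalars:

* ``ach_py`` / ``ach_tc`` / ``ach_re`` - K+-leak conductance multipliers for
  cortical, relay and reticular cells (ACh REDUCTION increases the cortical
  and relay leak but decreases the reticular leak).
* ``l_ach`` - AMPA conductance multiplier on PY->PY, TC->PY and TC->IN.
* ``l_gaba`` - GABAergic conductance multiplier on IN->PY, RE->RE and RE->TC.
* ``shift_ha`` - shift (mV) of the h-current activation curve in relay cells.
* ``tonic_gaba_scale`` - miniature-IPSP conductance multiplier (tonic
  inhibition experiments).
* ``gaba_tau_scale`` - GABA-A decay-time multiplier (propofol experiments).

The four named stages reproduce the stage table exactly; arbitrary levels are
mapped by component-wise piecewise-linear interpolation through the four
stage anchors (linear extrapolation outside, within documented bounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["NeuromodulatorState", "StageSchedule", "stage_scalars",
           "continuous_scalars", "apply_modulators", "propofol_mode",
           "tonic_gaba_variant", "STAGES", "STAGE_LEVELS", "STAGE_TABLE"]

STAGES = ("awake", "N2", "N3", "REM")

# neuromodulator levels (% of awake) per named stage
STAGE_LEVELS = {
    "awake": dict(ach=100.0, ha=100.0, gaba=100.0),
    "N2": dict(ach=80.0, ha=40.0, gaba=115.0),
    "N3": dict(ach=50.0, ha=30.0, gaba=130.0),
    "REM": dict(ach=115.0, ha=10.0, gaba=75.0),
}

# scalar table per named stage (ach_tc N3 value 2.0 fills a gap in the
# printed table; see docs/methods.md)
STAGE_TABLE = {
    "awake": dict(ach_py=1.0, ach_tc=1.0, ach_re=1.0, l_ach=1.0,
                  l_gaba=1.0, shift_ha=-8.0),
    "N2": dict(ach_py=1.25, ach_tc=1.25, ach_re=0.8, l_ach=1.25,
               l_gaba=1.15, shift_ha=-3.0),
    "N3": dict(ach_py=1.8, ach_tc=2.0, ach_re=0.5, l_ach=2.0,
               l_gaba=1.3, shift_ha=-2.0),
    "REM": dict(ach_py=0.85, ach_tc=0.85, ach_re=1.15, l_ach=0.8,
                l_gaba=0.75, shift_ha=0.0),
}

# documented extrapolation bounds for continuous levels (%)
LEVEL_BOUNDS = {"ach": (0.0, 125.0), "ha": (0.0, 125.0), "gaba": (25.0, 225.0)}


@dataclass(frozen=True)
class NeuromodulatorState:
    """Neuromodulator levels plus every derived parameter scalar."""
    ach: float = 100.0
    ha: float = 100.0
    gaba: float = 100.0
    ach_py: float = 1.0
    ach_tc: float = 1.0
    ach_re: float = 1.0
    l_ach: float = 1.0
    l_gaba: float = 1.0
    shift_ha: float = -8.0
    tonic_gaba_scale: float = 1.0
    gaba_tau_scale: float = 1.0
    l_gaba_cx: float | None = None    # override for cortical IN->PY GABA-A
    l_gaba_th: float | None = None    # override for RE->RE / RE->TC GABA
    stage: str | None = None

    def __post_init__(self):
        for name in ("ach", "ha", "gaba"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} level must be > 0")

    def scalar_vector(self) -> np.ndarray:
        """Columns follow SCALAR_NAMES; the cortical and thalamic GABA
        scalars default to the shared ``l_gaba`` value."""
        lg_cx = self.l_gaba if self.l_gaba_cx is None else self.l_gaba_cx
        lg_th = self.l_gaba if self.l_gaba_th is None else self.l_gaba_th
        return np.array([self.ach_py, self.ach_tc, self.ach_re, self.l_ach,
                         lg_cx, lg_th, self.shift_ha, self.tonic_gaba_scale,
                         self.gaba_tau_scale])


SCALAR_NAMES = ("ach_py", "ach_tc", "ach_re", "l_ach", "l_gaba_cx",
                "l_gaba_th", "shift_ha", "tonic_gaba_scale",
                "gaba_tau_scale")


def stage_scalars(stage: str, ha_k_leak_gain: float = 0.0) -> NeuromodulatorState:
    """Scalars of a named stage (awake | N2 | N3 | REM), exactly per table."""
    if stage not in STAGE_TABLE:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    lv, tab = STAGE_LEVELS[stage], dict(STAGE_TABLE[stage])
    if ha_k_leak_gain:
        _apply_ha_k_leak(tab, lv["ha"], ha_k_leak_gain)
    return NeuromodulatorState(stage=stage, **lv, **tab)


def _pwl(x, xs, ys):
    """Piecewise-linear interpolation with linear extrapolation at both ends."""
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if x < xs[0]:
        return ys[0] + (x - xs[0]) * (ys[1] - ys[0]) / (xs[1] - xs[0])
    if x > xs[-1]:
        return ys[-1] + (x - xs[-1]) * (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    return float(np.interp(x, xs, ys))


def _anchors(level_name: str, scalar_name: str):
    pairs = sorted((STAGE_LEVELS[s][level_name], STAGE_TABLE[s][scalar_name])
                   for s in STAGES)
    return [p[0] for p in pairs], [p[1] for p in pairs]


def _apply_ha_k_leak(tab: dict, ha: float, gain: float):
    """Optional HA contribution to the K+-leak scale (off by default)."""
    f = 1.0 + gain * (1.0 - ha / 100.0)
    for key in ("ach_py", "ach_tc", "ach_re"):
        tab[key] *= f


def continuous_scalars(ach: float, ha: float, gaba: float,
                       ha_k_leak_gain: float = 0.0) -> NeuromodulatorState:
    """Scalars for arbitrary (ACh, HA, GABA) levels in % of awake.

    Each scalar interpolates its own controlling level through the four stage
    anchors: the K+-leak and AMPA scalars follow ACh, the h-current shift
    follows HA, and the GABA conductance scalar follows the GABA level.
    Monotone by construction (the anchor tables are monotone in level).
    """
    for name, x in (("ach", ach), ("ha", ha), ("gaba", gaba)):
        lo, hi = LEVEL_BOUNDS[name]
        if not lo <= x <= hi:
            raise ValueError(f"{name} level {x} outside bounds [{lo}, {hi}]")
    tab = {}
    for scalar in ("ach_py", "ach_tc", "ach_re", "l_ach"):
        tab[scalar] = _pwl(ach, *_anchors("ach", scalar))
    tab["shift_ha"] = _pwl(ha, *_anchors("ha", "shift_ha"))
    tab["l_gaba"] = _pwl(gaba, *_anchors("gaba", "l_gaba"))
    if ha_k_leak_gain:
        _apply_ha_k_leak(tab, ha, ha_k_leak_gain)
    stage = next((s for s in STAGES
                  if STAGE_LEVELS[s] == dict(ach=ach, ha=ha, gaba=gaba)), None)
    return NeuromodulatorState(ach=ach, ha=ha, gaba=gaba, stage=stage, **tab)


def propofol_mode(tau_increase: float = 150.0, combined: bool = True,
                  interpretation: str = "by") -> NeuromodulatorState:
    """Anesthesia mode: lengthened GABA-A IPSP decay, optionally with the
    ACh/HA reduction of natural cat SWS.

    ``tau_increase`` is a percentage.  ``interpretation`` selects between the
    two readings of "increased by X%": "by" -> tau x (1 + X/100) (default),
    "to" -> tau x (X/100).  ``combined=False`` keeps every neuromodulator at
    its awake value and scales only the decay time.
    """
    if tau_increase < 0:
        raise ValueError("tau_increase must be >= 0")
    if interpretation == "by":
        scale = 1.0 + tau_increase / 100.0
    elif interpretation == "to":
        scale = max(tau_increase / 100.0, 1.0)
    else:
        raise ValueError("interpretation must be 'by' or 'to'")
    if combined:
        # ACh reduced to 75% of awake (cat natural SWS), HA to the N3 level
        base = continuous_scalars(75.0, 30.0, 130.0)
    else:
        base = stage_scalars("awake")
    return replace(base, gaba_tau_scale=scale, stage=None)


_TONIC_TABLE = {
    "A": {"awake": 1.0, "N2": 1.0, "N3": 1.0, "REM": 1.0},
    "B": {"awake": 1.0, "N2": 1.15, "N3": 1.30, "REM": 0.75},
    "C": {"awake": 1.0, "N2": 0.85, "N3": 0.70, "REM": 1.25},
}


def tonic_gaba_variant(variant: str, stage: str) -> float:
    """Miniature-IPSP conductance scale for the tonic-inhibition variants.

    A: tonic inhibition fixed; B: follows measured extracellular GABA
    (microdialysis); C: co-release with ACh/HA (inverted modulation).
    """
    if variant not in _TONIC_TABLE:
        raise ValueError("variant must be 'A', 'B' or 'C'")
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    return _TONIC_TABLE[variant][stage]


def apply_modulators(network, state: NeuromodulatorState) -> dict:
    """Effective parameters for an assembled network under ``state``.

    Pure function: base parameters are never mutated, so reapplication with
    the same state is idempotent.  Returns the effective K+-leak scale per
    population, the effective synaptic conductance per (source, target,
    type), the h-current activation shift, and the mini/tau scales.
    """
    g_eff = {}
    for name, proj in network.projections.items():
        for t in proj.syn_types:
            key = (proj.source, proj.target, t)
            g = network.synapse_params[key].g_syn
            if proj.modulator == "lach" and t == "AMPA":
                g = g * state.l_ach
            elif proj.modulator == "lgaba" and t in ("GABAA", "GABAB"):
                g = g * state.l_gaba
            g_eff[key] = g
    return dict(
        k_leak_scale={"PY": state.ach_py, "IN": state.ach_py,
                      "TC": state.ach_tc, "RE": state.ach_re},
        g_syn_effective=g_eff,
        shift_ha=state.shift_ha,
        tonic_mini_scale=state.tonic_gaba_scale,
        gabaa_decay_scale=state.gaba_tau_scale,
    )


@dataclass
class StageSchedule:
    """Ordered stage (or raw-level) segments with linear transition ramps.

    Each entry is ``(state, duration_s, ramp_s)`` where ``state`` is a stage
    name or a NeuromodulatorState.  During the first ``ramp_s`` seconds of a
    segment the scalars ramp linearly from the previous segment's values.
    """
    entries: list[tuple] = field(default_factory=list)

    def add(self, state, duration_s: float, ramp_s: float = 0.0):
        if duration_s <= 0:
            raise ValueError("durations must be > 0")
        if ramp_s < 0:
            raise ValueError("ramps must be >= 0")
        st = stage_scalars(state) if isinstance(state, str) else state
        self.entries.append((st, float(duration_s), float(ramp_s)))
        return self

    @property
    def total_duration_s(self) -> float:
        return sum(d for _, d, _ in self.entries)

    def segments(self) -> list[tuple[float, float, NeuromodulatorState]]:
        """(t_start_s, t_end_s, state) per segment."""
        out, t = [], 0.0
        for st, dur, _ in self.entries:
            out.append((t, t + dur, st))
            t += dur
        return out

    def scalar_time_course(self, dt_ms: float = 1.0) -> np.ndarray:
        """Scalars sampled every ``dt_ms``; shape (n_samples, 8).

        Columns follow SCALAR_NAMES.  With ramp 0 the course is stepwise.
        """
        if not self.entries:
            raise ValueError("empty schedule")
        n = int(round(self.total_duration_s * 1000.0 / dt_ms))
        out = np.empty((n, 9))
        prev = self.entries[0][0].scalar_vector()
        t0 = 0.0
        for st, dur, ramp in self.entries:
            cur = st.scalar_vector()
            i0 = int(round(t0 * 1000.0 / dt_ms))
            i1 = int(round((t0 + dur) * 1000.0 / dt_ms))
            ir = min(i0 + int(round(ramp * 1000.0 / dt_ms)), i1)
            if ir > i0:
                w = np.linspace(0.0, 1.0, ir - i0, endpoint=False)[:, None]
                out[i0:ir] = prev * (1.0 - w) + cur * w
            out[ir:i1] = cur
            prev, t0 = cur, t0 + dur
        return out

    def stage_labels(self, dt_ms: float = 1.0) -> list[str]:
        """Stage name (or 'custom') per sample."""
        labels = []
        for st, dur, _ in self.entries:
            labels += [st.stage or "custom"] * int(round(dur * 1000.0 / dt_ms))
        return labels
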