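"""Preset protocols: stage cycles, minimal models, species variants,
anesthesia and tonic-inhibition experiments, plus the neuromodulator-grid
sweep runner.

Each preset bundles a network scale, a stage schedule (or a raw scalar
state) and the qualitative outcome it is expected to show; ``run_preset``
executes it end to end, computes the relevant spectral features and returns
machine-readable verdicts.  ``run_sweep`` runs one seeded trial per grid
point over (ACh, GABA, HA) levels and accumulates a feature table suitable
for regime clustering.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .analysis import (band_power, compute_lfp, detect_events,
                       feature_table)
from .engine import SimConfig, SimulationResult, run
from .network import NetworkSpec, assemble
from .neuromodulation import (NeuromodulatorState, StageSchedule,
                              continuous_scalars, propofol_mode,
                              stage_scalars, tonic_gaba_variant)

__all__ = ["ExperimentPreset", "PRESETS", "run_preset", "run_sweep",
           "verdicts_for", "preset_names", "sweep_grid"]

_AWAKE = stage_scalars("awake")


def _minimal(base: str, target: str, **changes) -> NeuromodulatorState:
    """A minimal-model state: start from stage ``base`` scalars applied to
    one side of the loop only, everything else pinned at ``target``."""
    st = stage_scalars(base)
    return replace(st, stage=None, **changes)


def _stage_cycle(stage_s: float, ramp_s: float = 0.0,
                 tonic_variant: str | None = None,
                 stages=("awake", "N2", "N3", "N2", "REM")) -> StageSchedule:
    sched = StageSchedule()
    for s in stages:
        st = stage_scalars(s)
        if tonic_variant:
            st = replace(st, tonic_gaba_scale=tonic_gaba_variant(
                tonic_variant, s))
        sched.add(st, stage_s, ramp_s)
    return sched


@dataclass
class ExperimentPreset:
    """A runnable protocol with its expected qualitative outcome."""
    name: str
    description: str
    schedule_builder: object          # (stage_s) -> StageSchedule
    expectations: dict                # verdict name -> expected bool
    analyze_stage: str | None = None  # stage label to analyse (None = all)
    stage_s: float = 20.0             # default per-stage duration


def _two_stage(a: NeuromodulatorState, b: NeuromodulatorState):
    def build(stage_s):
        return StageSchedule().add(a, stage_s).add(b, stage_s)
    return build


def _single(state):
    def build(stage_s):
        return StageSchedule().add(state, 2 * stage_s)
    return build


def _make_presets() -> dict:
    p = {}
    p["stage-cycle"] = ExperimentPreset(
        "stage-cycle",
        "Full ultradian cycle awake->N2->N3->N2->REM with the baseline "
        "stage table.",
        lambda s: _stage_cycle(s),
        dict(spindles_in_n2=True, so_in_n3=True))

    # ---- minimal models: manipulations restricted to one side ------------
    aw, n2, n3 = stage_scalars("awake"), stage_scalars("N2"), stage_scalars("N3")
    # thalamus-only awake->N2 (all thalamic N2 changes; cortex pinned awake)
    th_n2 = replace(aw, ach_tc=1.25, ach_re=1.25, shift_ha=-3.0,
                    l_gaba_th=1.15, l_gaba_cx=1.0, stage=None)
    p["minimal-thalamic-n2"] = ExperimentPreset(
        "minimal-thalamic-n2",
        "Awake->N2 neuromodulation applied in the thalamus only.",
        _two_stage(_AWAKE, th_n2), dict(spindles=True))
    # cortex-only awake->N2
    cx_n2 = replace(aw, ach_py=1.25, l_ach=1.25, l_gaba_cx=1.15,
                    l_gaba_th=1.0, stage=None)
    p["minimal-cortical-n2"] = ExperimentPreset(
        "minimal-cortical-n2",
        "Awake->N2 neuromodulation applied in the cortex only.",
        _two_stage(_AWAKE, cx_n2), dict(spindles=False))
    # HA-only reduction in the thalamus
    ha_only = replace(aw, shift_ha=-3.0, stage=None)
    p["minimal-ha-only"] = ExperimentPreset(
        "minimal-ha-only",
        "Histamine reduction only (h-current shift -8 -> -3 mV).",
        _two_stage(_AWAKE, ha_only), dict(spindles=True))
    # thalamic ACh + HA reduction
    achha = replace(aw, ach_tc=1.25, ach_re=1.25, shift_ha=-3.0, stage=None)
    p["minimal-thalamic-achha"] = ExperimentPreset(
        "minimal-thalamic-achha",
        "ACh and HA reduced in the thalamus only.",
        _two_stage(_AWAKE, achha), dict(spindles=True))
    # thalamus-only N2->N3 (per its own caption values)
    th_n2_base = replace(n2, ach_py=n2.ach_py, stage=None)
    th_n3 = replace(n2, ach_tc=2.0, ach_re=2.0, shift_ha=-8.0,
                    l_gaba_th=1.3, stage=None)
    p["minimal-thalamic-n3"] = ExperimentPreset(
        "minimal-thalamic-n3",
        "N2->N3 neuromodulation applied in the thalamus only "
        "(caption scalar values).",
        _two_stage(th_n2_base, th_n3), dict(slow_oscillation=False))
    # cortex-only ACh reduction N2->N3
    p["minimal-cortical-ach-n3"] = ExperimentPreset(
        "minimal-cortical-ach-n3",
        "Cortical ACh reduction only on top of N2 (AChPY and LACh 1 -> "
        "1.25 relative to N2).",
        _two_stage(n2, replace(n2, ach_py=n2.ach_py * 1.25,
                               l_ach=n2.l_ach * 1.25, stage=None)),
        dict(slow_oscillation=True))
    # AMPA-strength increase only
    p["minimal-ampa-only"] = ExperimentPreset(
        "minimal-ampa-only",
        "Cortical AMPA increase only (LACh x1.25 on top of N2).",
        _two_stage(n2, replace(n2, l_ach=n2.l_ach * 1.25, stage=None)),
        dict(slow_oscillation=False, activated=True))
    # K-leak increase only
    p["minimal-kleak-only"] = ExperimentPreset(
        "minimal-kleak-only",
        "Cortical K+-leak increase only (AChPY x1.25 on top of N2).",
        _two_stage(n2, replace(n2, ach_py=n2.ach_py * 1.25, stage=None)),
        dict(slow_oscillation=False, quiescent=True))

    # ---- species / anesthesia variants -----------------------------------
    cat_sws = continuous_scalars(75.0, 30.0, 130.0)
    human_sws = continuous_scalars(45.0, 30.0, 130.0)
    p["cat-sws"] = ExperimentPreset(
        "cat-sws", "SWS with moderate ACh reduction (75% of awake): "
        "spindle and delta power positively correlated.",
        _single(cat_sws), dict(positive_spindle_delta_correlation=True))
    p["human-sws"] = ExperimentPreset(
        "human-sws", "N3 with strong ACh reduction (45% of awake): "
        "spindle and delta power negatively correlated "
        "(measured jointly with an N2 segment).",
        _two_stage(stage_scalars("N2"), human_sws),
        dict(negative_spindle_delta_correlation=True))
    p["propofol-combined"] = ExperimentPreset(
        "propofol-combined",
        "Propofol: GABA-A decay lengthened plus ACh/HA reduction.",
        _single(propofol_mode(150.0, combined=True)),
        dict(slow_oscillation=True, elevated_spindle_band=True))
    p["propofol-tau-only"] = ExperimentPreset(
        "propofol-tau-only",
        "Propofol control: only the GABA-A decay lengthened.",
        _single(propofol_mode(150.0, combined=False)),
        dict(slow_oscillation=False, elevated_spindle_band=False))
    for v in "ABC":
        p[f"tonic-gaba-{v.lower()}"] = ExperimentPreset(
            f"tonic-gaba-{v.lower()}",
            f"Stage cycle with tonic-inhibition variant {v} "
            "(miniature-IPSP conductance scaling).",
            (lambda vv: lambda s: _stage_cycle(s, tonic_variant=vv))(v),
            dict(spindles_in_n2=True, so_in_n3=True))
    p["extended-channels"] = ExperimentPreset(
        "extended-channels",
        "Stage cycle with ACh additionally scaling gKCa, gKm and gNap.",
        lambda s: _stage_cycle(s),
        dict(spindles_in_n2=True, so_in_n3=True))
    return p


PRESETS = _make_presets()


def preset_names():
    return sorted(PRESETS)


# ---------------------------------------------------------------------------
# Verdict computation
# ---------------------------------------------------------------------------


def _segment_lfp(res: SimulationResult, t0_s, t1_s):
    i0, i1 = int(t0_s * res.fs), int(t1_s * res.fs)
    return compute_lfp(res.py_v[i0:i1], res.fs, "all")


def _so_present(res: SimulationResult, t0, t1,
                require_dominance=True) -> bool:
    """Structural slow-oscillation check: delta episodes on the LFP, an
    active cortex, and a substantial fraction of network-silent 50 ms bins
    (the Down states).  ``require_dominance`` additionally demands delta
    power above spindle power; it is relaxed for states in which the slow
    oscillation deliberately coexists with strong spindling (anesthesia,
    mixed states)."""
    seg = _segment_lfp(res, t0, t1)
    x = seg.channel(0)
    sos = detect_events(seg, kind="slow_oscillation")
    de = band_power(x, res.fs, (0.5, 2.0))
    sp = band_power(x, res.fs, (7.0, 15.0))
    _, ts = res.spikes("PY", t0, t1)
    bins = np.histogram(ts, bins=np.arange(t0 * 1e3, t1 * 1e3, 50.0))[0]
    down = float(np.mean(bins == 0))
    rate = res.firing_rate("PY", t0, t1)
    ok = len(sos) >= 1 and down >= 0.15 and rate > 0.3
    return bool(ok and (de > sp or not require_dominance))


def verdicts_for(preset: ExperimentPreset, res: SimulationResult,
                 stage_s: float) -> dict:
    """Machine-readable checks of the preset's qualitative expectations.

    Two-stage presets are judged by CONTRAST: the manipulated (last)
    segment is compared against the run's own baseline (first) segment, so
    a verdict like "spindles" means the manipulation changed the rhythm,
    not merely that some band activity exists.  A 2 s settling margin is
    dropped after each transition.
    """
    dur = res.config.duration_s
    t0, t1 = dur - stage_s + 2.0, dur
    seg = _segment_lfp(res, t0, t1)
    x = seg.channel(0)
    b0, b1 = 2.0, stage_s
    base = _segment_lfp(res, b0, b1)
    xb = base.channel(0)
    out = {}
    exp = preset.expectations
    sos = detect_events(seg, kind="slow_oscillation")
    so_delta = band_power(x, res.fs, (0.5, 2.0))
    so_delta_base = band_power(xb, res.fs, (0.5, 2.0))
    spin_pw = band_power(x, res.fs, (7.0, 15.0))
    spin_base = band_power(xb, res.fs, (7.0, 15.0))
    py_rate = res.firing_rate("PY", t0, t1)
    py_base = res.firing_rate("PY", b0, b1)
    out["_spindle_band_power"] = spin_pw
    out["_spindle_band_base"] = spin_base
    out["_delta_power"] = so_delta
    out["_py_rate"] = py_rate

    if "spindles" in exp:
        # spindle activity appears: the thalamus engages (relay firing
        # well above its baseline) together with spindle-band LFP power
        # above baseline -- spindles are thalamically generated, so a
        # purely cortical power fluctuation does not count
        tc_rate = res.firing_rate("TC", t0, t1)
        tc_base = res.firing_rate("TC", b0, b1)
        out["_tc_rate"] = tc_rate
        out["spindles"] = (tc_rate > 2.0 * max(tc_base, 0.5)
                           and spin_pw > spin_base)
    if "spindles_in_n2" in exp:
        labels = res.stage_labels
        n2_ms = [i for i, l in enumerate(labels) if l == "N2"]
        s0, s1 = n2_ms[0] / 1000.0 + 2.0, n2_ms[0] / 1000.0 + stage_s
        segn2 = _segment_lfp(res, s0, min(s1, dur))
        spn2 = detect_events(segn2, kind="spindle")
        out["spindles_in_n2"] = len(spn2) >= 1
    if "so_in_n3" in exp:
        labels = res.stage_labels
        n3_ms = [i for i, l in enumerate(labels) if l == "N3"]
        s0 = n3_ms[0] / 1000.0 + 2.0
        s1 = min(n3_ms[-1] / 1000.0, dur)
        segn3 = _segment_lfp(res, s0, s1)
        out["so_in_n3"] = len(detect_events(segn3,
                                            kind="slow_oscillation")) >= 1
    if "slow_oscillation" in exp:
        # the slow oscillation = alternation of active Up states with
        # SILENT Down states: detected delta episodes, delta power grown
        # above baseline and dominating the spindle band, an active (not
        # quiescent) cortex, and a substantial fraction of network-silent
        # time bins (the Down states)
        _, ts = res.spikes("PY", t0, t1)
        bins = np.histogram(ts, bins=np.arange(t0 * 1e3, t1 * 1e3, 50.0))[0]
        down_frac = float(np.mean(bins == 0))
        out["_down_fraction"] = down_frac
        out["slow_oscillation"] = (len(sos) >= 1
                                   and so_delta > 2.0 * so_delta_base
                                   and so_delta > spin_pw
                                   and down_frac >= 0.15
                                   and py_rate > 0.3)
    if "activated" in exp:
        out["activated"] = py_rate > 2.0 * py_base
    if "quiescent" in exp:
        out["quiescent"] = py_rate < 0.5 * py_base
    if "elevated_spindle_band" in exp:
        # needs the natural-SWS reference power; see propofol_comparison
        out["elevated_spindle_band"] = None
    if "positive_spindle_delta_correlation" in exp or \
            "negative_spindle_delta_correlation" in exp:
        from .analysis import spindle_delta_correlation
        lf5 = compute_lfp(res.py_v[int(t0 * res.fs):], res.fs,
                          max(res.sizes["PY"] // 5, 1))
        tbl = feature_table(lf5, window_s=2.0, bands="model")
        r, pval = spindle_delta_correlation(tbl)
        out["_r"], out["_p"] = r, pval
        if "positive_spindle_delta_correlation" in exp:
            out["positive_spindle_delta_correlation"] = r > 0
        else:
            out["negative_spindle_delta_correlation"] = r < 0
    return out


def run_preset(name: str, seed: int = 0, scale: str = "reduced",
               stage_s: float | None = None,
               return_result: bool = True):
    """Run one preset end to end; returns (result, verdicts).

    ``scale`` is "full" (500/100/100/100 cells) or "reduced" (the desk-scale
    surrogate).  Expected-vs-observed mismatches are reported in the verdict
    dict; callers that need a hard failure can assert on it.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; options: {preset_names()}")
    preset = PRESETS[name]
    stage_s = stage_s or preset.stage_s
    spec = NetworkSpec.default() if scale == "full" else NetworkSpec.reduced()
    net = assemble(spec)
    sched = preset.schedule_builder(stage_s)
    cfg = SimConfig(schedule=sched, seed=seed,
                    extended=(name == "extended-channels"))
    res = run(cfg, net)
    v = verdicts_for(preset, res, stage_s)
    v["preset"] = name
    v["seed"] = seed
    v["pass"] = all(v.get(k) == want for k, want in
                    preset.expectations.items() if v.get(k) is not None)
    return (res, v) if return_result else v


# ---------------------------------------------------------------------------
# Neuromodulator-grid sweep
# ---------------------------------------------------------------------------


def sweep_grid(n_ach=7, n_gaba=9, n_ha=5):
    """Default grid over the explored ranges: ACh 0-120%, GABA 25-225%,
    HA 34-100% of the awake level."""
    return (np.linspace(0.0, 120.0, n_ach),
            np.linspace(25.0, 225.0, n_gaba),
            np.linspace(34.0, 100.0, n_ha))


def run_sweep(grid=None, seed=0, scale="reduced", trial_s=20.0,
              discard_s=10.0, window_s=2.0, per_window=False,
              out_dir=None, progress=False) -> pd.DataFrame:
    """One seeded trial per (ACh, GABA, HA) grid point; features per trial.

    Each trial runs ``trial_s`` seconds and the first ``discard_s`` are
    dropped as transient.  With ``per_window=False`` one feature row is
    produced per trial (powers and PLV over the analysed segment); with
    ``per_window=True`` one row per non-overlapping ``window_s`` window.
    If ``out_dir`` is given, completed grid points are check-pointed to a
    manifest and skipped on resume.
    """
    if grid is None:
        grid = sweep_grid()
    achs, gabas, has_ = grid
    spec = NetworkSpec.default() if scale == "full" else NetworkSpec.reduced()
    net = assemble(spec)
    manifest = os.path.join(out_dir, "sweep_manifest.json") if out_dir else None
    done = {}
    if manifest and os.path.exists(manifest):
        done = {tuple(json.loads(k)): v
                for k, v in json.load(open(manifest)).items()}
    rows = []
    trial = 0
    for ach in achs:
        for gaba in gabas:
            for ha in has_:
                key = (round(float(ach), 3), round(float(gaba), 3),
                       round(float(ha), 3))
                trial += 1
                if key in done:
                    rows.extend(done[key])
                    continue
                ach_eff = max(float(ach), 1.0)   # levels must stay positive
                st = continuous_scalars(ach_eff, float(ha), float(gaba))
                cfg = SimConfig(duration_s=trial_s, discard_s=discard_s,
                                seed=seed + trial, schedule=st)
                res = run(cfg, net)
                lf5 = compute_lfp(res.py_voltage(), res.fs,
                                  max(res.sizes["PY"] // 5, 1))
                win = window_s if per_window else (trial_s - discard_s)
                tbl = feature_table(lf5, window_s=win, bands="model",
                                    levels=(float(ach), float(ha),
                                            float(gaba)))
                recs = tbl.frame.to_dict("records")
                rows.extend(recs)
                if progress:
                    print(f"sweep point {key} -> {len(recs)} rows")
                if manifest:
                    done[key] = recs
                    with open(manifest, "w") as f:
                        json.dump({json.dumps(list(k)): v
                                   for k, v in done.items()}, f)
    return pd.DataFrame(rows)


def propofol_comparison(seed=0, scale="reduced", stage_s=20.0,
                        interpretation="by") -> dict:
    """Run the three anesthesia conditions and compare their spectra.

    Returns slow-oscillation presence and 7-15 Hz band power for the
    combined propofol model, the decay-time-only control and the natural
    SWS reference, plus the derived verdicts: the combined model must show
    a slow oscillation AND more spindle-band power than natural SWS, while
    the decay-time-only control shows neither.
    """
    conds = {
        "combined": propofol_mode(150.0, combined=True,
                                  interpretation=interpretation),
        "tau_only": propofol_mode(150.0, combined=False,
                                  interpretation=interpretation),
        "natural_sws": continuous_scalars(75.0, 30.0, 130.0),
    }
    spec = NetworkSpec.default() if scale == "full" else NetworkSpec.reduced()
    out = {}
    for name, st in conds.items():
        net = assemble(spec)
        cfg = SimConfig(duration_s=stage_s, seed=seed, schedule=st)
        res = run(cfg, net)
        seg = _segment_lfp(res, 4.0, stage_s)
        x = seg.channel(0)
        out[name] = dict(
            spindle_band=band_power(x, res.fs, (8.0, 15.0)),
            delta_band=band_power(x, res.fs, (0.2, 4.0)),
            so=_so_present(res, 4.0, stage_s,
                           require_dominance=False),
            py_rate=res.firing_rate("PY", 4.0, stage_s))
    out["verdict_combined"] = (out["combined"]["so"]
                               and out["combined"]["spindle_band"]
                               > out["natural_sws"]["spindle_band"])
    out["verdict_tau_only"] = (
        out["tau_only"]["spindle_band"] < out["combined"]["spindle_band"]
        and not out["tau_only"]["so"])
    return out
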