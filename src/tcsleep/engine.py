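"""Network integration engine: configuration, time stepping, recording,
stimulation and checkpointable run state.

The engine integrates an assembled :class:`~tcsleep.network.Network` under a
:class:`~tcsleep.neuromodulation.StageSchedule`, with miniature PSPs as the
only stochastic element (seeded, bit-reproducible).  Voltages are recorded at
1 kHz; spikes are somatic upward crossings of 0 mV with a 2 ms refractory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from . import _kernels as K
from .cells import (CorticalCellParams, ThalamicCellParams, resting_state,
                    cx_param_vector, tc_param_vector, CX_VD, CX_VS)
from .network import Network, NetworkSpec, assemble
from .neuromodulation import (StageSchedule, NeuromodulatorState,
                              stage_scalars)

__all__ = ["SimConfig", "SimulationResult", "RunState", "run", "init_state",
           "advance", "finalize", "apply_dc_pulse", "run_isolated"]

POPS = ("PY", "IN", "TC", "RE")


@dataclass
class StimEvent:
    """Square DC current pulse applied to every cell of one population."""
    population: str
    amplitude_nA: float
    onset_ms: float
    duration_ms: float

    def __post_init__(self):
        if self.population not in POPS:
            raise ValueError(f"unknown population {self.population!r}")
        if not np.isfinite(self.amplitude_nA):
            raise ValueError("amplitude must be finite")
        if self.duration_ms <= 0 or self.onset_ms < 0:
            raise ValueError("stimulation window invalid")


def apply_dc_pulse(config: "SimConfig", population: str,
                   amplitude_nA: float = 1.5, duration_ms: float = 100.0,
                   onset_ms: float = 0.0) -> StimEvent:
    """Register a DC pulse on ``config``; window must lie inside the run."""
    ev = StimEvent(population, amplitude_nA, onset_ms, duration_ms)
    if ev.onset_ms + ev.duration_ms > config.duration_s * 1000.0:
        raise ValueError("stimulation window outside run duration")
    config.stim_events.append(ev)
    return ev


@dataclass
class SimConfig:
    """Declarative description of one simulation run."""
    duration_s: float | None = None      # defaults to the schedule length
    dt_ms: float = 0.02
    discard_s: float = 0.0               # transient excluded from analysis
    seed: int = 0
    schedule: StageSchedule | str | NeuromodulatorState = "awake"
    stim_events: list = field(default_factory=list)
    mini_scale: float = 1.0              # 0 disables miniature PSPs
    depression_u: float = C.DEPRESSION_U
    depression_tau: float = C.DEPRESSION_TAU
    mini_normalization: str = "per_connection"   # per_connection | total
    extended: bool = False               # ACh also scales gKCa/gKm/gNap
    lfp_source: str = "dendrite"         # dendrite | soma (PY recording)
    spike_cap_hz: float = 120.0
    chunk_s: float = 5.0

    def __post_init__(self):
        if isinstance(self.schedule, str):
            sched = StageSchedule()
            sched.add(self.schedule, self.duration_s or 20.0)
            self.schedule = sched
        elif isinstance(self.schedule, NeuromodulatorState):
            sched = StageSchedule()
            sched.add(self.schedule, self.duration_s or 20.0)
            self.schedule = sched
        if self.duration_s is None:
            self.duration_s = self.schedule.total_duration_s
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if self.duration_s <= self.discard_s:
            raise ValueError("duration must exceed the discarded transient")
        spm = 1.0 / self.dt_ms
        if abs(spm - round(spm)) > 1e-9:
            raise ValueError("1 ms must be an integer number of steps")

    def content_hash(self) -> str:
        ent = [(s.scalar_vector().tolist(), d, r)
               for s, d, r in self.schedule.entries]
        blob = json.dumps([self.duration_s, self.dt_ms, self.discard_s,
                           self.seed, ent,
                           [(e.population, e.amplitude_nA, e.onset_ms,
                             e.duration_ms) for e in self.stim_events],
                           self.mini_scale, self.extended], sort_keys=True)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


@dataclass
class RunState:
    """Complete mutable state of a run; supports checkpointed continuation."""
    config: SimConfig
    network: Network
    t_ms: float
    pops: dict           # population state arrays
    syn: dict            # synapse state arrays
    rec_py: np.ndarray
    rec_mean: np.ndarray
    spk_t: np.ndarray
    spk_id: np.ndarray
    spk_n: int
    scal: np.ndarray
    stim: np.ndarray
    _packed: tuple = None


@dataclass
class SimulationResult:
    """Recorded output of a run (1 kHz voltage traces, spikes, scalars)."""
    config: SimConfig
    sizes: dict
    fs: float                      # recording sample rate (Hz)
    py_v: np.ndarray               # (n_ms, n_PY) PY voltage (dend or soma)
    pop_mean: np.ndarray           # (n_ms, 4) mean voltage per population
    spike_t: np.ndarray            # ms
    spike_id: np.ndarray           # global cell index (PY, IN, TC, RE blocks)
    scalars: np.ndarray            # (n_ms, 8) applied modulator scalars
    stage_labels: list
    seed: int
    config_hash: str = ""

    def _pop_slice(self, pop: str) -> tuple[int, int]:
        o = 0
        for p in POPS:
            n = self.sizes[p]
            if p == pop:
                return o, o + n
            o += n
        raise ValueError(f"unknown population {pop!r}")

    def spikes(self, pop: str, t0_s: float = 0.0, t1_s: float | None = None):
        """(cell_index, t_ms) arrays for one population."""
        lo, hi = self._pop_slice(pop)
        t1 = (t1_s if t1_s is not None else self.config.duration_s) * 1000.0
        m = ((self.spike_id >= lo) & (self.spike_id < hi)
             & (self.spike_t >= t0_s * 1000.0) & (self.spike_t < t1))
        return self.spike_id[m] - lo, self.spike_t[m]

    def firing_rate(self, pop: str, t0_s: float | None = None,
                    t1_s: float | None = None) -> float:
        """Mean firing rate (Hz per cell) over [t0, t1) (default: after the
        discarded transient)."""
        t0 = self.config.discard_s if t0_s is None else t0_s
        t1 = self.config.duration_s if t1_s is None else t1_s
        _, ts = self.spikes(pop, t0, t1)
        return len(ts) / self.sizes[pop] / (t1 - t0)

    def py_voltage(self, discard: bool = True) -> np.ndarray:
        """(n_samples, n_PY) recorded PY voltages, transient dropped."""
        i0 = int(self.config.discard_s * self.fs) if discard else 0
        return self.py_v[i0:]

    def time_s(self, discard: bool = True) -> np.ndarray:
        i0 = int(self.config.discard_s * self.fs) if discard else 0
        return np.arange(i0, self.py_v.shape[0]) / self.fs

    def raster_text(self, path):
        """Export spikes as columnar text: cell_id t_ms."""
        np.savetxt(path, np.column_stack([self.spike_id, self.spike_t]),
                   fmt=["%d", "%.2f"], header="cell_id t_ms")

    def save(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.attrs["fs"] = self.fs
            f.attrs["seed"] = self.seed
            f.attrs["config_hash"] = self.config_hash
            f.attrs["duration_s"] = self.config.duration_s
            f.attrs["discard_s"] = self.config.discard_s
            f.attrs["sizes"] = json.dumps(self.sizes)
            f.create_dataset("py_v", data=self.py_v, compression="gzip")
            f.create_dataset("pop_mean", data=self.pop_mean)
            f.create_dataset("spike_t", data=self.spike_t)
            f.create_dataset("spike_id", data=self.spike_id)
            f.create_dataset("scalars", data=self.scalars)
            f.create_dataset("stage_labels",
                             data=np.array(self.stage_labels, dtype="S8"))

    @classmethod
    def load(cls, path):
        import h5py
        with h5py.File(path, "r") as f:
            sizes = json.loads(f.attrs["sizes"])
            cfg = SimConfig(duration_s=float(f.attrs["duration_s"]),
                            discard_s=float(f.attrs["discard_s"]),
                            seed=int(f.attrs["seed"]))
            return cls(config=cfg, sizes=sizes, fs=float(f.attrs["fs"]),
                       py_v=f["py_v"][:], pop_mean=f["pop_mean"][:],
                       spike_t=f["spike_t"][:], spike_id=f["spike_id"][:],
                       scalars=f["scalars"][:],
                       stage_labels=[s.decode()
                                     for s in f["stage_labels"][:]],
                       seed=int(f.attrs["seed"]),
                       config_hash=str(f.attrs["config_hash"]))


# ---------------------------------------------------------------------------
# State construction
# ---------------------------------------------------------------------------

_GVEC_KEYS = [("PY", "PY", "AMPA"), ("PY", "PY", "NMDA"),
              ("PY", "IN", "AMPA"), ("PY", "IN", "NMDA"),
              ("IN", "PY", "GABAA"), ("TC", "PY", "AMPA"),
              ("TC", "IN", "AMPA"), ("PY", "TC", "AMPA"),
              ("PY", "RE", "AMPA"), ("TC", "RE", "AMPA"),
              ("RE", "TC", "GABAA"), ("RE", "TC", "GABAB"),
              ("RE", "RE", "GABAA")]
_PROJ_ORDER = ["PY->PY", "PY->IN", "IN->PY", "TC->PY", "TC->IN", "PY->TC",
               "PY->RE", "TC->RE", "RE->TC", "RE->RE"]


def _csr(edges, normalization="per_connection"):
    if normalization == "total":
        invfan = np.where(edges.fan_in > 0, 1.0 / np.maximum(edges.fan_in, 1),
                          0.0)
    else:
        invfan = np.where(edges.fan_in > 0, 1.0, 0.0)
    return (edges.indptr.astype(np.int64), edges.src.astype(np.int64),
            invfan.astype(np.float64))


def init_state(config: SimConfig, network: Network | None = None,
               cell_overrides: dict | None = None) -> RunState:
    """Allocate and seed the full run state at t = 0."""
    network = network or assemble(NetworkSpec.default())
    sz = network.sizes
    n_ms = int(round(config.duration_s * 1000.0))
    scal = config.schedule.scalar_time_course(1.0)
    if scal.shape[0] < n_ms:
        scal = np.vstack([scal, np.repeat(scal[-1:], n_ms - scal.shape[0], 0)])
    scal = np.ascontiguousarray(scal[:n_ms])
    stim = np.zeros((n_ms, 4))
    for ev in config.stim_events:
        j = POPS.index(ev.population)
        i0 = int(ev.onset_ms)
        i1 = int(ev.onset_ms + ev.duration_ms)
        stim[i0:i1, j] += ev.amplitude_nA

    ov = cell_overrides or {}
    py_par = ov.get("PY", CorticalCellParams(extended=config.extended))
    in_par = ov.get("IN", CorticalCellParams.interneuron())
    if config.extended:
        in_par.extended = True
    tc_par = ov.get("TC", ThalamicCellParams())
    re_par = ov.get("RE", ThalamicCellParams.reticular())

    pops = dict(
        py=np.tile(resting_state("PY"), (sz["PY"], 1)),
        inn=np.tile(resting_state("IN"), (sz["IN"], 1)),
        tc=np.tile(resting_state("TC", v=-68.0), (sz["TC"], 1)),
        re=np.tile(resting_state("RE", v=-70.0), (sz["RE"], 1)),
        pyp=cx_param_vector(py_par), inp=cx_param_vector(in_par),
        tcp=tc_param_vector(tc_par), rep=tc_param_vector(re_par),
    )
    gvec = np.zeros(16)
    for k, key in enumerate(_GVEC_KEYS):
        gvec[k] = network.synapse_params[key].g_syn
    gvec[13] = C.G_MINI["PY_PY"] * config.mini_scale
    gvec[14] = C.G_MINI["PY_IN"] * config.mini_scale
    gvec[15] = C.G_MINI["IN_PY"] * config.mini_scale

    projs = tuple(
        _csr(network.edges[name],
             network.projections[name].normalization
             or network.spec.normalization)
        for name in _PROJ_ORDER)

    def mini_pack(name, n_post):
        e = network.edges[name]
        if config.mini_normalization == "total":
            w = np.where(e.fan_in[e.dst] > 0,
                         1.0 / np.maximum(e.fan_in[e.dst], 1), 0.0)
        else:
            w = np.ones(len(e))
        return (e.src.astype(np.int64), e.dst.astype(np.int64),
                w.astype(np.float64), np.zeros(len(e)), np.zeros(n_post))

    minis = (mini_pack("PY->PY", sz["PY"]), mini_pack("PY->IN", sz["IN"]),
             mini_pack("IN->PY", sz["PY"]))

    syn = dict(
        o_ampa_py=np.zeros(sz["PY"]), o_nmda_py=np.zeros(sz["PY"]),
        dep_py=np.ones(sz["PY"]), o_gabaa_in=np.zeros(sz["IN"]),
        o_ampa_tc=np.zeros(sz["TC"]), o_gabaa_re=np.zeros(sz["RE"]),
        gb_r=np.zeros(sz["RE"]), gb_g=np.zeros(sz["RE"]),
        pulse_py=np.full(sz["PY"], -1e9), pulse_in=np.full(sz["IN"], -1e9),
        pulse_tc=np.full(sz["TC"], -1e9), pulse_re=np.full(sz["RE"], -1e9),
        t0_py=np.full(sz["PY"], -1e9), t0_in=np.full(sz["IN"], -1e9),
        ls_py=np.full(sz["PY"], -1e9), ls_in=np.full(sz["IN"], -1e9),
        ls_tc=np.full(sz["TC"], -1e9), ls_re=np.full(sz["RE"], -1e9),
        gvec=gvec, projs=projs, minis=minis,
    )
    n_cells = sum(sz.values())
    cap = int(n_cells * config.duration_s * config.spike_cap_hz) + 10000
    tabs = K.build_tables(config.dt_ms)
    K.seed_rng(config.seed % (2 ** 31))
    st = RunState(
        config=config, network=network, t_ms=0.0, pops=pops, syn=syn,
        rec_py=np.zeros((n_ms, sz["PY"]), dtype=np.float64),
        rec_mean=np.zeros((n_ms, 4)), spk_t=np.zeros(cap),
        spk_id=np.zeros(cap, dtype=np.int64), spk_n=0, scal=scal, stim=stim)
    st._packed = tabs
    return st


def advance(state: RunState, seconds: float | None = None) -> RunState:
    """Integrate further by ``seconds`` (default: to the configured end)."""
    cfg = state.config
    dt = cfg.dt_ms
    steps_per_ms = int(round(1.0 / dt))
    n_ms_total = state.scal.shape[0]
    t_end_ms = (n_ms_total if seconds is None
                else min(state.t_ms + seconds * 1000.0, n_ms_total))
    cx_tab, tc_tab, re_tab = state._packed
    nap_fac = float(np.exp(-dt / C.NAP_TAU))
    s = state.syn
    p = state.pops
    chunk_ms = int(cfg.chunk_s * 1000)
    while state.t_ms < t_end_ms - 1e-9:
        ms0 = int(round(state.t_ms))
        n_ms = min(chunk_ms, int(round(t_end_ms)) - ms0)
        n_steps = n_ms * steps_per_ms
        res = K.run_chunk(
            n_steps, dt, float(ms0), steps_per_ms,
            cfg.depression_u, cfg.depression_tau,
            state.scal, state.stim,
            p["py"], p["inn"], p["tc"], p["re"],
            p["pyp"], p["inp"], p["tcp"], p["rep"],
            cx_tab, tc_tab, re_tab, nap_fac,
            s["projs"], s["minis"], s["gvec"],
            s["o_ampa_py"], s["o_nmda_py"], s["dep_py"], s["o_gabaa_in"],
            s["o_ampa_tc"], s["o_gabaa_re"], s["gb_r"], s["gb_g"],
            s["pulse_py"], s["pulse_in"], s["pulse_tc"], s["pulse_re"],
            s["t0_py"], s["t0_in"], s["ls_py"], s["ls_in"], s["ls_tc"],
            s["ls_re"],
            state.rec_py[ms0:ms0 + n_ms], state.rec_mean[ms0:ms0 + n_ms],
            CX_VS if cfg.lfp_source == "soma" else CX_VD,
            state.spk_t, state.spk_id, state.spk_n)
        state.spk_n, err, err_cell, err_t = res
        if err:
            raise FloatingPointError(
                f"non-finite voltage in cell {err_cell} at t = {err_t:.2f} ms")
        state.t_ms = ms0 + n_ms
    return state


def finalize(state: RunState) -> SimulationResult:
    cfg = state.config
    n = state.spk_n
    labels = cfg.schedule.stage_labels(1.0)
    return SimulationResult(
        config=cfg, sizes=dict(state.network.sizes), fs=1000.0,
        py_v=state.rec_py, pop_mean=state.rec_mean,
        spike_t=state.spk_t[:n].copy(), spike_id=state.spk_id[:n].copy(),
        scalars=state.scal, stage_labels=labels, seed=cfg.seed,
        config_hash=cfg.content_hash())


def run(config: SimConfig, network: Network | None = None,
        cell_overrides: dict | None = None) -> SimulationResult:
    """Run a complete simulation and return the recorded result."""
    state = init_state(config, network, cell_overrides)
    advance(state)
    return finalize(state)


def run_isolated(kind: str, duration_s: float = 2.0, dt_ms: float = 0.02,
                 modulators: NeuromodulatorState | str = "awake",
                 i_inject_nA: float = 0.0, inject_window_ms=None,
                 cell_overrides: dict | None = None):
    """Integrate one isolated cell of ``kind`` (all synapses disabled).

    Returns (t_s, v) at 1 kHz, plus the spike times (ms) of that cell.
    Used for single-cell validation and integrator-convergence checks.
    """
    spec = NetworkSpec(sizes={"PY": 1, "IN": 1, "TC": 1, "RE": 1})
    net = assemble(spec)
    for par in net.synapse_params.values():
        par.g_syn = 0.0
    mods = stage_scalars(modulators) if isinstance(modulators, str) \
        else modulators
    cfg = SimConfig(duration_s=duration_s, dt_ms=dt_ms, schedule=mods,
                    mini_scale=0.0, chunk_s=max(duration_s, 1.0))
    if i_inject_nA:
        w = inject_window_ms or (0.0, duration_s * 1000.0)
        cfg.stim_events.append(StimEvent(kind, i_inject_nA, w[0],
                                         w[1] - w[0]))
    res = run(cfg, net, cell_overrides)
    col = POPS.index(kind)
    if kind == "PY":
        v = res.py_v[:, 0]
    else:
        v = res.pop_mean[:, col]
    _, ts = res.spikes(kind)
    return np.arange(len(v)) / res.fs, v, ts
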