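"""Signal analysis for simulated (and recorded) field potentials.

The chain mirrors what is routinely applied to sleep LFP/EEG: a simulated
LFP is the mean membrane voltage over a group of pyramidal cells; band power
is integrated from windowed FFT periodograms; synchronization between LFP
channels is the phase-locking value (PLV) of band-filtered analytic-signal
phases; spindle and slow-oscillation episodes are detected from envelope and
half-wave criteria; and dynamical regimes across neuromodulator conditions
are clustered with a Gaussian mixture model whose component count is chosen
by the Akaike information criterion (AIC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "LfpSeries", "SpectralFeatureTable", "StateClusterModel", "BANDS",
    "compute_lfp", "band_power", "band_power_windows", "plv",
    "detect_events", "Episode", "spindle_delta_correlation",
    "cluster_states", "project_clusters", "feature_table", "load_lfp_text",
]

# band conventions (Hz): delta and spindle ranges per recording context
BANDS = {
    "model": dict(delta=(0.5, 4.0), spindle=(7.0, 15.0), plv=(0.5, 20.0)),
    "animal": dict(delta=(0.2, 4.0), spindle=(8.0, 15.0), plv=(0.5, 20.0)),
    "human": dict(delta=(0.01, 2.0), spindle=(9.0, 17.0), plv=(0.5, 20.0)),
}


@dataclass
class LfpSeries:
    """One or more LFP channels at a common sample rate."""
    fs: float                      # Hz
    data: np.ndarray               # (n_samples, n_channels), mV
    grouping: str = ""             # which cells were averaged

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] < self.data.shape[1]:
            pass  # caller's layout is trusted: (samples, channels)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("LFP contains non-finite samples")
        if self.data.shape[1] < 1:
            raise ValueError("at least one channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel(self, i: int) -> np.ndarray:
        return self.data[:, i]


def compute_lfp(voltages: np.ndarray, fs: float,
                grouping: str | int = "all") -> LfpSeries:
    """Simulated LFP: arithmetic mean of cell voltages per group.

    ``voltages`` is (n_samples, n_cells).  ``grouping`` is "all" (one global
    channel) or an integer n: consecutive groups of n cells, one channel per
    group (a population of 500 with n=100 yields 5 channels; a trailing
    remainder forms a final, smaller group).
    """
    v = np.asarray(voltages, dtype=float)
    if v.ndim != 2:
        raise ValueError("voltages must be (n_samples, n_cells)")
    n_cells = v.shape[1]
    if grouping == "all":
        return LfpSeries(fs=fs, data=v.mean(axis=1, keepdims=True),
                         grouping="all")
    n = int(grouping)
    if n < 1 or n > n_cells:
        raise ValueError("group size must be in [1, n_cells]")
    chans = [v[:, i:i + n].mean(axis=1) for i in range(0, n_cells, n)]
    return LfpSeries(fs=fs, data=np.column_stack(chans),
                     grouping=f"groups_of({n})")


def load_lfp_text(path, fs: float | None = None) -> LfpSeries:
    """Plain columnar text: first column time (s), remaining columns mV."""
    arr = np.loadtxt(path)
    t, data = arr[:, 0], arr[:, 1:]
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return LfpSeries(fs=fs, data=data, grouping="external")


# ---------------------------------------------------------------------------
# Spectral measures
# ---------------------------------------------------------------------------


def _periodogram(x, fs, window="hann"):
    win = "boxcar" if window == "rect" else window
    f, p = sps.periodogram(x, fs=fs, window=win, detrend="constant")
    return f, p


def band_power(series, fs=None, band=(7.0, 15.0), window="hann"):
    """Integrated spectral power of ``series`` in ``band`` (Hz).

    Accepts an LfpSeries (uses channel 0) or a plain 1-D array with ``fs``.
    The FFT periodogram uses a Hann window by default; pass window="rect"
    for the rectangular window under which the band powers over a partition
    of [0, Nyquist] sum exactly to the signal variance (Parseval).
    """
    if isinstance(series, LfpSeries):
        x, fs = series.channel(0), series.fs
    else:
        x = np.asarray(series, dtype=float)
        if fs is None:
            raise ValueError("fs required for a plain array")
    lo, hi = band
    if not 0 <= lo < hi:
        raise ValueError("band must satisfy 0 <= lo < hi")
    if hi > fs / 2 + 1e-9:
        raise ValueError("band exceeds the Nyquist frequency")
    f, p = _periodogram(x, fs, window)
    m = (f >= lo) & (f < hi)
    return float(np.sum(p[m]) * (f[1] - f[0]))


def band_power_windows(series, fs=None, band=(7.0, 15.0), window_s=2.0,
                       slide_s=None, window="hann"):
    """Per-window band power: (window_start_s, power) arrays.

    ``slide_s`` defaults to ``window_s`` (non-overlapping windows, the model
    convention); recordings are often analysed with a 5 s window slid by 1 s.
    """
    if isinstance(series, LfpSeries):
        x, fs = series.channel(0), series.fs
    else:
        x = np.asarray(series, dtype=float)
    slide_s = slide_s or window_s
    nw, ns = int(round(window_s * fs)), int(round(slide_s * fs))
    if nw > len(x):
        raise ValueError("window longer than the series")
    starts = np.arange(0, len(x) - nw + 1, ns)
    powers = np.array([band_power(x[s:s + nw], fs, band, window)
                       for s in starts])
    return starts / fs, powers


def _bandpass(x, fs, band, order=3):
    ny = fs / 2.0
    lo = max(band[0], 1e-3)
    b, a = sps.butter(order, [lo / ny, band[1] / ny], btype="band")
    return sps.filtfilt(b, a, x - np.mean(x))


def plv(channel_a, channel_b, fs, band=(0.5, 20.0)) -> float:
    """Phase-locking value between two channels in ``band``.

    Both channels are band-filtered, their instantaneous phases extracted by
    the Hilbert transform, and the PLV is the modulus of the mean unit
    phasor of the phase difference; 1 for perfectly locked signals, -> 0 for
    long independent signals.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance channel")
    pa = np.angle(sps.hilbert(_bandpass(a, fs, band)))
    pb = np.angle(sps.hilbert(_bandpass(b, fs, band)))
    # drop filter/Hilbert edge transients (5% each side)
    m = max(int(0.05 * len(a)), 1)
    d = (pa - pb)[m:-m] if len(a) > 2 * m else (pa - pb)
    return float(np.abs(np.mean(np.exp(1j * d))))


def mean_pairwise_plv(lfp: LfpSeries, band=(0.5, 20.0)) -> float:
    """Mean PLV over all channel pairs of a multichannel LFP."""
    n = lfp.n_channels
    if n < 2:
        return 1.0
    vals = [plv(lfp.channel(i), lfp.channel(j), lfp.fs, band)
            for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------


@dataclass
class Episode:
    onset_s: float
    offset_s: float
    peak_freq_hz: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def detect_events(lfp, fs=None, kind="spindle", band=None,
                  threshold=2.0, boundary_threshold=1.2,
                  min_duration_s=0.4, merge_gap_s=0.3,
                  amplitude_percentile=60.0):
    """Detect spindle or slow-oscillation episodes in one LFP channel.

    Spindles: the analytic-signal envelope of the band-filtered (default
    7-15 Hz) signal is smoothed (100 ms) and episodes are scored with the
    standard dual-threshold rule: an episode is detected where the envelope
    exceeds ``threshold`` times the epoch median (a relative threshold, so
    a pure amplitude rescaling of the signal does not change the
    detections), and its onset/offset are delimited where the envelope
    falls back below ``boundary_threshold`` times the median.
    Supra-threshold runs closer than ``merge_gap_s`` are merged and runs
    shorter than ``min_duration_s`` discarded.

    Slow oscillations: zero crossings of the delta-filtered signal define
    half-waves; consecutive alternating half-waves whose amplitudes exceed
    the ``amplitude_percentile`` of all half-wave amplitudes, with period in
    the delta range, form episodes.

    Returns a list of :class:`Episode`.
    """
    if isinstance(lfp, LfpSeries):
        x, fs = lfp.channel(0), lfp.fs
    else:
        x = np.asarray(lfp, dtype=float)
    if fs is None or fs < 100.0:
        raise ValueError("sample rate must be >= 100 Hz")
    if np.ptp(x) == 0:
        return []
    if kind == "spindle":
        band = band or (7.0, 15.0)
        xf = _bandpass(x, fs, band)
        env = np.abs(sps.hilbert(xf))
        w = max(int(0.1 * fs), 1)
        env = np.convolve(env, np.ones(w) / w, mode="same")
        med = np.median(env)
        core = env > threshold * med
        # delimit each core detection at the lower boundary crossing
        low = env > min(boundary_threshold, threshold) * med
        above = _extend_runs(core, low)
        episodes = _runs_to_episodes(above, fs, merge_gap_s, min_duration_s)
        out = []
        for i0, i1 in episodes:
            f, p = _periodogram(xf[i0:i1], fs)
            m = (f >= band[0]) & (f <= band[1])
            pk = float(f[m][np.argmax(p[m])]) if m.any() else np.nan
            out.append(Episode(i0 / fs, i1 / fs, pk))
        return out
    if kind == "slow_oscillation":
        band = band or (0.5, 4.0)
        xf = _bandpass(x, fs, (max(band[0], 0.3), min(band[1], 2.0)))
        sign = np.signbit(xf)
        crossings = np.flatnonzero(np.diff(sign.astype(int)) != 0)
        if len(crossings) < 3:
            return []
        amps = np.array([np.max(np.abs(xf[a:b]))
                         for a, b in zip(crossings[:-1], crossings[1:])])
        thr = np.percentile(amps, amplitude_percentile)
        good = amps >= thr
        out = []
        start = None
        for k in range(len(good)):
            dur = (crossings[k + 1] - crossings[k]) / fs   # half-wave
            ok = good[k] and 0.1 <= dur <= 1.7
            if ok and start is None:
                start = k
            elif not ok and start is not None:
                if k - start >= 2:   # at least one full cycle
                    i0, i1 = crossings[start], crossings[k]
                    period = 2 * (i1 - i0) / fs / (k - start)
                    out.append(Episode(i0 / fs, i1 / fs, 1.0 / period))
                start = None
        if start is not None and len(good) - start >= 2:
            i0, i1 = crossings[start], crossings[-1]
            period = 2 * (i1 - i0) / fs / (len(good) - start)
            out.append(Episode(i0 / fs, i1 / fs, 1.0 / period))
        return out
    raise ValueError("kind must be 'spindle' or 'slow_oscillation'")


def _extend_runs(core, low):
    """Grow every True-run of ``core`` outward over the ``low`` mask."""
    idx = np.flatnonzero(np.diff(np.r_[0, low.astype(int), 0]))
    out = np.zeros_like(core)
    for s, e in zip(idx[::2], idx[1::2]):
        if core[s:e].any():
            out[s:e] = True
    return out


def _runs_to_episodes(above, fs, merge_gap_s, min_duration_s):
    idx = np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0]))
    starts, stops = idx[::2], idx[1::2]
    merged = []
    for s, e in zip(starts, stops):
        if merged and (s - merged[-1][1]) / fs < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if (e - s) / fs >= min_duration_s]


# ---------------------------------------------------------------------------
# Feature tables and correlations
# ---------------------------------------------------------------------------


@dataclass
class SpectralFeatureTable:
    """Per-window (or per-trial) delta power, spindle power and PLV."""
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("t_start", "t_end", "delta_power", "spindle_power", "plv")

    def __post_init__(self):
        if len(self.frame):
            for c in ("delta_power", "spindle_power"):
                if (self.frame[c] < 0).any():
                    raise ValueError(f"{c} must be >= 0")
            if ((self.frame["plv"] < 0) | (self.frame["plv"] > 1)).any():
                raise ValueError("plv must lie in [0, 1]")

    def to_text(self, path):
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_text(cls, path):
        return cls(frame=pd.read_csv(path, sep="\t"))


def feature_table(lfp: LfpSeries, window_s=2.0, bands="model",
                  stage=None, levels=None) -> SpectralFeatureTable:
    """Windowed delta/spindle power and mean pairwise PLV for one LFP.

    Powers are measured on the global (channel-mean) trace; the PLV uses all
    channel pairs within each window.  ``levels`` optionally attaches the
    (ACh, HA, GABA) coordinates of the condition that generated the data.
    """
    bd = BANDS[bands] if isinstance(bands, str) else bands
    x = lfp.data.mean(axis=1)
    fs = lfp.fs
    t, dp = band_power_windows(x, fs, bd["delta"], window_s)
    _, sp = band_power_windows(x, fs, bd["spindle"], window_s)
    nw = int(round(window_s * fs))
    rows = []
    for k, t0 in enumerate(t):
        i0 = int(round(t0 * fs))
        seg = LfpSeries(fs=fs, data=lfp.data[i0:i0 + nw])
        try:
            p = mean_pairwise_plv(seg, bd["plv"])
        except ValueError:
            p = 0.0
        row = dict(t_start=t0, t_end=t0 + window_s, delta_power=dp[k],
                   spindle_power=sp[k], plv=p)
        if stage is not None:
            row["stage"] = stage
        if levels is not None:
            row["ach"], row["ha"], row["gaba"] = levels
        rows.append(row)
    return SpectralFeatureTable(frame=pd.DataFrame(rows))


def spindle_delta_correlation(table) -> tuple[float, float]:
    """Pearson correlation between spindle and delta power across windows.

    Returns (r, p) with the standard two-sided t-transform significance.
    Accepts a SpectralFeatureTable or a DataFrame with the two power columns.
    """
    df = table.frame if isinstance(table, SpectralFeatureTable) else table
    if len(df) < 3:
        raise ValueError("need at least 3 windows")
    r, p = stats.pearsonr(df["spindle_power"], df["delta_power"])
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Regime clustering
# ---------------------------------------------------------------------------


@dataclass
class StateClusterModel:
    """Fitted Gaussian mixture over (spindle power, delta power, PLV)."""
    n_components: int
    means: np.ndarray
    covariances: np.ndarray
    weights: np.ndarray
    aic: np.ndarray                 # AIC per candidate component count 1..K
    assignments: np.ndarray
    feature_names: tuple = ("spindle_power", "delta_power", "plv")
    ellipsoids: dict = field(default_factory=dict)


def cluster_states(table, max_components=10, seed=0, n_init=3,
                   max_iter=500, selection="saturation", saturation_q=2.0,
                   log_power=True) -> StateClusterModel:
    """Fit Gaussian mixtures for 1..max_components and select by AIC.

    Features are (spindle power, delta power, PLV); powers are log10
    transformed by default (they span orders of magnitude across regimes).
    EM runs ``max_iter`` iterations with ``n_init`` seeded restarts.  The
    component count is the smallest k whose AIC is within ``saturation_q``
    of any further improvement (AIC(k+1) - AIC(k) > -q); selection="argmin"
    takes the plain minimum.
    """
    df = table.frame if isinstance(table, SpectralFeatureTable) else table
    feats = np.column_stack([df["spindle_power"], df["delta_power"],
                             df["plv"]]).astype(float)
    if log_power:
        feats[:, 0] = np.log10(feats[:, 0] + 1e-12)
        feats[:, 1] = np.log10(feats[:, 1] + 1e-12)
    kmax = int(min(max_components, len(feats)))
    aic, models = [], []
    for k in range(1, kmax + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             max_iter=max_iter, n_init=n_init,
                             reg_covar=1e-6, random_state=seed)
        gm.fit(feats)
        aic.append(gm.aic(feats))
        models.append(gm)
    aic = np.asarray(aic)
    if selection == "argmin":
        k_sel = int(np.argmin(aic)) + 1
    else:
        k_sel = kmax
        for k in range(1, kmax):
            if aic[k] - aic[k - 1] > -saturation_q:
                k_sel = k
                break
    gm = models[k_sel - 1]
    return StateClusterModel(
        n_components=k_sel, means=gm.means_, covariances=gm.covariances_,
        weights=gm.weights_, aic=aic, assignments=gm.predict(feats))


def project_clusters(model: StateClusterModel, coordinates) -> dict:
    """Ellipsoid (centre, covariance, axes) per cluster in (ACh, HA, GABA).

    ``coordinates`` is (n_trials, 3) aligned with the fitted assignments.
    Clusters with fewer than 4 members are flagged degenerate and carry no
    ellipsoid.  Axis lengths are the square roots of the covariance
    eigenvalues (one standard deviation).
    """
    xyz = np.asarray(coordinates, dtype=float)
    if xyz.shape[0] != len(model.assignments):
        raise ValueError("every trial needs neuromodulator coordinates")
    out = {}
    for k in range(model.n_components):
        pts = xyz[model.assignments == k]
        if len(pts) < 4:
            out[k] = dict(degenerate=True, n=len(pts),
                          center=pts.mean(axis=0) if len(pts) else None)
            continue
        center = pts.mean(axis=0)
        cov = np.cov(pts.T)
        evals, evecs = np.linalg.eigh(cov)
        out[k] = dict(degenerate=False, n=len(pts), center=center, cov=cov,
                      axes=np.sqrt(np.maximum(evals, 0.0)), directions=evecs)
    model.ellipsoids = out
    return out
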