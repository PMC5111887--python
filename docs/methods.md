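# Methods

`tcsleep` is a conductance-based model of the thalamocortical system in
which three exogenous neuromodulator drives — acetylcholine (ACh),
histamine (HA) and GABA, each expressed as a percentage of the awake level —
control a small set of intrinsic and synaptic parameters and thereby switch
the network between the electrographic signatures of waking, N2 sleep
(recurring 7–15 Hz spindles), N3 sleep (a < 1 Hz slow oscillation of Up and
Down states) and REM sleep. The package also implements the signal-analysis
chain used to characterise those regimes (simulated LFP, windowed band
power, phase-locking value, spindle and slow-oscillation event detection,
and Gaussian-mixture clustering of dynamical regimes with AIC model
selection), and a set of preset computational experiments (minimal models,
species variants, propofol anesthesia, tonic-inhibition variants, and a
neuromodulator-grid sweep).

## Network and cell models

Four 1-D populations: 500 cortical pyramidal cells (PY), 100 cortical
interneurons (IN), 100 thalamic relay cells (TC) and 100 reticular cells
(RE). Connectivity is local and receiver-centric: a target cell receives
from every source cell within a fixed radius (in source-layer index units)
of its proportionally mapped centre; interior fan-in is 2r within a
population (no self-connections) and 2r+1 across populations. Default
radii: PY→PY 5, PY→IN 5, IN→PY 5, TC→PY 10, TC→IN 2, PY→TC 10, PY→RE 8,
TC→RE 8, RE→TC 8, RE→RE 5. Boundaries truncate by default (periodic
selectable).

Cortical cells are reduced two-compartment models. The dendrite carries the
capacitive dynamics and the currents K⁺-leak (ACh-scaled), Cl⁻/mixed leak,
fast Na⁺, persistent Na⁺, high-voltage-activated Ca²⁺, Ca²⁺-activated K⁺,
M-type K⁺ and all synaptic input; the axo-somatic compartment has zero
capacitance and carries fast Na⁺, delayed-rectifier K⁺ and persistent Na⁺.
Because the somatic persistent current is given a fast gating state
(τ = 0.2 ms), every somatic current is linear in the somatic voltage at
fixed gates and the algebraic balance g_cs(V_d − V_s) = −(I_Na + I_K +
I_Nap) is solved exactly in closed form each step. TC and RE cells are
single compartments with fast Na⁺/K⁺, a low-threshold (T-type) Ca²⁺
current, leaks, and — in TC cells only — the calcium-gated h-current.

Rate-function provenance is documented in `constants.py`: Traub-type spike
currents, the Huguenard–Prince and Destexhe T-current fits with Q10
correction, the Reuveni HVA Ca²⁺ current, the Mainen–Sejnowski M-current,
and the five-state Ca-gated h-current scheme (C↔O voltage gating,
P0+4Ca↔P1 calcium sensing, O+P1↔OL locking, conductance g·([O]+k·[OL]),
activation midpoint −75−shift mV with slope 5.5). The HA level acts
exclusively through the shift of that activation curve.

### Departures from the printed parameter set

Three printed values proved dynamically unworkable and are replaced by the
values of the model family this network descends from; each is a documented
package choice:

* **Cortical Cm = 0.75 µF/cm²** (printed: 0.075). The printed value gives a
  2.5 ms membrane time constant, making unitary PSPs 5–10× too large for
  any balanced regime.
* **Persistent Na⁺ activation saturates at 0.02** (Alzheimer-type fit).
  With a unit-saturating sigmoid the printed gNap = 2.0 mS/cm² creates a
  stable depolarised plateau.
* **Cortical GABA-A reversal −70 mV** (printed: −90 mV, retained for
  thalamic GABA-A). With −90 mV cortical IPSPs veto all recruitment and Up
  states cannot form.

Unprinted quantities exposed as parameters with documented defaults:
compartment areas (soma 2×10⁻⁶ cm², dendrite/soma ratio 165 for PY and 50
for IN), coupling resistance 5 MΩ, reversal potentials (E_Na +50, E_K −95,
cortical leak −55, TC leak −70, RE leak −77, E_h −40 mV, Ca²⁺ by Nernst),
and the spike-current voltage frames (cortex −50, TC −45, RE −50 mV). The
relay cell's raised spike threshold makes it fire on full low-threshold
bursts rather than on every rebound; the reticular cell's T-current
inactivation midpoint (−84 mV) keeps RE silent between spindles — these two
choices are what turn the spindle loop episodic rather than continuous.

## Synapses

AMPA, NMDA and GABA-A follow first-order activation schemes driven by a
0.5 mM transmitter pulse lasting 1 ms per evoked spike; GABA-B uses the
second-order G-protein cascade with quartic activation; NMDA carries the
standard sigmoidal Mg-block. Intracortical excitatory connections depress
(use fraction 0.07 per spike, 700 ms recovery). ACh scales AMPA conductance
on PY→PY, TC→PY and TC→IN (LACh); GABA level scales GABA conductance on
IN→PY, RE→RE and RE→TC (LGABA). Propofol mode divides the GABA-A closing
rate by the decay-time scale.

Printed synaptic conductances on intracortical projections are interpreted
per connection (matching the per-connection miniature quanta); on
projections involving the thalamus they are per-target totals shared across
the realized fan-in. The normalization is selectable per projection.

Miniature PSPs exist on PY→PY, PY→IN and IN→PY connections only and are
the model's sole noise source. Release on each connection is an
inhomogeneous Poisson process whose hazard is zero immediately after a
presynaptic spike and saturates at 1/250 per ms, sampled by thinning
against the saturating bound. In the network kernel each release adds a
fixed quantal open fraction (that of a brief 0.07 ms transmitter transient,
≈ 0.037) to a per-target aggregate that then decays with the exact synaptic
closing rate; release timing is resolved at 1 ms. The mini quantum and the
evoked pulse duration are the model's noise/recurrence calibration: they
were set so that the awake cortex fires sparsely (~1–2 Hz) from mini
coincidences while the N3 cortex sustains Up/Down alternation.

## Neuromodulator mapping

The stage tables are exact: AChPY (cortical K-leak ×) 1 / 1.25 / 1.8 / 0.85
for awake / N2 / N3 / REM; AChTC 1 / 1.25 / 2.0 / 0.85 (the N3 entry fills
a gap in the printed three-value list, consistent with the thalamus-only
deep-sleep preset); AChRE 1 / 0.8 / 0.5 / 1.15; LACh 1 / 1.25 / 2.0 / 0.8;
LGABA 1 / 1.15 / 1.3 / 0.75; ShiftHA −8 / −3 / −2 / 0 mV. Stage levels are
ACh 100/80/50/115 %, HA 100/40/30/10 %, GABA 100/115/130/75 %. Arbitrary
levels interpolate each scalar piecewise-linearly through its four stage
anchors along its controlling level (ACh for the K-leak and AMPA scalars,
HA for the h-current shift, GABA for LGABA), with linear extrapolation
inside documented bounds. Since the GABA anchors are proportional, LGABA
equals the GABA level /100 exactly.

Note one asymmetry in the source material: the h-current formula makes the
activation DECREASE with a more positive shift value (the half-activation
voltage is −75−shift); a stronger HA drive therefore means a more negative
shift. The minimal-model presets replicate their own caption values even
where those differ from the stage table (notably AChRE rising with sleep
depth in the thalamus-only presets).

"Increased by 150 %" for the propofol decay time is read as ×2.5 by
default, with ×1.5 selectable; the anesthesia verdicts hold under both.
The optional action of HA on K-leak (described in prose but absent from the
printed equations) is available behind `ha_k_leak_gain` and off by default.
Tonic-inhibition variants scale the IN→PY mini conductance per stage
(A: flat; B: 1 / 1.15 / 1.30 / 0.75; C: 1 / 0.85 / 0.70 / 1.25).

## Numerical scheme

Fixed step dt = 0.02 ms. Voltage-dependent gates relax exactly
exponentially using (x∞, e^(−dt/τ)) lookup tables (0.1 mV grid, linear
interpolation); membrane voltages take an implicit-Euler step with
conductances frozen at the current gates (unconditionally stable); slow
states (Ca pools, h-current scheme, G-protein cascade, depression recovery)
use forward Euler. The zero-capacitance soma is solved in closed form.
Spikes are somatic upward crossings of 0 mV with a 2 ms refractory;
voltages are recorded at 1 kHz. A single seeded numba RNG stream with a
fixed loop order makes runs bit-reproducible; checkpointed continuation
reproduces the dynamics exactly (spike timestamps can differ in the last
floating-point bit across the resume boundary). Halving dt moves isolated-
cell spike times by well under a millisecond (see the convergence tests).

## Analysis chain

The simulated LFP is the mean dendritic voltage of a PY group (all 500, or
groups of 100 for the five-channel analyses; somatic recording is
selectable). Band power integrates Hann-window FFT periodograms
(rectangular window selectable for exact Parseval checks) over the band
presets delta 0.5–4 / spindle 7–15 Hz (model), 0.2–4 / 8–15 Hz (animal),
0.01–2 / 9–17 Hz (human). The PLV band-filters both channels (0.5–20 Hz),
extracts analytic-signal phases, discards 5 % edge transients and takes the
modulus of the mean unit phasor of the phase difference.

The spindle detector smooths the 7–15 Hz envelope over 100 ms and scores
episodes with the standard dual-threshold rule: detection where the
envelope exceeds 2× the epoch median, boundaries where it falls back below
1.2× the median, gaps under 0.3 s merged, episodes under 0.4 s discarded.
Because thresholds are relative to the epoch's own envelope, a pure
amplitude rescaling leaves detections unchanged. The slow-oscillation
detector takes half-waves of the delta-filtered signal between zero
crossings, keeps alternations whose amplitude exceeds the 60th percentile
and whose half-wave durations fall in the slow range, and reports episode
frequency from the mean period.

Regime clustering fits full-covariance Gaussian mixtures to (log spindle
power, log delta power, PLV) for 1…10 components (EM, 500 iterations,
seeded restarts) and selects the smallest count whose AIC is within q = 2
of any further improvement (plain argmin selectable). Cluster projections
to neuromodulator space use member means and covariance eigendecomposition;
clusters with fewer than 4 members are flagged degenerate.

## What the model reproduces, and known limitations

Under the default calibration the full network shows: sparse awake firing
(PY ≈ 1–2 Hz, IN ≈ 1–3 Hz; a brief relay stimulation evokes a transient
response); N2 with spindle episodes recurring every ≈ 4–8 s whose full
events last 2–3 s — brief aborted ignitions also appear in the detector
output, so the *median* detected duration is ≈ 1.4–1.8 s, slightly below
the 2–5 s the detector is meant to bracket; N3 with a delta-dominated LFP
peaking at ≈ 0.6–0.9 Hz; and an activated, low-power REM-like state. The
awake thalamus is quieter than in sleep but not perfectly silent: occasional
short spindle-band events occur.

The minimal-model dissections reproduce the expected asymmetry (thalamic
ACh+HA reduction suffices for spindles; cortical changes alone do not;
cortical ACh reduction, via its two joint actions, is required for the slow
oscillation; AMPA-only gives an activated state, K-leak-only a quiescent
one), the spindle–delta correlation flips sign between moderate (75 %) and
strong (45 %) ACh reduction, and the anesthesia contrast requires combined
ACh/HA reduction on top of the lengthened GABA-A decay.

The synthetic (simulated) data differ from real recordings in ways any
user should keep in mind: the LFP is a population-mean membrane voltage,
not a volume-conducted field; there are no measurement noise, artifacts,
non-stationarities, or electrode geometry; stage transitions are exogenous
steps, not gradual neuromodulator drifts; and the miniature-PSP process is
the only stochasticity. Passing tests therefore demonstrate properties of
the model and analysis code, not claims about any particular recording.

Problem sizes used by the test suite and the acceptance script are stated
in their docstrings: single-condition claims run the full network (20–90 s
segments); multi-run protocols use the desk-scale surrogate, whose
thalamus — lacking spatial structure — oscillates continuously in N2 rather
than in discrete episodes, which is why episode statistics are always
computed on the full network.
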