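# tcsleep

A biophysical thalamocortical network model of sleep-stage transitions
under neuromodulatory control, with the signal-analysis chain used to
characterise the resulting brain rhythms.

## The scientific problem

Within one ultradian sleep cycle the brain moves through waking, light
NREM sleep (N2, marked by 7–15 Hz **sleep spindles**), deep NREM sleep
(N3, marked by the < 1 Hz **slow oscillation** of cortical Up and Down
states) and REM sleep. These stages coincide with large changes in the
levels of acetylcholine (ACh), histamine (HA) and GABA. `tcsleep`
implements a conductance-based network — 500 two-compartment pyramidal
cells (PY) and 100 interneurons (IN) in cortex, 100 relay (TC) and 100
reticular (RE) cells in thalamus — in which those three neuromodulator
levels act through exactly four parameter families:

* ACh sets the K⁺-leak conductance (`AChPY·g_KL` in PY/IN, `AChTC·g_KL`
  in TC, `AChRE·g_KL` in RE — note the inverted sign of action on RE) and
  the AMPA strength `I_AMPA = L_ACh · g_syn · [O] · (V − E_AMPA)`;
* HA shifts the activation of the relay-cell h-current,
  `h∞(V) = 1/(1 + e^{(V+75+Shift_HA)/5.5})`, whose open state can be locked
  by intracellular Ca²⁺ (the five-state scheme C↔O, P0+4Ca↔P1, O+P1↔OL
  with conductance `g_h([O] + k[OL])`) — the mechanism that makes spindles
  wax, wane and stay refractory;
* GABA scales the GABAergic conductances, `I_GABA = L_GABA · g_syn · [O] ·
  (V − E_GABA)`, and (in the tonic-inhibition variants) the miniature-IPSP
  quanta.

Miniature PSPs — Poisson quanta whose hazard is suppressed after each
presynaptic spike, `rate(Δt) = (2/(1+e^{−Δt/20}) − 1)/250` per ms — are
the model's only noise source and the igniters of cortical Up states.

The analysis layer computes the simulated LFP (group-mean PY voltage),
windowed delta/spindle band power, phase-locking values between LFP
channels, spindle and slow-oscillation episodes, spindle–delta power
correlations, and Gaussian-mixture clustering (AIC-selected component
count) of dynamical regimes over the (ACh, HA, GABA) space.

## A worked example

Run the desk-scale network (100/20/20/20 cells) through one N3 segment and
measure what dominates the field potential:

```python
import numpy as np
from scipy import signal
import tcsleep as T

net = T.assemble(T.NetworkSpec.reduced())
cfg = T.SimConfig(duration_s=20.0, seed=3, schedule="N3", discard_s=4.0)
res = T.run(cfg, net)

print(f"PY rate: {res.firing_rate('PY'):.2f} Hz, "
      f"IN rate: {res.firing_rate('IN'):.2f} Hz")
x = res.py_voltage().mean(axis=1)
f, p = signal.welch(x - x.mean(), fs=res.fs, nperseg=8192)
m = (f >= 0.2) & (f <= 30)
print(f"dominant LFP peak: {f[m][np.argmax(p[m])]:.2f} Hz")
```

Output (seed 3):

```
PY rate: 2.69 Hz, IN rate: 2.60 Hz
dominant LFP peak: 0.61 Hz
```

The pyramidal population alternates between active Up states and silent
Down states about once per 1–2 seconds, so the LFP spectrum peaks well
below 1 Hz — the slow oscillation. Running the same two lines with
`schedule="awake"` gives sparse firing (≈ 1 Hz) and no slow peak;
`schedule="N2"` on the full network (`NetworkSpec.default()`) produces
recurring spindle episodes instead — see `examples/` for one short
narrative script per capability (stage battery, spindle detection,
minimal models, propofol contrast, regime clustering, PLV).

A thin command line exists for shell use:

```bash
tcsleep simulate --stage awake,N2,N3,REM --duration 20 --reduced --out run.h5
tcsleep analyze run.h5 --events spindle
tcsleep experiment list
```

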