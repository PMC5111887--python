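"""Anesthesia contrast: lengthening the GABA-A decay alone is not enough.

The combined model (decay x2.5 plus ACh/HA reduction) shows a slow
oscillation and more spindle-band power than natural SWS; the decay-only
control shows neither.
"""
from tcsleep.experiments import propofol_comparison

out = propofol_comparison(seed=1, scale="reduced", stage_s=16.0)
for cond in ("combined", "tau_only", "natural_sws"):
    d = out[cond]
    print(f"{cond:<12} spindle-band {d['spindle_band']:6.2f}  "
          f"delta {d['delta_band']:6.2f}  slow osc: {d['so']}")
print(f"combined-anesthesia verdict: {out['verdict_combined']}")
print(f"decay-only control verdict:  {out['verdict_tau_only']}")
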