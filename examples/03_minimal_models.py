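"""Dissect which side of the loop each rhythm needs.

Thalamic ACh+HA reduction alone suffices for spindles; the same changes in
cortex do not produce them.  Cortical ACh reduction alone brings the slow
oscillation; its two partial actions (AMPA-only, K-leak-only) do not.
"""
from tcsleep.experiments import run_preset

for name in ("minimal-thalamic-achha", "minimal-cortical-n2",
             "minimal-cortical-ach-n3", "minimal-ampa-only",
             "minimal-kleak-only"):
    _, v = run_preset(name, seed=1, scale="reduced", stage_s=12.0)
    public = {k: x for k, x in v.items()
              if not k.startswith("_") and k not in ("preset", "seed")}
    print(f"{name:<26} {public}")
print("\n'pass' compares each verdict against the expected dissection "
      "outcome for that manipulation.")
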