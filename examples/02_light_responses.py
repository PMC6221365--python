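"""Shine a 2-s light step on modes 1-3 and compare their responses.

The photoreceptor channel high-passes the light level with a mode-specific
adaptation time constant and polarity.  Mode 1 is a slowly adapting ON
unit (burst at light onset, slowing down), mode 2 a transient OFF unit
(silent in light, rebound burst at offset), mode 3 a sustained OFF unit
that fires in darkness and is suppressed by light.
"""

import numpy as np

from spikesim import UnitSpec, run_simulation

light = np.zeros(8000)
light[2000:4000] = 20.0  # light step, arbitrary light units

for mode in (1, 2, 3):
    log = run_simulation(
        [UnitSpec("u", mode=mode, light_trace=light)],
        duration=8000.0, dt=1.0, seed=0,
    )["u"]
    sp = log.spike_times()
    in_light = np.sum((sp >= 2000) & (sp < 4000))
    onset = np.sum((sp >= 2000) & (sp < 2200))
    offset = np.sum((sp >= 4000) & (sp < 4200))
    dark = np.sum(sp < 2000)
    print(f"mode {mode}: dark {dark:3d} | in light {in_light:3d} "
          f"(first 200 ms: {onset}) | 200 ms after offset {offset}")

print("\n-> mode 1 fires at onset then adapts; mode 2 bursts only at "
      "light OFF; mode 3 keeps a dark rate that light suppresses.")
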