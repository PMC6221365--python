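"""Step one model neuron through a current step and inspect its firing.

The unit is the two-variable Izhikevich model (membrane potential v,
recovery u).  Each preset "mode" pairs a firing phenotype with a
photoreceptor personality; here we drive the regular-spiking preset with
a constant current and watch spike-frequency adaptation: the first
inter-spike intervals are short, then lengthen to a steady value.
"""

import numpy as np

from spikesim import get_mode, preset_modes, resting_state, simulate_unit

print("shipped presets:")
for i, p in enumerate(preset_modes(), start=1):
    print(f"  mode {i}: {p.label}  (a={p.a}, b={p.b}, c={p.c}, d={p.d})")

params = get_mode(1)
drive = np.zeros(3000)
drive[500:] = 10.0  # model current units, switched on at t = 500 ms

v, spikes = simulate_unit(params, drive, dt=1.0, state=resting_state(params))
isi = np.diff(spikes)

print(f"\n{len(spikes)} spikes over {len(drive)/1000:.1f} s of drive I=10")
print("first five inter-spike intervals (ms):", isi[:5])
print("steady-state interval (ms):", isi[-1])
print("-> the interval lengthens after onset: spike-frequency adaptation.")
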