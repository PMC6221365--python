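"""Estimate linear filters by reverse correlation against binary noise.

The stimulus port delivers 50-Hz binary light noise to the photoreceptor.
Averaging the stimulus preceding each spike gives the spike-triggered
average (STA); cross-correlating the hyperpolarised (subthreshold)
membrane potential with the stimulus gives the filter of the generator
potential.  With slow photo adaptation the subthreshold filter is
monophasic (low-pass); retuning the same unit to fast adaptation makes it
biphasic (band-pass).
"""

import numpy as np

from spikesim.protocols import reverse_correlation

res = reverse_correlation(seed=0)
for label in ("slow", "fast"):
    tab = res.tables[f"filters_{label}"]
    print(f"{label} photo adaptation ({res.summary[f'{label}_n_spikes']} spikes):")
    print(tab.head(6).round(3).to_string(index=False))
    print(f"  subthreshold sign changes: "
          f"{res.summary[f'{label}_sub_sign_changes']} "
          f"({'monophasic/low-pass' if res.summary[f'{label}_sub_sign_changes'] == 0 else 'biphasic/band-pass'})\n")
print("-> one photoreceptor time constant flips the subthreshold filter "
      "from low-pass to band-pass.")
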