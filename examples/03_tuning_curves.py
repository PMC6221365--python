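"""Amplitude tuning: sweep the input gain of a pulsed drive.

The internal stimulus generator feeds square pulses into the analog-in
port; sweeping the gain dial scales the current step each pulse delivers.
Per gain we measure spikes per pulse, instantaneous rate (1 / first
inter-spike interval), first-spike latency, and first-spike jitter across
pulses.  Noise-free, the response is perfectly repeatable (zero jitter);
adding membrane noise distorts spike timing before it changes counts.
"""

from spikesim.protocols import amplitude_tuning

res = amplitude_tuning(seed=0)
print(res.tables["tuning"].round(2).to_string(index=False))
print(f"\nwith membrane noise at gain 8: first-spike jitter "
      f"{res.summary['noisy_jitter_ms']:.2f} ms "
      f"(noise-free jitter is 0), spikes/pulse "
      f"{res.summary['noisy_mean_count']:.2f} vs "
      f"{res.summary['clean_mean_count']:.2f} clean")
print("-> count grows and latency shrinks with gain; noise jitters "
      "timing while counts barely move.")
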