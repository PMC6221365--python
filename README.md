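# spikesim

A software spiking-neuron teaching lab: simulate Izhikevich model neurons
with the input channels of a classroom electrophysiology rig — a
photoreceptor with adaptation, two input synapses, membrane noise, a
static holding current and a built-in stimulus generator — wire units
into small networks, log every sample to CSV, and analyse the recordings
with the classic tools of sensory neuroscience (tuning curves, phase
locking, stochastic resonance, spike-triggered averaging).

It is aimed at students and instructors of neural coding who want to run
"experiments" on a faithful, fully observable model cell — and at anyone
who needs a compact, deterministic spiking testbed with a clean Python
API.

## The model

Each unit integrates the two-variable Izhikevich neuron

```
dv/dt = 0.04 v² + 5 v + 140 − u + I
du/dt = a (b v − u)
if v ≥ 30 mV:  v ← c,  u ← u + d        (spike + reset)
```

with `v` the membrane potential (mV), `u` a recovery variable, and `I`
the summed drive from six channels: photoreceptor, synapse 1, synapse 2,
analog-in, noise and static current (`I_total = Σ I_channel`, logged per
channel).  Five preset **modes** pair firing phenotypes (regular spiking,
bursting, fast spiking, ...) with photoreceptor personalities (ON/OFF
polarity, slow/fast adaptation, dark current):

| mode | phenotype |
|------|-----------|
| 1 | slowly adapting light-ON unit (regular spiking) |
| 2 | transient light-OFF unit with rebound bursts |
| 3 | sustained light-OFF unit, elevated dark rate |
| 4 | fast-spiking ON unit |
| 5 | intrinsically bursting ON unit |

The photoreceptor high-passes the light level `L` through a first-order
adaptation state `A` (`τ_adapt` per mode): `I_photo = ±(L − A) + I_dark`.
Synapses add an exponentially decaying current (jump `g`, decay
`τ_syn` = 10 ms) per presynaptic spike.  The stimulus generator produces
square pulses (50 % duty cycle) or 50-Hz binary noise.

The analysis toolkit implements spike detection, stimulus-aligned rasters
and averages, amplitude tuning (count, instantaneous rate, latency,
first-spike jitter), vector strength `VS = |Σ exp(iθ_k)|/N` with a
phase-shuffled significance null, stochastic-resonance noise sweeps, the
spike-triggered average, and subthreshold (response-weighted) linear
filters.

## A worked example

```bash
python examples/02_light_responses.py
```

```
mode 1: dark   0 | in light  18 (first 200 ms: 9) | 200 ms after offset 0
mode 2: dark   0 | in light   0 (first 200 ms: 0) | 200 ms after offset 10
mode 3: dark  46 | in light   0 (first 200 ms: 0) | 200 ms after offset 9
```

A 2-s light step is delivered to each of modes 1–3.  Mode 1 fires 18
spikes during the light, half of them in the first 200 ms — an ON
response that adapts.  Mode 2 is silent in light but fires a 10-spike
rebound burst within 200 ms of light OFF.  Mode 3 fires 46 spikes in the
2 s of darkness before the step (a 23-Hz dark rate) and is silenced by
the light.

The other examples follow the same pattern, one capability each:
`01_single_neuron.py` (presets and spike-frequency adaptation),
`03_tuning_curves.py` (gain sweep; timing jitter under noise),
`04_stochastic_resonance.py` (volley coding; noise-assisted phase
locking), `05_network_cpg.py` (synaptic gain sweep; two-unit central
pattern generator), `06_reverse_correlation.py` (STA and subthreshold
filters from binary noise).

## Command line

```bash
spikesim simulate config.yaml --out run/        # units+wiring from YAML → CSVs + manifest
spikesim analyze vs run/u0.csv --period 200     # phase locking of a recording
spikesim protocol volley_sr --seed 1 --check    # scripted figure experiment + assertions
```

Recording CSVs carry one row per sample (`t, v, i_total`, the six current
channels, `stimulus`, `spike`, synapse-event flags) and round-trip
bit-exactly; every run writes a manifest from which it can be reproduced
exactly.

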