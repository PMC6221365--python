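# Methods

## Model

Each unit is the two-variable Izhikevich phenomenological neuron

    dv/dt = 0.04 v² + 5 v + 140 − u + I
    du/dt = a (b v − u)

with a hard reset at the 30 mV cutoff (`v ← c`, `u ← u + d`; a step that
reaches exactly 30 counts as a spike).  `v` is in mV, time in ms, and all
currents in the dimensionless "model units" that match the mV-scaled
equations — no physical pA calibration is claimed.  The subthreshold
rest state under a holding current `I₀` is the lower root of
`0.04 v² + (5 − b) v + 140 + I₀ = 0` with `u = b v`; for `b = 0.2`,
`I₀ = 0` this is `(v, u) = (−70, −14)`, which the integrator preserves
exactly.

### Preset modes

Five presets map canonical parameter sets to sensory phenotypes.  The
phenotypes — not the constants — are the contract; the constants are the
standard published sets for the named firing classes:

| mode | a | b | c | d | photo | τ_adapt (ms) | dark current |
|---|---|---|---|---|---|---|---|
| 1 regular spiking | 0.02 | 0.2 | −65 | 8 | ON | 500 | 0 |
| 2 bursting (chattering reset) | 0.02 | 0.2 | −50 | 2 | OFF | 50 | 0 |
| 3 regular spiking, dark-active | 0.02 | 0.2 | −65 | 8 | OFF | 5000 | 10 |
| 4 fast spiking | 0.1 | 0.2 | −65 | 2 | ON | 50 | 0 |
| 5 intrinsically bursting | 0.02 | 0.2 | −55 | 4 | ON | 500 | 0 |

Mode 3's very long adaptation constant makes its light suppression
effectively sustained on classroom timescales, and its dark current of 10
gives a maintained ~22 Hz rate in darkness.  Modes 4–5 round out the
table with the two remaining classic phenotypes (high sustained rates;
doublet/burst onset).

### Integration

The update is forward Euler with two half-steps for `v` per full step for
`u` — the standard scheme for this model — applied on internal substeps
capped at 0.02 ms regardless of the sampling step `dt` (default 1 ms),
with `v` clamped at the cutoff before the recovery update whenever a
substep crosses it.  Plain 1-ms Euler distorts this model badly once
rates are high: the quadratic upstroke overshoots in one step and feeds
an inflated `v` into the `u` update, and spike times quantise to the
grid; we measured deficits of tens of spikes per 10 s for the
fast-spiking preset.  With substepping + clamping, 10-s spike counts at
`dt = 1 ms` match an independent single-step Euler reference at
`dt = 0.01 ms` exactly for every preset at the package's standard test
drive (a constant step of 5 model units), and halving `dt` leaves counts
unchanged.  The scalar kernel is numba-jitted with an
arithmetic-identical pure-Python fallback.  Sub-step spike-time
interpolation is deliberately not attempted; spike times live on the
sampling grid.

## Input channels

* **Photoreceptor** — adaptation state `A` relaxes to the light level `L`
  with time constant `τ_adapt` (exact exponential update);
  `I_photo = polarity · (L − A) + I_dark`.  "Slow" is 500 ms, "fast"
  50 ms; the one parameter reproduces ON-adapting, OFF-rebound and
  sustained-OFF behaviour and the low-pass→band-pass filter change.
* **Synapses** — each presynaptic event (delivered one sampling step
  after the source spike) adds an instantaneous jump of the signed gain,
  decaying exponentially with `τ_syn = 10 ms`; contributions sum
  linearly.
* **Noise** — zero-mean Gaussian, i.i.d. per sample, SD set by the dial.
  Per-unit RNG streams are derived from the master seed plus a CRC of the
  unit id, so adding a unit never perturbs another unit's noise.
* **Stimulus generator** — square pulses (high phase starts each period;
  duty 0.5 by default) or binary noise held constant within frames
  (50 Hz default), equiprobable two levels: symmetric ±amplitude for
  analysis, {0, amplitude} when driving the light path.
* All channels are summed per sample into `I_total`, and every component
  is logged.

## Recording format

One CSV per unit: `t, v, i_total, i_photo, i_syn1, i_syn2, i_analog,
i_noise, i_static, stimulus, spike, syn1_event, syn2_event`, one row per
sample, comma-separated, '.' decimal, no quoting.  Spike samples log
`v = 30` (the cutoff); the dynamical state continues from the reset
value.  Reading uses round-trip float parsing so write→read→write is
byte-identical.  Readers tolerate any column subset containing `t` and
`v`; non-uniform time spacing is a format error naming the first
offending row, and rows violating `i_total = Σ` components raise a
warning, not an error.

## Analysis conventions

* **Spike detection** — logged flags are authoritative; the fallback for
  bare `t, v` logs is upward crossings of 0 mV with a 2-ms refractory
  merge.
* **Filters** — reported on the stimulus frame grid, most-recent lag
  first (the time-reversed impulse response).  The STA is in stimulus
  units; the subthreshold filter is normalised by the stimulus variance
  so an identity system yields a unit impulse.  Shape classification
  counts sign changes among lobes exceeding 15 % of the peak magnitude
  (a noise-floor guard fixed a priori).
* **Phase** — phase 0 at the stimulus rising edge;
  `VS = |Σ exp(iθ_k)| / N`.  Significance uses a seeded phase-shuffled
  null (1000 uniform-phase surrogates, 95th percentile) rather than a
  parametric test.
* **Tuning** — instantaneous rate is 1/(first inter-spike interval) per
  trial; latency is the first spike after onset; jitter is the SD of
  latency across trials; trials without spikes contribute zero count and
  undefined (NaN) latency.

## Protocols and their design choices

Protocol constants were chosen once to put each phenomenon in its
textbook regime and are printed in every bundle manifest.

* **Standard current step** — 5 model units for 10 s: modest
  suprathreshold drive at which all five presets show their phenotypes
  (the bursting preset's intervals split cleanly: <20 ms within bursts,
  >50 ms between, none in 20–50 ms).
* **Amplitude tuning** — 2-Hz square pulses via analog-in, gains 0–12,
  8 pulses per gain; noisy variant at gain 8 with noise SD 1.5.
* **Volley / stochastic resonance** — volley: 20-Hz drive of amplitude 5
  (the unit follows every other cycle).  SR: 5-Hz drive of amplitude 3.5
  with a −1 holding current (verified spike-free without noise), noise
  SDs 0, 0.5, 1, 2, 4, 8, 20 seeds each.
* **Synaptic gain sweep** — source held at drive 8, target at 5, so the
  two units fire at different rates; with identical drives the
  deterministic units fire in near-synchrony and synaptic input lands in
  the target's refractory period, flattening the sweep.
* **CPG** — two mode-2 units, mutual excitatory gain 4, plus a static
  depolarisation of 4.5 on both (dial 4) and a 300-ms kick to one unit.
  The background drive is essential: with purely additive excitatory
  synapses, a pair of bursting units is bistable between silence and
  tonic locking — episodic bursting requires a source of re-ignition
  after each adaptation-terminated episode, which the static current
  provides.  The result is ~5 bursts/s sustained in both units
  indefinitely.
* **Reverse correlation** — 50-Hz binary light noise of amplitude 14 for
  120 s.  The spike-level STA comes from a spiking run with 1.0 SD of
  membrane noise (which linearises spike generation).  The subthreshold
  filter is measured on the *generator potential*: a second run
  hyperpolarised below threshold (hold −14, verified spike-free),
  because the spiking trace contaminates the filter with spike-reset
  afterpotentials (a spurious negative lobe of ~20–30 % of peak for the
  slow variant).  Hyperpolarising to expose the generator potential is
  itself a standard use of the static-current dial.

## What the simulations do and do not show

The generators emulate the study conditions of a bench device: perfectly
known stimuli, Gaussian membrane noise, exactly linear synapses, and a
noiseless photoreceptor.  Real recordings add drift, electrode noise,
synaptic depression and cell-to-cell variability that none of the tests
here probe; passing them shows the algorithms are correct on their own
model, not that the model captures any particular biological cell.  The
spike-level filter of the fast photo variant is reported but its exact
lobe count is sensitive to drive and noise settings and is treated as
exploratory.

## Problem sizes

Defaults keep every protocol under ~2 s and the whole acceptance run
under a minute on one core: 10-s single-unit runs, 20-s volley, 120 SR
trials of 10 s, 22-s CPG, two 120-s reverse-correlation runs, and a
40 000-frame linear-nonlinear-Poisson surrogate (~4000 spikes) for
filter-recovery validation.  All are comfortably past the convergence
needs of the statistics they feed (e.g. the STA noise floor at 4000
spikes is ~0.016 per lag against lobe amplitudes of order 0.5).

## Known limitations

* Fixed shared `dt`; the hardware's variable loop rate is not emulated.
* Spike times quantise to the sampling grid (no sub-step interpolation).
* One spike flag per sample: intervals shorter than `dt` cannot be
  represented at coarse sampling.
* The noise dial is white Gaussian current noise; real membrane noise is
  coloured and state-dependent.
* TTL pulse width is ignored: a presynaptic pulse is one event at its
  rising edge.
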