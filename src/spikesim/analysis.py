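"""Neural-coding measurements on recording logs.

The toolkit mirrors what a student would measure on a real cell: spike
detection, stimulus-aligned rasters and averages, amplitude tuning
(count, instantaneous rate, latency, first-spike jitter), phase locking
(vector strength), stochastic-resonance noise sweeps, and linear-filter
estimation by reverse correlation at the spike level (the spike-triggered
average) and at the subthreshold level (response-weighted average).

All functions are pure: the same log in gives the same numbers out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import RecordingLog

__all__ = [
    "TuningCurve",
    "LinearFilter",
    "AlignedTrials",
    "detect_spikes",
    "align_to_stimulus",
    "tuning_curves",
    "vector_strength",
    "vs_null_threshold",
    "stochastic_resonance_sweep",
    "sta",
    "subthreshold_filter",
    "count_sign_changes",
]

#: Refractory merge window (ms) for threshold-based spike detection.
_REFRACTORY_MS = 2.0


class UndefinedResultError(ValueError):
    """The requested quantity is undefined for this input (e.g. no spikes)."""


# ---------------------------------------------------------------------------
# Spike detection and alignment
# ---------------------------------------------------------------------------

def detect_spikes(log: RecordingLog) -> np.ndarray:
    """Spike times (ms), strictly increasing.

    Logged spike flags are authoritative when present.  For flag-less logs
    (e.g. a bare t,v trace from an external device) spikes are upward
    crossings of 0 mV, with crossings closer than 2 ms merged into one
    event.
    """
    if "spike" in log.data.columns:
        return log.spike_times()
    v = log.v
    t = log.t
    up = np.nonzero((v[1:] >= 0.0) & (v[:-1] < 0.0))[0] + 1
    times = []
    for i in up:
        if not times or t[i] - times[-1] >= _REFRACTORY_MS:
            times.append(t[i])
    return np.asarray(times, dtype=float)


@dataclass
class AlignedTrials:
    """Stimulus-aligned response segments: one row per retained onset."""

    window_t: np.ndarray            # time within window (ms from onset)
    v_trials: np.ndarray            # (n_trials, n_window) membrane potential
    spike_rasters: list[np.ndarray]  # spike times relative to each onset
    v_mean: np.ndarray
    n_dropped: int

    @property
    def n_trials(self) -> int:
        return self.v_trials.shape[0]


def align_to_stimulus(log: RecordingLog, onsets, window: float) -> AlignedTrials:
    """Cut the log into per-onset segments of length ``window`` ms and
    average them.  Onsets whose window does not fit inside the log
    (including negative onsets) are dropped and counted."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("at least one onset is required")
    t = log.t
    v = log.v
    n_w = int(round(window / log.dt))
    if n_w < 1:
        raise ValueError(f"window {window} ms shorter than one step")
    spikes = detect_spikes(log)

    rows, rasters, kept = [], [], 0
    for onset in onsets:
        i0 = int(round((onset - t[0]) / log.dt))
        if onset < t[0] or i0 + n_w > len(t):
            continue
        rows.append(v[i0:i0 + n_w])
        rel = spikes[(spikes >= onset) & (spikes < onset + window)] - onset
        rasters.append(rel)
        kept += 1
    if kept == 0:
        raise UndefinedResultError("no onset leaves a full window inside the log")
    v_trials = np.vstack(rows)
    return AlignedTrials(
        window_t=np.arange(n_w) * log.dt,
        v_trials=v_trials,
        spike_rasters=rasters,
        v_mean=v_trials.mean(axis=0),
        n_dropped=int(onsets.size - kept),
    )


# ---------------------------------------------------------------------------
# Amplitude tuning
# ---------------------------------------------------------------------------

@dataclass
class TuningCurve:
    """Per swept value: mean spikes per stimulus, instantaneous rate
    (1 / first inter-spike interval, Hz), first-spike latency (ms) and
    first-spike jitter (SD of latency across trials, ms).

    Trials without spikes contribute zero count and leave latency/rate
    undefined (NaN)."""

    values: np.ndarray
    spike_count: np.ndarray
    rate_inst: np.ndarray
    latency: np.ndarray
    jitter: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "value": self.values,
            "spike_count": self.spike_count,
            "rate_inst_hz": self.rate_inst,
            "latency_ms": self.latency,
            "jitter_ms": self.jitter,
        })


def _trial_metrics(rasters: list[np.ndarray]):
    counts = np.array([len(r) for r in rasters], dtype=float)
    lats = np.array([r[0] if len(r) else np.nan for r in rasters])
    rates = np.array([
        1000.0 / (r[1] - r[0]) if len(r) >= 2 else np.nan for r in rasters
    ])
    ok = ~np.isnan(lats)
    jitter = float(np.std(lats[ok], ddof=1)) if ok.sum() >= 2 else np.nan
    return (
        float(counts.mean()),
        float(np.nanmean(rates)) if np.any(~np.isnan(rates)) else np.nan,
        float(np.nanmean(lats)) if ok.any() else np.nan,
        jitter,
    )


def tuning_curves(values, simulate, n_repeats: int = 5) -> TuningCurve:
    """Amplitude tuning over a swept parameter (typically the input gain).

    ``simulate(value, repeat)`` must return the spike times of one trial
    relative to stimulus onset (any sequence of ms values).  Requires at
    least 3 swept values and 5 repeats per value.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("a sweep needs at least 3 values")
    if n_repeats < 5:
        raise ValueError("a sweep needs at least 5 repeats per value")
    count, rate, lat, jit = [], [], [], []
    for val in values:
        rasters = [np.asarray(simulate(val, rep), dtype=float) for rep in range(n_repeats)]
        c, r, l, j = _trial_metrics(rasters)
        count.append(c)
        rate.append(r)
        lat.append(l)
        jit.append(j)
    return TuningCurve(
        values=values,
        spike_count=np.array(count),
        rate_inst=np.array(rate),
        latency=np.array(lat),
        jitter=np.array(jit),
    )


# ---------------------------------------------------------------------------
# Phase locking and stochastic resonance
# ---------------------------------------------------------------------------

def vector_strength(spike_times, period: float):
    """Mean resultant length of spike phases relative to a periodic
    stimulus (phase 0 at each rising edge).

    Returns ``(vs, mean_phase)``; VS is 1 for perfect locking and ~0 for
    uniform phases.  Raises on an empty spike train.
    """
    times = np.asarray(spike_times, dtype=float)
    if times.size == 0:
        raise UndefinedResultError("vector strength undefined for zero spikes")
    if not period > 0:
        raise ValueError(f"period must be > 0, got {period}")
    phases = 2.0 * np.pi * ((times % period) / period)
    z = np.exp(1j * phases).mean()
    return float(np.abs(z)), float(np.angle(z))


def vs_null_threshold(
    n_spikes: int,
    n_resamples: int = 1000,
    q: float = 95.0,
    seed: int = 0,
) -> float:
    """The ``q``-th percentile of vector strength under the phase-shuffled
    null (spike phases i.i.d. uniform), for ``n_spikes`` spikes.

    Used as the significance threshold for observed phase locking."""
    if n_spikes < 1:
        raise UndefinedResultError("null undefined for zero spikes")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_resamples, n_spikes))
    vs = np.abs(np.exp(1j * phases).mean(axis=1))
    return float(np.percentile(vs, q))


def stochastic_resonance_sweep(
    amplitudes,
    run_trial,
    period: float,
    n_seeds: int = 20,
) -> pd.DataFrame:
    """Noise sweep around a subthreshold periodic drive.

    ``run_trial(amplitude, seed)`` must return the spike times of one run.
    ``amplitudes`` must be sorted ascending and start at 0; the zero-noise
    runs are required to produce no spikes (the drive must be verified
    subthreshold), else a precondition error is raised.

    Returns a frame with one row per amplitude: mean spike count and mean
    vector strength across seeds (NaN where no seed produced spikes), plus
    a ``best_amplitude`` attribute — the amplitude maximising mean VS.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size < 2 or amplitudes[0] != 0.0:
        raise ValueError("amplitudes must start at 0 and contain >= 2 values")
    if np.any(np.diff(amplitudes) <= 0):
        raise ValueError("amplitudes must be sorted ascending")

    rows = []
    for amp in amplitudes:
        counts, vss = [], []
        for s in range(n_seeds):
            spikes = np.asarray(run_trial(amp, s), dtype=float)
            if amp == 0.0 and spikes.size > 0:
                raise ValueError(
                    "protocol is not subthreshold: spikes occurred at zero noise"
                )
            counts.append(len(spikes))
            if spikes.size:
                vss.append(vector_strength(spikes, period)[0])
        rows.append({
            "amplitude": amp,
            "mean_spike_count": float(np.mean(counts)),
            "mean_vs": float(np.mean(vss)) if vss else np.nan,
            "n_seeds_with_spikes": len(vss),
        })
    out = pd.DataFrame(rows)
    with_vs = out.dropna(subset=["mean_vs"])
    out.attrs["best_amplitude"] = (
        float(with_vs.loc[with_vs["mean_vs"].idxmax(), "amplitude"])
        if len(with_vs) else np.nan
    )
    return out


# ---------------------------------------------------------------------------
# Reverse correlation
# ---------------------------------------------------------------------------

@dataclass
class LinearFilter:
    """A linear filter on the stimulus frame grid, most-recent lag first
    (the time-reversed impulse response)."""

    lags_ms: np.ndarray
    values: np.ndarray
    level: str                     # "spike" or "subthreshold"
    n_spikes: int | None = None
    n_excluded: int = 0
    uninformative: bool = False


def sta(frame_values, frame_times, spike_times, window: float) -> LinearFilter:
    """Spike-triggered average: the mean stimulus segment preceding each
    spike, on the stimulus frame grid.

    Spikes earlier than one full window after the start are excluded and
    counted in ``n_excluded``.  A zero-variance stimulus yields a filter
    flagged ``uninformative``.
    """
    frames = np.asarray(frame_values, dtype=float)
    f_t = np.asarray(frame_times, dtype=float)
    spikes = np.asarray(spike_times, dtype=float)
    if frames.size != f_t.size:
        raise ValueError("frame_values and frame_times must have equal length")
    if frames.size < 2:
        raise ValueError("need at least two stimulus frames")
    frame_dt = f_t[1] - f_t[0]
    n_lags = int(round(window / frame_dt))
    if n_lags < 1:
        raise ValueError("window shorter than one stimulus frame")

    segs = []
    excluded = 0
    for t_sp in spikes:
        i = int(np.searchsorted(f_t, t_sp, side="right")) - 1
        if i < n_lags - 1 or i >= frames.size:
            excluded += 1
            continue
        segs.append(frames[i - n_lags + 1: i + 1][::-1])
    if not segs:
        raise UndefinedResultError("no spike leaves a full window of stimulus")
    values = np.mean(segs, axis=0)
    return LinearFilter(
        lags_ms=np.arange(n_lags) * frame_dt,
        values=values,
        level="spike",
        n_spikes=len(segs),
        n_excluded=excluded,
        uninformative=bool(np.ptp(frames) == 0),
    )


def subthreshold_filter(stimulus, v, window: float, dt: float) -> LinearFilter:
    """Response-weighted average at the subthreshold level: the
    cross-correlation of the mean-subtracted response with the stimulus,
    normalised by the stimulus variance so that an identity system (v a
    delayed copy of the stimulus) recovers a unit impulse at the delay.

    ``stimulus`` and ``v`` must be aligned, equal-length traces on a
    common grid of step ``dt`` ms; the stimulus is expected zero-mean and
    is re-centred defensively.
    """
    s = np.asarray(stimulus, dtype=float)
    r = np.asarray(v, dtype=float)
    if s.size != r.size:
        raise ValueError("stimulus and response must have equal length")
    var = np.var(s)
    if var == 0:
        raise UndefinedResultError("zero-variance stimulus carries no information")
    n_lags = int(round(window / dt))
    if n_lags < 1:
        raise ValueError("window shorter than one step")
    s0 = s - s.mean()
    r0 = r - r.mean()
    vals = np.empty(n_lags)
    for j in range(n_lags):
        # correlate response at t with stimulus at t - j
        vals[j] = np.dot(r0[j:], s0[: s0.size - j]) / (s0.size * var)
    return LinearFilter(
        lags_ms=np.arange(n_lags) * dt,
        values=vals,
        level="subthreshold",
    )


def count_sign_changes(values, rel_threshold: float = 0.15) -> int:
    """Number of sign changes among filter lobes, ignoring samples smaller
    than ``rel_threshold`` times the peak magnitude (noise-floor guard).

    0 = monophasic, 1 = biphasic, 2 = triphasic."""
    v = np.asarray(values, dtype=float)
    peak = np.max(np.abs(v))
    if peak == 0:
        return 0
    signs = np.sign(v[np.abs(v) >= rel_threshold * peak])
    if signs.size == 0:
        return 0
    return int(np.sum(signs[1:] != signs[:-1]))
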