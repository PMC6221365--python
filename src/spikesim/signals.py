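"""Current-generating input channels and their summation.

The simulated unit is driven by the sum of six channels, mirroring the
front panel of the hardware it models:

* a **stimulus generator** (square pulses or binary noise on port 1),
* a **photoreceptor** with first-order adaptation (ON or OFF polarity),
* two **input synapses** responding to presynaptic spike events,
* **membrane noise** (zero-mean Gaussian, SD set by a dial),
* a **static current** that sets the resting level.

All traces are sampled on a uniform grid of step ``dt`` ms; currents are in
the dimensionless model units of :mod:`spikesim.model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .model import ModeParams

__all__ = [
    "StimulusConfig",
    "DialSettings",
    "CurrentBreakdown",
    "square_stimulus",
    "binary_noise_stimulus",
    "photo_current",
    "synapse_current",
    "noise_current",
    "sum_currents",
    "n_samples",
    "read_stimulus_trace",
]


def n_samples(duration: float, dt: float) -> int:
    """Number of samples in a trace of ``duration`` ms at step ``dt`` ms."""
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if not duration > 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    return int(round(duration / dt))


@dataclass(frozen=True)
class StimulusConfig:
    """Settings of the port-1 stimulus generator.

    ``kind`` selects square pulses (default), binary noise, or an
    externally supplied trace.  ``rate`` (Hz) is the square-pulse
    repetition rate (dial 1); ``duty`` the fraction of each period spent
    high.  ``noise_frame_rate`` (Hz) is the frame-update rate of the
    binary-noise generator; ``seed`` makes the noise reproducible.
    """

    kind: str = "square"
    rate: float = 1.0
    duty: float = 0.5
    noise_frame_rate: float = 50.0
    amplitude: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("square", "binary_noise", "external"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not 0.0 <= self.duty <= 1.0:
            raise ValueError(f"duty must lie in [0, 1], got {self.duty}")
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")
        if not self.noise_frame_rate > 0:
            raise ValueError(
                f"noise_frame_rate must be > 0, got {self.noise_frame_rate}"
            )


@dataclass(frozen=True)
class DialSettings:
    """Front-panel dial state of one unit.

    ``stim_rate`` (dial 1) sets the stimulus-generator rate; ``input_gain``
    (dial 2) scales the analog-in drive (and synapse 2 when wired);
    ``noise_amplitude`` (dial 3) is the SD of the membrane-noise current;
    ``static_current`` (dial 4) sets the resting drive.  ``synapse1_gain``
    is dial 1's alternate role when port 1 acts as a synapse.
    """

    stim_rate: float = 1.0
    input_gain: float = 1.0
    noise_amplitude: float = 0.0
    static_current: float = 0.0
    synapse1_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_amplitude < 0:
            raise ValueError(
                f"noise_amplitude must be >= 0, got {self.noise_amplitude}"
            )


@dataclass
class CurrentBreakdown:
    """Per-channel current traces and their sum ``i_total``.

    ``i_total`` is definitionally the elementwise sum of the components;
    the components are kept for logging.
    """

    i_photo: np.ndarray
    i_syn1: np.ndarray
    i_syn2: np.ndarray
    i_analog: np.ndarray
    i_noise: np.ndarray
    i_static: np.ndarray
    i_total: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        parts = [
            self.i_photo, self.i_syn1, self.i_syn2,
            self.i_analog, self.i_noise, self.i_static,
        ]
        n = {p.shape for p in parts}
        if len(n) != 1:
            raise ValueError(f"channel traces differ in length: {sorted(n)}")
        self.i_total = np.sum(parts, axis=0)

    CHANNELS = ("i_photo", "i_syn1", "i_syn2", "i_analog", "i_noise", "i_static")


def square_stimulus(config: StimulusConfig, duration: float, dt: float = 1.0) -> np.ndarray:
    """Square-pulse train of the port-1 generator: value ``amplitude``
    for the first ``duty`` fraction of each period (rising edge at t=0),
    0 otherwise.  ``rate=0`` degenerates to an all-low trace.
    """
    if config.kind != "square":
        raise ValueError(f"square_stimulus requires kind='square', got {config.kind!r}")
    n = n_samples(duration, dt)
    if n > 50_000_000:
        raise ValueError(f"trace of {n} samples exceeds the representable limit")
    if config.rate == 0:
        return np.zeros(n)
    period = 1000.0 / config.rate
    t = np.arange(n) * dt
    phase = (t % period) / period
    return np.where(phase < config.duty, config.amplitude, 0.0)


def binary_noise_stimulus(
    config: StimulusConfig,
    duration: float,
    dt: float = 1.0,
    unipolar: bool = False,
):
    """Binary noise held constant within frames of ``1000/noise_frame_rate``
    ms, each frame drawn equiprobably from two levels.

    Levels are symmetric ``+/- amplitude`` by default; ``unipolar=True``
    uses ``{0, amplitude}`` for the light-driving path (light cannot be
    negative).

    Returns ``(trace, frame_onsets)`` where ``frame_onsets`` are the frame
    start times in ms.
    """
    if config.kind != "binary_noise":
        raise ValueError(
            f"binary_noise_stimulus requires kind='binary_noise', got {config.kind!r}"
        )
    if config.seed is None:
        raise ValueError("binary noise requires a seed for reproducibility")
    frame_len = 1000.0 / config.noise_frame_rate
    if frame_len < dt:
        raise ValueError(
            f"noise frame ({frame_len} ms) shorter than the step ({dt} ms)"
        )
    n = n_samples(duration, dt)
    n_frames = int(round(duration / frame_len))
    rng = np.random.default_rng(config.seed)
    bits = rng.integers(0, 2, size=n_frames)
    if unipolar:
        levels = bits * config.amplitude
    else:
        levels = (2.0 * bits - 1.0) * config.amplitude
    t = np.arange(n) * dt
    idx = np.minimum((t / frame_len).astype(int), n_frames - 1)
    frame_onsets = np.arange(n_frames) * frame_len
    return levels[idx].astype(float), frame_onsets


def photo_current(light_trace, params: ModeParams, dt: float = 1.0) -> np.ndarray:
    """Photoreceptor transduction with first-order adaptation.

    The adaptation state ``A`` relaxes toward the light level ``L`` with
    time constant ``params.photo_adaptation_tau``; the output is the
    high-passed drive ``polarity * (L - A) + baseline``.  An ON unit
    (+1) is depolarised by light increments, an OFF unit (-1) by
    decrements; a nonzero baseline gives a maintained dark current.
    """
    light = np.asarray(light_trace, dtype=float)
    if np.any(light < 0):
        raise ValueError("light trace must be non-negative")
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    alpha = 1.0 - np.exp(-dt / params.photo_adaptation_tau)
    # A[k] = (1-alpha) A[k-1] + alpha L[k-1], A[0] = 0
    adapt = lfilter([0.0, alpha], [1.0, -(1.0 - alpha)], light)
    return params.photo_polarity * (light - adapt) + params.photo_baseline


def synapse_current(
    presyn_spike_times,
    gain: float,
    tau_syn: float = 10.0,
    duration: float = 1000.0,
    dt: float = 1.0,
) -> np.ndarray:
    """Exponential synapse: each presynaptic event adds an instantaneous
    jump of size ``gain`` that decays with time constant ``tau_syn`` ms;
    contributions sum linearly.  Negative gain hyperpolarises.
    """
    if not tau_syn > 0:
        raise ValueError(f"tau_syn must be > 0, got {tau_syn}")
    n = n_samples(duration, dt)
    impulses = np.zeros(n)
    for ts in presyn_spike_times:
        if not 0 <= ts < duration:
            raise ValueError(f"spike time {ts} outside [0, {duration})")
        impulses[int(ts / dt)] += gain
    decay = np.exp(-dt / tau_syn)
    return lfilter([1.0], [1.0, -decay], impulses)


def noise_current(
    amplitude: float, duration: float, dt: float = 1.0, seed: int | None = None
) -> np.ndarray:
    """Membrane-noise current: zero-mean Gaussian samples with SD
    ``amplitude``, i.i.d. across samples, reproducible from ``seed``."""
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    n = n_samples(duration, dt)
    if amplitude == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, amplitude, size=n)


def read_stimulus_trace(path, duration: float, dt: float = 1.0) -> np.ndarray:
    """Load an externally supplied stimulus trace (the analog-in port).

    Accepts delimited text with either one column (samples already on the
    simulation grid; length must match) or two columns ``time_ms, value``
    (linearly interpolated onto the grid).  Comment lines start with '#'.
    """
    data = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
    n = n_samples(duration, dt)
    t_grid = np.arange(n) * dt
    if data.shape[1] == 1:
        if data.shape[0] != n:
            raise ValueError(
                f"single-column trace has {data.shape[0]} samples, "
                f"expected {n} for {duration} ms at dt={dt}"
            )
        return data[:, 0].astype(float)
    if data.shape[1] == 2:
        t, val = data[:, 0], data[:, 1]
        if np.any(np.diff(t) <= 0):
            raise ValueError("time column must be strictly increasing")
        return np.interp(t_grid, t, val)
    raise ValueError(f"expected 1 or 2 columns, got {data.shape[1]}")


def sum_currents(
    *,
    i_photo=None,
    i_syn1=None,
    i_syn2=None,
    i_analog=None,
    i_noise=None,
    i_static=None,
    n: int | None = None,
) -> CurrentBreakdown:
    """Combine per-channel traces into a :class:`CurrentBreakdown`.

    Missing channels default to zero; ``n`` (or the first given channel)
    fixes the length.  Raises on length mismatch.
    """
    given = {
        "i_photo": i_photo, "i_syn1": i_syn1, "i_syn2": i_syn2,
        "i_analog": i_analog, "i_noise": i_noise, "i_static": i_static,
    }
    arrays = {k: np.asarray(v, dtype=float) for k, v in given.items() if v is not None}
    if n is None:
        if not arrays:
            raise ValueError("no channels given and no length n")
        n = len(next(iter(arrays.values())))
    full = {k: arrays.get(k, np.zeros(n)) for k in given}
    return CurrentBreakdown(**full)
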