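"""Multi-unit simulation engine and the CSV recording-log format.

Units advance on a shared clock.  A spike in one unit is delivered to the
synapse ports of its wired targets on the next step (a fixed one-step
delay, mirroring the loop latency of the hardware being modelled).  Every
sample of every unit is logged: membrane potential, the per-channel
current breakdown, the stimulus value, the spike flag and incoming
synapse-event flags.  Logs round-trip bit-exactly through CSV.
"""

from __future__ import annotations

import os
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    SPIKE_CUTOFF,
    ModeParams,
    get_mode,
    resting_state,
    step_neuron,
)
from .signals import (
    DialSettings,
    StimulusConfig,
    binary_noise_stimulus,
    n_samples,
    square_stimulus,
)

__all__ = [
    "ConfigurationError",
    "FormatError",
    "UnitSpec",
    "SynapseEdge",
    "WiringGraph",
    "RecordingLog",
    "run_simulation",
    "write_log",
    "read_log",
    "DEFAULT_TAU_SYN",
]

#: Default decay time constant (ms) of both input synapses.
DEFAULT_TAU_SYN = 10.0

#: Canonical column order of the recording CSV.
LOG_COLUMNS = [
    "t", "v", "i_total", "i_photo", "i_syn1", "i_syn2",
    "i_analog", "i_noise", "i_static", "stimulus", "spike",
    "syn1_event", "syn2_event",
]

_CURRENT_COLUMNS = ["i_photo", "i_syn1", "i_syn2", "i_analog", "i_noise", "i_static"]


class ConfigurationError(ValueError):
    """Invalid simulation configuration (dangling wiring, port conflict...)."""


class FormatError(ValueError):
    """A recording file does not match the expected CSV schema."""


@dataclass(frozen=True)
class UnitSpec:
    """Configuration of one unit in a simulation.

    ``mode`` is a 1-based index into the preset table or an explicit
    :class:`ModeParams`.  ``stimulus`` (if given) occupies port 1 and is
    routed either to the analog-in port (``stimulus_route='analog'``,
    scaled by the input-gain dial) or to the photoreceptor as a light
    drive (``'light'``).  Explicit ``light_trace`` / ``analog_trace``
    arrays may be attached instead.
    """

    unit_id: str
    mode: int | ModeParams = 1
    dials: DialSettings = field(default_factory=DialSettings)
    stimulus: StimulusConfig | None = None
    stimulus_route: str = "analog"
    light_trace: np.ndarray | None = None
    analog_trace: np.ndarray | None = None
    tau_syn: float = DEFAULT_TAU_SYN

    def params(self) -> ModeParams:
        return self.mode if isinstance(self.mode, ModeParams) else get_mode(self.mode)


@dataclass(frozen=True)
class SynapseEdge:
    """Directed connection: spike output of ``source`` into synapse port
    ``port`` (1 or 2) of ``target`` with signed ``gain``."""

    source: str
    target: str
    port: int = 2
    gain: float = 1.0


@dataclass
class WiringGraph:
    edges: list[SynapseEdge] = field(default_factory=list)

    def validate(self, units: list[UnitSpec]) -> None:
        ids = [u.unit_id for u in units]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("unit_id values must be unique")
        known = set(ids)
        stim_units = {u.unit_id for u in units if u.stimulus is not None}
        for e in self.edges:
            if e.source not in known:
                raise ConfigurationError(f"edge source {e.source!r} is not a unit")
            if e.target not in known:
                raise ConfigurationError(f"edge target {e.target!r} is not a unit")
            if e.port not in (1, 2):
                raise ConfigurationError(f"synapse port must be 1 or 2, got {e.port}")
            if e.port == 1 and e.target in stim_units:
                raise ConfigurationError(
                    f"port 1 of unit {e.target!r} is occupied by the stimulus "
                    "generator and cannot receive a synapse"
                )


@dataclass
class RecordingLog:
    """Tidy per-sample record of one unit: the data-logging stream of the
    device, as a DataFrame with uniform time step ``dt`` (ms)."""

    unit_id: str
    dt: float
    data: pd.DataFrame

    def spike_times(self) -> np.ndarray:
        """Times (ms) of flagged spike samples."""
        if "spike" not in self.data.columns:
            return np.array([])
        return self.data.loc[self.data["spike"] == 1, "t"].to_numpy(dtype=float)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(dtype=float)

    @property
    def v(self) -> np.ndarray:
        return self.data["v"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def _unit_rng(master_seed: int, unit_id: str) -> np.random.Generator:
    # Stable per-unit stream: adding/removing a unit leaves others untouched.
    key = zlib.crc32(unit_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(key,)))


def _resolve_inputs(unit: UnitSpec, n: int, duration: float, dt: float,
                    rng: np.random.Generator):
    """Precompute stimulus, light, analog, noise and static traces."""
    params = unit.params()
    stimulus = np.zeros(n)
    light = None
    analog = None

    if unit.stimulus is not None:
        cfg = unit.stimulus
        if cfg.kind == "square":
            stimulus = square_stimulus(cfg, duration, dt)
        elif cfg.kind == "binary_noise":
            if cfg.seed is None:
                cfg = replace(cfg, seed=int(rng.integers(0, 2**31 - 1)))
            unipolar = unit.stimulus_route == "light"
            stimulus, _ = binary_noise_stimulus(cfg, duration, dt, unipolar=unipolar)
        else:
            raise ConfigurationError(
                "external stimulus traces attach via analog_trace/light_trace"
            )
        if unit.stimulus_route == "analog":
            analog = stimulus
        elif unit.stimulus_route == "light":
            light = stimulus
        else:
            raise ConfigurationError(
                f"stimulus_route must be 'analog' or 'light', got {unit.stimulus_route!r}"
            )

    if unit.light_trace is not None:
        if light is not None:
            raise ConfigurationError(
                f"unit {unit.unit_id!r}: both a light-routed stimulus and an "
                "explicit light trace were given"
            )
        light = np.asarray(unit.light_trace, dtype=float)
        if light.size != n:
            raise ConfigurationError(
                f"unit {unit.unit_id!r}: light trace length {light.size} != {n}"
            )
    if unit.analog_trace is not None:
        if analog is not None:
            raise ConfigurationError(
                f"unit {unit.unit_id!r}: both an analog-routed stimulus and an "
                "explicit analog trace were given"
            )
        analog = np.asarray(unit.analog_trace, dtype=float)
        if analog.size != n:
            raise ConfigurationError(
                f"unit {unit.unit_id!r}: analog trace length {analog.size} != {n}"
            )

    from .signals import photo_current  # local import avoids cycle at module load

    i_photo = photo_current(light if light is not None else np.zeros(n), params, dt)
    i_analog = unit.dials.input_gain * (analog if analog is not None else np.zeros(n))
    if unit.dials.noise_amplitude > 0:
        i_noise = rng.normal(0.0, unit.dials.noise_amplitude, size=n)
    else:
        i_noise = np.zeros(n)
    i_static = np.full(n, float(unit.dials.static_current))
    return params, stimulus, i_photo, i_analog, i_noise, i_static


def run_simulation(
    units: list[UnitSpec],
    wiring: WiringGraph | None = None,
    duration: float = 1000.0,
    dt: float = 1.0,
    seed: int = 0,
) -> dict[str, RecordingLog]:
    """Step all units on a shared clock and return one log per unit.

    A spike in unit A at step ``k`` injects a synaptic jump of the edge
    gain into each wired target at step ``k + 1``.  Given identical
    configuration and seed the result (and its CSV bytes) is identical.
    """
    if not units:
        raise ConfigurationError("at least one unit is required")
    if wiring is None:
        wiring = WiringGraph()
    wiring.validate(units)
    n = n_samples(duration, dt)

    prep = {}
    for u in units:
        rng = _unit_rng(seed, u.unit_id)
        prep[u.unit_id] = _resolve_inputs(u, n, duration, dt, rng)

    out_edges: dict[str, list[SynapseEdge]] = {u.unit_id: [] for u in units}
    for e in wiring.edges:
        out_edges[e.source].append(e)

    decay = {u.unit_id: np.exp(-dt / u.tau_syn) for u in units}
    state = {u.unit_id: resting_state(prep[u.unit_id][0]) for u in units}
    syn = {u.unit_id: [0.0, 0.0] for u in units}       # current port values
    pending = {u.unit_id: [0.0, 0.0] for u in units}   # jumps to apply next step
    events = {u.unit_id: [0, 0] for u in units}

    rec = {
        u.unit_id: {c: np.zeros(n) for c in LOG_COLUMNS}
        for u in units
    }
    t_axis = np.arange(n) * dt

    for k in range(n):
        # deliver events scheduled from the previous step, then decay+jump
        for u in units:
            uid = u.unit_id
            s = syn[uid]
            p = pending[uid]
            d = decay[uid]
            events[uid][0] = 1 if p[0] != 0.0 else 0
            events[uid][1] = 1 if p[1] != 0.0 else 0
            s[0] = s[0] * d + p[0]
            s[1] = s[1] * d + p[1]
            p[0] = 0.0
            p[1] = 0.0
        for u in units:
            uid = u.unit_id
            params, stimulus, i_photo, i_analog, i_noise, i_static = prep[uid]
            i_syn1, i_syn2 = syn[uid]
            i_tot = (
                i_photo[k] + i_syn1 + i_syn2
                + i_analog[k] + i_noise[k] + i_static[k]
            )
            st = step_neuron(state[uid], params, i_tot, dt)
            state[uid] = st
            if st.spiked:
                for e in out_edges[uid]:
                    pending[e.target][e.port - 1] += e.gain
            r = rec[uid]
            r["v"][k] = SPIKE_CUTOFF if st.spiked else st.v
            r["i_total"][k] = i_tot
            r["i_photo"][k] = i_photo[k]
            r["i_syn1"][k] = i_syn1
            r["i_syn2"][k] = i_syn2
            r["i_analog"][k] = i_analog[k]
            r["i_noise"][k] = i_noise[k]
            r["i_static"][k] = i_static[k]
            r["stimulus"][k] = stimulus[k]
            r["spike"][k] = 1 if st.spiked else 0
            r["syn1_event"][k] = events[uid][0]
            r["syn2_event"][k] = events[uid][1]

    logs = {}
    for u in units:
        r = rec[u.unit_id]
        r["t"] = t_axis
        df = pd.DataFrame({c: r[c] for c in LOG_COLUMNS})
        for c in ("spike", "syn1_event", "syn2_event"):
            df[c] = df[c].astype(int)
        logs[u.unit_id] = RecordingLog(unit_id=u.unit_id, dt=dt, data=df)
    return logs


# ---------------------------------------------------------------------------
# CSV log I/O
# ---------------------------------------------------------------------------

def write_log(log: RecordingLog, destination) -> None:
    """Write a recording log as CSV: header row, one row per sample,
    comma-separated, '.' decimal, UTF-8, no quoting.  The format
    round-trips bit-exactly through :func:`read_log`."""
    log.data.to_csv(destination, index=False)


def read_log(source, unit_id: str | None = None) -> RecordingLog:
    """Read a recording CSV (from this engine or from a real device).

    ``t`` and ``v`` are mandatory; other columns are optional and absent
    channels are simply missing from the frame.  Non-uniform time spacing
    is a :class:`FormatError`; rows whose ``i_total`` disagrees with the
    sum of logged components beyond tolerance trigger a warning, not an
    error.
    """
    df = pd.read_csv(source, float_precision="round_trip")
    for col in ("t", "v"):
        if col not in df.columns:
            raise FormatError(f"mandatory column {col!r} missing")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("log must contain at least two samples")
    steps = np.diff(t)
    dt = steps[0]
    bad = np.nonzero(~np.isclose(steps, dt, rtol=1e-9, atol=1e-9))[0]
    if bad.size:
        raise FormatError(
            f"non-uniform time spacing first at row {bad[0] + 1} "
            f"(t={t[bad[0] + 1]})"
        )
    present = [c for c in _CURRENT_COLUMNS if c in df.columns]
    if "i_total" in df.columns and len(present) == len(_CURRENT_COLUMNS):
        resid = df["i_total"].to_numpy() - df[present].to_numpy().sum(axis=1)
        n_bad = int(np.sum(np.abs(resid) > 1e-6))
        if n_bad:
            warnings.warn(
                f"{n_bad} rows violate i_total = sum(components); "
                "log retained as-is",
                RuntimeWarning,
                stacklevel=2,
            )
    if unit_id is None:
        name = getattr(source, "name", None) or (
            source if isinstance(source, (str, os.PathLike)) else "log"
        )
        unit_id = os.path.splitext(os.path.basename(str(name)))[0]
    return RecordingLog(unit_id=unit_id, dt=float(dt), data=df)
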