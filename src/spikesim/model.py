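"""Izhikevich neuron core and the table of preset firing modes.

The unit of simulation is the two-variable phenomenological Izhikevich
model: a fast membrane potential ``v`` (mV) with quadratic dynamics and a
slow recovery variable ``u``,

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with a hard reset whenever ``v`` reaches the spike cutoff of 30 mV:
``v <- c``, ``u <- u + d``.  Time is in ms and the drive ``I`` is in the
dimensionless "model current" units that match the mV-scaled equations; no
physical pA calibration is claimed.

Integration is forward Euler with two half-steps for ``v`` per full step
for ``u``, carried out on internal substeps no longer than
:data:`DEFAULT_MAX_SUBSTEP` ms regardless of the sampling step ``dt``, and
with ``v`` clamped at the cutoff before the recovery update.  The
substepping and the clamp keep spike counts at the default 1-ms sampling
step in agreement with a fine-step reference integration (see
docs/methods.md); the logged grid remains ``dt``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPIKE_CUTOFF",
    "DEFAULT_MAX_SUBSTEP",
    "ModeParams",
    "NeuronState",
    "step_neuron",
    "simulate_unit",
    "preset_modes",
    "get_mode",
    "resting_state",
]

#: Hard spike cutoff (mV).  A step that reaches exactly this value counts
#: as a spike.
SPIKE_CUTOFF = 30.0

#: Ceiling (ms) on the internal integration substep.
DEFAULT_MAX_SUBSTEP = 0.02


@dataclass(frozen=True)
class ModeParams:
    """One neuron preset: Izhikevich coefficients plus the photoreceptor
    personality (polarity, adaptation speed, dark current) that together
    define a "mode".

    Parameters
    ----------
    label:
        Short name of the preset.
    a:
        Recovery time scale (1/ms); larger = faster recovery.
    b:
        Recovery sensitivity to ``v`` (dimensionless).
    c:
        Post-spike reset potential (mV).
    d:
        Post-spike recovery increment (model units).
    photo_polarity:
        +1 for an ON unit (light depolarises), -1 for an OFF unit.
    photo_adaptation_tau:
        Time constant (ms) of the photoreceptor's adaptation state.
    photo_baseline:
        Constant current injected by the photo channel in darkness; a
        positive value yields a dark-active unit.
    """

    label: str
    a: float
    b: float
    c: float
    d: float
    photo_polarity: int = 1
    photo_adaptation_tau: float = 500.0
    photo_baseline: float = 0.0
    description: str = ""

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"recovery time scale a must be > 0, got {self.a}")
        if not self.photo_adaptation_tau > 0:
            raise ValueError(
                f"photo_adaptation_tau must be > 0, got {self.photo_adaptation_tau}"
            )
        if not self.c < SPIKE_CUTOFF:
            raise ValueError(
                f"reset potential c must lie below the {SPIKE_CUTOFF} mV cutoff"
            )
        if self.photo_polarity not in (1, -1):
            raise ValueError("photo_polarity must be +1 (ON) or -1 (OFF)")


@dataclass
class NeuronState:
    """Instantaneous state of one unit.

    ``spiked`` refers to the step just completed; ``t`` is elapsed model
    time in ms.
    """

    v: float = -70.0
    u: float = -14.0
    spiked: bool = False
    t: float = 0.0


def resting_state(params: ModeParams, i_hold: float = 0.0) -> NeuronState:
    """State at the subthreshold fixed point of the dynamics under a
    constant drive ``i_hold`` (the lower root of the v-nullcline with
    ``u = b v``).

    Raises ``ValueError`` if no fixed point exists (drive suprathreshold).
    """
    # 0.04 v^2 + (5 - b) v + 140 + I = 0
    disc = (5.0 - params.b) ** 2 - 4.0 * 0.04 * (140.0 + i_hold)
    if disc < 0:
        raise ValueError("no resting fixed point: drive is suprathreshold")
    v = (-(5.0 - params.b) - math.sqrt(disc)) / (2.0 * 0.04)
    return NeuronState(v=v, u=params.b * v, spiked=False, t=0.0)


# ---------------------------------------------------------------------------
# Integrator kernel
# ---------------------------------------------------------------------------

def _advance_py(v, u, a, b, c, d, i_total, dt, n_sub):
    """Advance (v, u) by dt under constant drive, on n_sub substeps.

    Returns (v, u, spiked).  Within each substep v takes two half-steps;
    if the cutoff is reached, v is clamped there for the recovery update
    and then reset, and integration continues from the reset point.
    """
    h = dt / n_sub
    half = 0.5 * h
    spiked = False
    for _ in range(n_sub):
        v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + i_total)
        if v < SPIKE_CUTOFF:
            v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + i_total)
        if v >= SPIKE_CUTOFF:
            u += h * a * (b * SPIKE_CUTOFF - u)
            v = c
            u += d
            spiked = True
        else:
            u += h * a * (b * v - u)
    return v, u, spiked


def _make_integrate(advance):
    def _integrate(v, u, a, b, c, d, current, dt, n_sub):
        """Integrate over a current trace; returns (v_trace, flags, v, u).

        Spike samples are logged at the cutoff value; the dynamical state
        continues from the reset potential.
        """
        n = current.shape[0]
        v_out = np.empty(n)
        spikes = np.zeros(n, dtype=np.uint8)
        for k in range(n):
            if v >= SPIKE_CUTOFF:
                # entry above cutoff: the reset rule applies immediately
                v = c
                u += d
                sp = True
            else:
                v, u, sp = advance(v, u, a, b, c, d, current[k], dt, n_sub)
            if sp:
                v_out[k] = SPIKE_CUTOFF
                spikes[k] = 1
            else:
                v_out[k] = v
        return v_out, spikes, v, u

    return _integrate


try:  # jitted kernels; the pure-Python path is arithmetic-identical
    from numba import njit

    _advance = njit(cache=False)(_advance_py)
    _integrate = njit(cache=False)(_make_integrate(_advance))
except ImportError:  # pragma: no cover - numba is a declared dependency
    _advance = _advance_py
    _integrate = _make_integrate(_advance_py)


def _n_sub(dt: float, max_substep: float) -> int:
    if not max_substep > 0:
        raise ValueError(f"max_substep must be > 0, got {max_substep}")
    return max(1, int(math.ceil(dt / max_substep - 1e-12)))


def step_neuron(
    state: NeuronState,
    params: ModeParams,
    i_total: float,
    dt: float,
    max_substep: float = DEFAULT_MAX_SUBSTEP,
) -> NeuronState:
    """Advance one unit by ``dt`` ms under the total drive ``i_total``.

    Returns a new :class:`NeuronState`.  If the membrane reaches the
    30 mV cutoff during the step, the sample is flagged as a spike and
    the reset ``v <- c``, ``u <- u + d`` is applied; a state already at
    or above the cutoff on entry is reset immediately.  Deterministic for
    identical inputs.
    """
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if not (math.isfinite(state.v) and math.isfinite(state.u) and math.isfinite(i_total)):
        raise ValueError("non-finite state or drive")
    if state.v >= SPIKE_CUTOFF:
        return NeuronState(
            v=params.c, u=state.u + params.d, spiked=True, t=state.t + dt
        )
    v, u, spiked = _advance(
        state.v, state.u, params.a, params.b, params.c, params.d,
        float(i_total), dt, _n_sub(dt, max_substep),
    )
    return NeuronState(v=v, u=u, spiked=spiked, t=state.t + dt)


def simulate_unit(
    params: ModeParams,
    current_trace,
    dt: float = 1.0,
    state: NeuronState | None = None,
    max_substep: float = DEFAULT_MAX_SUBSTEP,
):
    """Integrate one unit over a current trace.

    Sample ``k`` of the returned voltage trace is the membrane potential
    after stepping under ``current_trace[k]``; spike samples are logged
    at the 30 mV cutoff (the dynamical state itself continues from the
    reset potential ``c``).

    Returns ``(v_trace, spike_times)``: spike times in ms on the
    ``k * dt`` grid, strictly increasing.
    """
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    current = np.ascontiguousarray(current_trace, dtype=float)
    if current.size == 0:
        raise ValueError("current trace must be non-empty")
    if not np.all(np.isfinite(current)):
        raise ValueError("current trace contains non-finite values")
    if state is None:
        state = resting_state(params)
    if not (math.isfinite(state.v) and math.isfinite(state.u)):
        raise ValueError("non-finite initial state")
    v_out, flags, _, _ = _integrate(
        state.v, state.u, params.a, params.b, params.c, params.d,
        current, dt, _n_sub(dt, max_substep),
    )
    spike_times = (np.nonzero(flags)[0] * dt).astype(float)
    return v_out, list(spike_times)


# ---------------------------------------------------------------------------
# Preset mode table
# ---------------------------------------------------------------------------

_PRESETS = (
    ModeParams(
        label="ON sustained (regular spiking)",
        a=0.02, b=0.2, c=-65.0, d=8.0,
        photo_polarity=+1, photo_adaptation_tau=500.0, photo_baseline=0.0,
        description=(
            "Slowly adapting light-ON unit: a light step drives an initial "
            "burst that gradually slows as the photoreceptor adapts."
        ),
    ),
    ModeParams(
        label="OFF transient (bursting)",
        a=0.02, b=0.2, c=-50.0, d=2.0,
        photo_polarity=-1, photo_adaptation_tau=50.0, photo_baseline=0.0,
        description=(
            "Rapidly adapting light-OFF unit: silent in steady light, fires "
            "a rebound burst when the light is removed.  Chattering-type "
            "reset (c=-50, d=2) groups spikes into bursts."
        ),
    ),
    ModeParams(
        label="OFF sustained, dark-active",
        a=0.02, b=0.2, c=-65.0, d=8.0,
        photo_polarity=-1, photo_adaptation_tau=5000.0, photo_baseline=10.0,
        description=(
            "Sustained light-OFF unit with an elevated basal rate in "
            "darkness; light suppresses the maintained firing."
        ),
    ),
    ModeParams(
        label="ON fast spiking",
        a=0.1, b=0.2, c=-65.0, d=2.0,
        photo_polarity=+1, photo_adaptation_tau=50.0, photo_baseline=0.0,
        description=(
            "Fast-spiking interneuron-like unit: sustains high rates with "
            "little adaptation; fast photo adaptation."
        ),
    ),
    ModeParams(
        label="ON intrinsically bursting",
        a=0.02, b=0.2, c=-55.0, d=4.0,
        photo_polarity=+1, photo_adaptation_tau=500.0, photo_baseline=0.0,
        description=(
            "Intrinsically-bursting-like unit: an initial spike doublet or "
            "burst followed by regular single spikes."
        ),
    ),
)


def preset_modes() -> list[ModeParams]:
    """The shipped table of preset modes, in button-toggle order (mode 1
    first).  Exactly five presets are defined."""
    return list(_PRESETS)


def get_mode(index: int) -> ModeParams:
    """Look up a preset by 1-based mode number (as toggled on the device)."""
    presets = preset_modes()
    if not 1 <= index <= len(presets):
        raise ValueError(f"mode index must be 1..{len(presets)}, got {index}")
    return presets[index - 1]
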