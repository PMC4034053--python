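"""Grids of Izhikevich neurons with spike traces.

The membrane model is the standard two-variable quadratic
integrate-and-reset system

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)

with a spike emitted when ``v`` reaches ``v_peak`` (30 mV), followed by the
reset ``v <- c``, ``u <- u + d``.  Integration is forward Euler with the
membrane advanced in two half-steps of ``dt/2`` per step (the common
practice for this model) and the recovery variable in one full step.

Spikes are recorded in a :class:`SpikeRaster` and additionally low-pass
filtered into a per-unit "trace" (exponential decay with time constant
``tau_syn``, incremented by 1 at each spike).  The traces are what the
network module feeds into the drive equations: they turn the lockstep
binary spike maps into sustained synaptic activity.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional

import numpy as np

__all__ = [
    "IzhParams",
    "GridState",
    "SpikeRaster",
    "REGULAR_SPIKING",
    "REBOUND",
    "izh_step",
    "simulate_grid",
    "update_trace",
]


@dataclasses.dataclass(frozen=True)
class IzhParams:
    """Parameters of one Izhikevich unit.

    a : 1/ms recovery rate; b : dimensionless v-u coupling; c : mV reset;
    d : recovery increment at spike; v_peak : mV spike cutoff.
    """

    a: float
    b: float
    c: float
    d: float
    v_peak: float = 30.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if self.v_peak <= self.c:
            raise ValueError(f"v_peak ({self.v_peak}) must exceed reset c ({self.c})")


#: Cortical regular-spiking cell (excitation-driven areas).
REGULAR_SPIKING = IzhParams(a=0.02, b=0.2, c=-65.0, d=8.0)

#: Low-threshold rebound-capable cell (area 2); fires on release from
#: strong hyperpolarization.
REBOUND = IzhParams(a=0.03, b=0.25, c=-60.0, d=4.0)


@dataclasses.dataclass
class GridState:
    """Membrane state (v, u) and filtered spike trace for a grid of units."""

    v: np.ndarray
    u: np.ndarray
    trace: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=np.float64)
        self.u = np.asarray(self.u, dtype=np.float64)
        self.trace = np.asarray(self.trace, dtype=np.float64)
        if not (self.v.shape == self.u.shape == self.trace.shape):
            raise ValueError("v, u and trace must share a shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.v.shape

    @classmethod
    def initial(
        cls,
        shape: tuple[int, ...],
        params: IzhParams,
        v0: float = -65.0,
        jitter_mv: float = 0.0,
        rng: Optional[np.random.Generator] = None,
    ) -> "GridState":
        """Resting start: v = v0, u = b*v, empty trace.

        ``jitter_mv`` adds seeded uniform +-jitter to the initial voltage
        (off by default; useful only to break pathological synchrony).
        """
        v = np.full(shape, v0, dtype=np.float64)
        if jitter_mv:
            if rng is None:
                raise ValueError("jitter requested but no rng supplied")
            v += rng.uniform(-jitter_mv, jitter_mv, size=shape)
        return cls(v=v, u=params.b * v, trace=np.zeros(shape))


class SpikeRaster:
    """Recorded spikes of a unit grid over a fixed-step simulation.

    Stored as a dense boolean array of shape ``(n_steps, *grid_shape)``;
    the spike emitted during step k is stamped with time ``(k + 1) * dt``
    (the end of the step), so all times lie in ``(0, duration]``.
    """

    def __init__(self, spikes: np.ndarray, dt: float):
        self.spikes = np.asarray(spikes, dtype=bool)
        self.dt = float(dt)

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.spikes.shape[1:]

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    def counts(self) -> np.ndarray:
        """Spike count per unit."""
        return self.spikes.sum(axis=0)

    def total_count(self) -> int:
        return int(self.spikes.sum())

    def spiked_mask(self) -> np.ndarray:
        """Boolean map of units that spiked at least once."""
        return self.spikes.any(axis=0)

    def spike_times(self, index: tuple[int, ...] = ()) -> np.ndarray:
        """Ordered spike times (ms) of one unit."""
        train = self.spikes[(slice(None),) + tuple(index)]
        steps = np.nonzero(train)[0]
        return (steps + 1) * self.dt

    def first_spike_times(self) -> np.ndarray:
        """First spike time per unit (ms); NaN for silent units."""
        any_spk = self.spikes.any(axis=0)
        first = self.spikes.argmax(axis=0).astype(np.float64)
        first = (first + 1) * self.dt
        first[~any_spk] = np.nan
        return first


def izh_step(
    state: GridState, I: np.ndarray | float, params: IzhParams, dt: float
) -> np.ndarray:
    """Advance a grid one step under drive ``I``; returns the spike indicator.

    ``state`` is updated in place (v, u only; the caller owns the trace).
    Raises on numerical blow-up, naming the first offending unit.
    """
    if not 0 < dt <= 1.0:
        raise ValueError(f"dt must lie in (0, 1] ms, got {dt}")
    v, u = state.v, state.u
    half = 0.5 * dt
    for _ in range(2):
        v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
    u += dt * params.a * (params.b * v - u)
    if not np.isfinite(v).all() or not np.isfinite(u).all():
        bad = tuple(int(i) for i in np.argwhere(~(np.isfinite(v) & np.isfinite(u)))[0])
        raise FloatingPointError(f"non-finite membrane state at unit {bad}; reduce dt")
    spiked = v >= params.v_peak
    if spiked.any():
        v[spiked] = params.c
        u[spiked] += params.d
    return spiked


def update_trace(
    trace: np.ndarray, spiked: np.ndarray, dt: float, tau_syn: float
) -> np.ndarray:
    """Exponentially filtered spike train: decay by ``exp(-dt/tau_syn)``, +1 at spikes.

    ``tau_syn = 0`` degenerates to the instantaneous binary spike map.
    """
    if tau_syn < 0:
        raise ValueError(f"tau_syn must be >= 0, got {tau_syn}")
    if tau_syn == 0:
        return spiked.astype(np.float64)
    return trace * math.exp(-dt / tau_syn) + spiked


def simulate_grid(
    params: IzhParams,
    drive_provider: Callable[[int, GridState], np.ndarray | float],
    duration: float,
    dt: float,
    shape: tuple[int, ...] = (),
    tau_syn: float = 5.0,
    state: Optional[GridState] = None,
) -> SpikeRaster:
    """Run an isolated grid for ``duration`` ms and return its raster.

    ``drive_provider(step, state)`` supplies the drive for each step; the
    state it sees is the one from the end of the previous step.
    """
    n_steps = round(duration / dt)
    if not math.isclose(n_steps * dt, duration):
        raise ValueError(f"duration {duration} is not a multiple of dt {dt}")
    if state is None:
        state = GridState.initial(shape, params)
    spikes = np.zeros((n_steps,) + state.shape, dtype=bool)
    for k in range(n_steps):
        I = drive_provider(k, state)
        spiked = izh_step(state, I, params, dt)
        state.trace = update_trace(state.trace, spiked, dt, tau_syn)
        spikes[k] = spiked
    return SpikeRaster(spikes, dt)
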