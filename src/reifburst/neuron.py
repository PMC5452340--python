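"""Refractory exponential integrate-and-fire (rEIF) single neuron.

The membrane voltage obeys

    C dV/dt = −G_L(T)·(V − V_L(T)) + G_L(T)·Δ_T(T)·exp[(V − V_T(T)) / Δ_T(T)]
              + I_in(V, t) + σ dW/dt

where T is the time since the last spike and the four parenthesised
parameters relax exponentially from their post-spike values back to the
basal ones (see :mod:`reifburst.params`).  When V reaches the absolute
threshold ``V_Tabs`` a spike is registered, V resets to ``V_r`` and T to 0.
Integration uses the Euler–Maruyama scheme at a fixed step (0.1 ms by
default throughout the package).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .params import ReifParams

#: sentinel "never spiked" value for the time-since-spike variable; all
#: relaxation terms vanish and the basal parameters apply.
T_NEVER = math.inf

DEFAULT_DT = 0.1  # ms


@dataclass
class NeuronState:
    """Dynamical state (V, T) of one rEIF neuron."""

    V: float
    T: float = T_NEVER

    def __post_init__(self) -> None:
        if not math.isfinite(self.V):
            raise ValueError(f"membrane voltage must be finite, got {self.V}")
        if self.T < 0:
            raise ValueError(f"time since spike must be >= 0, got {self.T}")


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane-voltage trace (post-step samples)."""

    dt: float
    samples: np.ndarray
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.samples.size < 1:
            raise ValueError("trace must contain at least one sample")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms (``t0`` is the time of the first sample)."""
        return self.t0 + self.dt * np.arange(self.samples.size)

    @property
    def duration(self) -> float:
        return self.dt * self.samples.size


@dataclass
class SimResult:
    trace: VoltageTrace
    spike_times: np.ndarray
    state: NeuronState


def relax_params(T: float, p: ReifParams) -> tuple[float, float, float, float]:
    """Instantaneous (G_L, V_L, V_T, Delta_T) at time-since-spike ``T``.

    ``T = T_NEVER`` (or any very large T) yields exactly the basal values.
    """
    if T < 0 or math.isnan(T):
        raise ValueError(f"time since spike must be >= 0 or T_NEVER, got {T}")
    pv = _kernels.pack_params(p)
    return _kernels.relax_kernel(T, pv)


def step_neuron(
    s: NeuronState,
    p: ReifParams,
    I_in: float,
    dt: float = DEFAULT_DT,
    noise_draw: float = 0.0,
) -> tuple[NeuronState, bool]:
    """Advance one Euler–Maruyama step under injected current ``I_in`` (pA).

    ``noise_draw`` is a standard-normal variate scaled internally by
    ``sigma·sqrt(dt)``.  Returns the new state and a spike flag.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pv = _kernels.pack_params(p)
    zero = np.zeros(1)
    V_out, spikes, V, T, err = _kernels.integrate_neuron(
        s.V, s.T, dt, np.array([float(I_in)]), zero, zero, 0.0, 0.0, pv,
        np.array([float(noise_draw)]),
    )
    if err >= 0:
        raise FloatingPointError(
            f"voltage became non-finite in one step from V={s.V} mV, "
            f"T={s.T} ms, I_in={I_in} pA, dt={dt} ms"
        )
    return NeuronState(V=V, T=T), spikes.size > 0


def _as_drive(drive, n_steps: int | None):
    """Normalise a drive spec to (I_ext, g_E, g_I, V_E, V_I) arrays."""
    if isinstance(drive, dict):
        g_E = np.ascontiguousarray(drive["g_E"], dtype=np.float64)
        g_I = np.ascontiguousarray(drive.get("g_I", np.zeros_like(g_E)),
                                   dtype=np.float64)
        V_E = float(drive.get("V_E", 0.0))
        V_I = float(drive.get("V_I", -75.0))
        if g_E.shape != g_I.shape:
            raise ValueError("g_E and g_I must have equal length")
        I_ext = np.asarray(drive.get("I_ext", np.zeros_like(g_E)),
                           dtype=np.float64)
        if I_ext.shape != g_E.shape:
            raise ValueError("I_ext must match conductance length")
        n = g_E.size
    else:
        I_ext = np.ascontiguousarray(drive, dtype=np.float64)
        if I_ext.ndim != 1:
            raise ValueError("current drive must be one-dimensional")
        n = I_ext.size
        g_E = g_I = np.zeros(n)
        V_E = V_I = 0.0
    if n_steps is not None and n != n_steps:
        raise ValueError(
            f"drive length {n} does not cover duration/dt = {n_steps} steps"
        )
    return I_ext, g_E, g_I, V_E, V_I


def simulate_neuron(
    p: ReifParams,
    drive,
    dt: float = DEFAULT_DT,
    *,
    duration: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    state: NeuronState | None = None,
    sigma: float | None = None,
    t0: float = 0.0,
    meta: dict | None = None,
) -> SimResult:
    """Integrate one neuron against a drive series.

    ``drive`` is either a current series (pA, one value per step) or a
    mapping with keys ``g_E``/``g_I`` (nS) and reversals ``V_E``/``V_I``
    (mV), in which case ``I_in = g_E·(V_E−V) + g_I·(V_I−V)`` is computed
    each step.  ``sigma`` (mV/s^1/2) overrides the noise intensity of
    ``p``; pass 0 for a deterministic run.  Passing ``rng`` (consumed one
    draw per step) makes consecutive calls with carried-over ``state``
    exactly equivalent to a single longer call.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = None if duration is None else int(round(duration / dt))
    I_ext, g_E, g_I, V_E, V_I = _as_drive(drive, n_steps)
    n = I_ext.size
    if state is None:
        state = NeuronState(V=p.V_L0, T=T_NEVER)
    sigma_ms = None if sigma is None else sigma / math.sqrt(1000.0)
    pv = _kernels.pack_params(p, sigma_ms=sigma_ms)
    if pv[-1] == 0.0:
        noise = np.zeros(n)
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        noise = rng.standard_normal(n)
    V_out, spike_idx, V, T, err = _kernels.integrate_neuron(
        state.V, state.T, dt, I_ext, g_E, g_I, V_E, V_I, pv, noise
    )
    if err >= 0:
        raise FloatingPointError(
            f"voltage became non-finite at step {err} (t = {t0 + (err + 1) * dt}"
            f" ms); drive at that step: I_ext={I_ext[err]}, g_E={g_E[err]},"
            f" g_I={g_I[err]}"
        )
    # sample i holds the state after step i, i.e. at t0 + (i+1)·dt
    trace = VoltageTrace(dt=dt, samples=V_out, t0=t0 + dt,
                         meta={"seed": seed, **(meta or {})})
    spike_times = t0 + dt * (spike_idx + 1.0)
    return SimResult(trace=trace, spike_times=spike_times,
                     state=NeuronState(V=V, T=T))


def write_trace(path, trace: VoltageTrace) -> None:
    """Write a voltage trace as two-column text (time_ms, V_mV)."""
    np.savetxt(path, np.column_stack([trace.times, trace.samples]),
               fmt="%.6f", header="time_ms\tV_mV", delimiter="\t")


def write_spike_times(path, spike_times: Sequence[float]) -> None:
    np.savetxt(path, np.asarray(spike_times, dtype=float)[:, None],
               fmt="%.6f", header="spike_time_ms", delimiter="\t")
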