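"""Compiled fixed-step integrators.

Both kernels advance the rEIF voltage equation with the Euler–Maruyama
scheme: deterministic drift ``(dt/C)·[−G_L(T)·(V−V_L(T)) +
G_L(T)·Δ_T(T)·exp((V−V_T(T))/Δ_T(T)) + I_in]`` plus an additive noise
increment ``σ·sqrt(dt)·ξ`` on the voltage.  The exponential argument is
capped at 20 before exponentiation; once V has reached the absolute
threshold the spike fires regardless, so the cap cannot move spike times
for physiological parameter values.

A "never spiked" state is encoded as T = inf, for which every relaxation
term vanishes and the basal parameter values apply.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: layout of the packed single-neuron parameter vector
_PV_FIELDS = (
    "C", "V_Tabs", "V_r", "G_L0", "a_GL", "tau_GL", "V_L0", "a_VL",
    "tau_VLa", "b_VL", "tau_VLb", "V_T0", "a_VT", "tau_VT", "DeltaT0",
    "a_DeltaT", "tau_DeltaT",
)

_EXP_CAP = 20.0


def pack_params(p, sigma_ms: float | None = None) -> np.ndarray:
    """Pack a ReifParams into the float64 vector the kernels consume.

    ``sigma_ms`` overrides the noise intensity (already on the ms base);
    by default it is taken from ``p``.
    """
    pv = np.empty(len(_PV_FIELDS) + 1, dtype=np.float64)
    for i, name in enumerate(_PV_FIELDS):
        pv[i] = getattr(p, name)
    pv[-1] = p.sigma_ms if sigma_ms is None else sigma_ms
    return pv


@njit(cache=True)
def relax_kernel(T, pv):
    """Instantaneous (G_L, V_L, V_T, Delta_T) at time-since-spike T."""
    G_L = pv[3] + pv[4] * math.exp(-T / pv[5])
    V_L = pv[6] + pv[7] * math.exp(-T / pv[8]) + pv[9] * math.exp(-T / pv[10])
    V_T = pv[11] + pv[12] * math.exp(-T / pv[13])
    D_T = pv[14] + pv[15] * math.exp(-T / pv[16])
    return G_L, V_L, V_T, D_T


@njit(cache=True)
def integrate_neuron(V0, T0, dt, I_ext, g_E, g_I, V_E, V_I, pv, noise):
    """Advance one neuron over ``len(I_ext)`` steps.

    Conductance drive contributes ``g_E·(V_E−V) + g_I·(V_I−V)`` on top of
    the injected current series.  Returns the post-step voltage trace,
    spike step indices, final (V, T) and the index of the first non-finite
    step (−1 if none; the caller raises).
    """
    n = I_ext.shape[0]
    V_out = np.empty(n, dtype=np.float64)
    spikes = np.empty(n, dtype=np.int64)
    nsp = 0
    V = V0
    T = T0
    sqdt = math.sqrt(dt)
    C = pv[0]
    V_Tabs = pv[1]
    V_r = pv[2]
    sigma = pv[17]
    for i in range(n):
        G_L, V_L, V_T, D_T = relax_kernel(T, pv)
        I_in = I_ext[i] + g_E[i] * (V_E - V) + g_I[i] * (V_I - V)
        arg = (V - V_T) / D_T
        if arg > _EXP_CAP:
            arg = _EXP_CAP
        drift = (-G_L * (V - V_L) + G_L * D_T * math.exp(arg) + I_in) / C
        V = V + dt * drift + sigma * sqdt * noise[i]
        if not math.isfinite(V):
            return V_out, spikes[:nsp], V, T, i
        if V >= V_Tabs:
            V = V_r
            T = 0.0
            spikes[nsp] = i
            nsp += 1
        else:
            T = T + dt
        V_out[i] = V
    return V_out, spikes[:nsp], V, T, -1


@njit(cache=True)
def network_chunk(V, T, N, G, W, pv, sv, dt, noise,
                  ev_step, ev_neuron, ev_release):
    """Advance the all-to-all excitatory network over one noise chunk.

    Per step: (1) vesicle pools recover, dN = dt·(1−N)/τ_N, and efferent
    conductances decay, dG = −dt·G/τ_GE (forward Euler); (2) each neuron
    receives I = γ_max·(Γ_E·G)·(V_E−V) + I_0; (3) voltages advance by
    Euler–Maruyama; (4) every spiking neuron releases r·N — its efferent
    conductance jumps by that amount and the pool shrinks to N·(1−r).

    State arrays are updated in place.  Spike events (step, neuron,
    released fraction) are appended to the ``ev_*`` buffers; returns the
    event count and an error step (−1 if none, −2 on vesicle-bound
    breach).
    """
    n_steps = noise.shape[0]
    n = V.shape[0]
    tau_N = sv[0]
    r = sv[1]
    tau_GE = sv[2]
    gamma_max = sv[3]
    I_0 = sv[4]
    V_E = sv[5]
    C = pv[0]
    V_Tabs = pv[1]
    V_r = pv[2]
    sigma = pv[17]
    sqdt = math.sqrt(dt)
    nev = 0
    I_syn = np.empty(n, dtype=np.float64)
    for s in range(n_steps):
        for j in range(n):
            N[j] = N[j] + dt * (1.0 - N[j]) / tau_N
            G[j] = G[j] - dt * G[j] / tau_GE
        # synaptic drive from start-of-step conductances, before any
        # release jump of this step can feed back
        for j in range(n):
            acc = 0.0
            for k in range(n):
                acc += W[j, k] * G[k]
            I_syn[j] = gamma_max * acc * (V_E - V[j]) + I_0
        for j in range(n):
            I_in = I_syn[j]
            G_L, V_L, V_T, D_T = relax_kernel(T[j], pv)
            arg = (V[j] - V_T) / D_T
            if arg > _EXP_CAP:
                arg = _EXP_CAP
            drift = (-G_L * (V[j] - V_L) + G_L * D_T * math.exp(arg) + I_in) / C
            V[j] = V[j] + dt * drift + sigma * sqdt * noise[s, j]
            if not math.isfinite(V[j]):
                return nev, s
            if V[j] >= V_Tabs:
                V[j] = V_r
                T[j] = 0.0
                released = r * N[j]
                G[j] = G[j] + released
                N[j] = N[j] - released
                ev_step[nev] = s
                ev_neuron[nev] = j
                ev_release[nev] = released
                nev += 1
            else:
                T[j] = T[j] + dt
            if N[j] < -1e-12 or N[j] > 1.0 + 1e-12:
                return nev, -2
    return nev, -1
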