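"""Independent reference implementations used only by the test suite.

These deliberately share no code path with the package kernels: the
single-neuron oracle integrates the continuous-time model with scipy's
adaptive RK45 and event-based spike detection; the network oracle is a
straightforward pure-Python transcription of the discrete update scheme
that consumes the identical noise stream.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp

from reifburst.params import ReifParams, SynapseParams


def _relax(T: float, p: ReifParams):
    G_L = p.G_L0 + p.a_GL * math.exp(-T / p.tau_GL)
    V_L = (p.V_L0 + p.a_VL * math.exp(-T / p.tau_VLa)
           + p.b_VL * math.exp(-T / p.tau_VLb))
    V_T = p.V_T0 + p.a_VT * math.exp(-T / p.tau_VT)
    D_T = p.DeltaT0 + p.a_DeltaT * math.exp(-T / p.tau_DeltaT)
    return G_L, V_L, V_T, D_T


def ode_neuron_oracle(
    p: ReifParams,
    I_of_t,
    duration: float,
    V0: float,
    T0: float = math.inf,
    rtol: float = 1e-10,
    atol: float = 1e-9,
    max_step: float = 0.05,
):
    """Adaptive high-accuracy integration of the deterministic rEIF model.

    ``I_of_t`` maps time (ms) to injected current (pA).  Returns
    ``(dense_V, spike_times)`` where ``dense_V(t)`` evaluates the voltage
    at arbitrary times.  Spikes are located by root-finding on
    V = V_Tabs and handled by restarting from the reset state.
    """

    def rhs(t, y):
        V, T = y
        G_L, V_L, V_T, D_T = _relax(T, p)
        drift = (-G_L * (V - V_L) + G_L * D_T * math.exp((V - V_T) / D_T)
                 + I_of_t(t)) / p.C
        return [drift, 1.0]

    def hit_threshold(t, y):
        return y[0] - p.V_Tabs

    hit_threshold.terminal = True
    hit_threshold.direction = 1.0

    segments = []
    spikes = []
    t, y = 0.0, [V0, min(T0, 1e12)]
    while t < duration:
        sol = solve_ivp(rhs, (t, duration), y, events=hit_threshold,
                        rtol=rtol, atol=atol, max_step=max_step,
                        dense_output=True)
        segments.append(sol)
        if sol.t_events[0].size:
            t = float(sol.t_events[0][0])
            spikes.append(t)
            y = [p.V_r, 0.0]
        else:
            break

    def dense_V(ts):
        ts = np.atleast_1d(np.asarray(ts, dtype=float))
        out = np.empty(ts.size)
        for i, tq in enumerate(ts):
            for sol in segments:
                if sol.t[0] <= tq <= sol.t[-1]:
                    out[i] = sol.sol(tq)[0]
                    break
            else:
                out[i] = segments[-1].sol(tq)[0]
        return out

    return dense_V, np.asarray(spikes)


def reference_network(
    n: int,
    duration: float,
    dt: float,
    seed: int,
    p: ReifParams,
    sp: SynapseParams,
    W: np.ndarray,
    normalize_by_n: bool = True,
    rec_every: float = 100.0,
    exp_cap: float = 20.0,
):
    """Pure-Python transcription of the network update scheme.

    Consumes noise in the same chunked order as the package simulator so
    results can be compared trajectory-for-trajectory.  Returns final
    state arrays and the spike list [(time_ms, neuron, released)].
    """
    gamma = (sp.coupling_scale * sp.gamma_max / n if normalize_by_n
             else sp.gamma_max)
    tau_N = sp.tau_N_ms
    sigma_ms = p.sigma_ms
    V = [p.V_L0] * n
    T = [math.inf] * n
    N = [1.0] * n
    G = [0.0] * n
    spikes = []
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    chunk = max(1, int(round(rec_every / dt)))
    sqdt = math.sqrt(dt)
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        noise = (rng.standard_normal((m, n)) if p.sigma > 0
                 else np.zeros((m, n)))
        for s in range(m):
            for j in range(n):
                N[j] += dt * (1.0 - N[j]) / tau_N
                G[j] -= dt * G[j] / sp.tau_GE
            I_syn = []
            for j in range(n):
                acc = 0.0
                for k in range(n):
                    acc += W[j][k] * G[k]
                I_syn.append(gamma * acc * (sp.V_E - V[j]) + sp.I_0)
            for j in range(n):
                G_L, V_L, V_T, D_T = _relax(T[j], p)
                arg = min((V[j] - V_T) / D_T, exp_cap)
                drift = (-G_L * (V[j] - V_L) + G_L * D_T * math.exp(arg)
                         + I_syn[j]) / p.C
                V[j] = V[j] + dt * drift + sigma_ms * sqdt * noise[s, j]
                if V[j] >= p.V_Tabs:
                    V[j] = p.V_r
                    T[j] = 0.0
                    released = sp.r * N[j]
                    G[j] += released
                    N[j] -= released
                    spikes.append(((done + s + 1) * dt, j, released))
                else:
                    T[j] += dt
        done += m
    return np.array(V), np.array(T), np.array(N), np.array(G), spikes
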