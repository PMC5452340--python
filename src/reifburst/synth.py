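"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the experimental data the analysis consumes:
epileptiform voltage-clamp current pairs (excitatory component recorded
at −80 mV, inhibitory at 0 mV, 24 consecutive bursts with burst-to-burst
variability in the inhibitory/excitatory charge ratio), miniature-EPSC
traces for unitary-conductance calibration, and voltage traces with
planted action potentials for validating the AP detector.  Every
generator is a pure function of (config, seed): identical seeds give
byte-identical outputs.

Each synthetic burst is an alpha-like envelope multiplying a shot-noise
sum of unitary synaptic events; interburst intervals are gamma
distributed, parameterised by (mean, CV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .clamp import (
    ConductanceTemplate,
    CurrentRecordingMeta,
    EXCITATORY_META,
    INHIBITORY_META,
    UnitaryEPSC,
    current_to_conductance,
    unitary_epsc_waveform,
)
from .neuron import DEFAULT_DT, VoltageTrace


@dataclass
class TemplateGenConfig:
    """Conditions for the synthetic epileptiform recording.

    Defaults emulate the recorded protocol: 24 consecutive bursts a few
    hundred ms long recurring every couple of seconds, with the
    inhibitory/excitatory charge ratio varying from burst to burst.
    """

    n_bursts: int = 24
    env_rise_ms: float = 15.0       # burst envelope rise
    env_decay_ms: float = 80.0      # burst envelope decay
    peak_gE_nS: float = 20.0        # pre-scaling excitatory peak
    ibi_mean_s: float = 2.0         # onset-to-onset interval mean
    ibi_cv: float = 0.4
    ratio_mean: float = 1.2         # Q_I / Q_E per burst
    ratio_sd: float = 0.4
    event_rate_hz: float = 400.0    # within-burst unitary event rate (at peak)
    noise_pA: float = 2.0
    dt: float = DEFAULT_DT
    seed: int = 0
    unitary_E: UnitaryEPSC = field(
        default_factory=lambda: UnitaryEPSC(peak_nS=0.3, rise_ms=0.5, decay_ms=3.0))
    unitary_I: UnitaryEPSC = field(
        default_factory=lambda: UnitaryEPSC(peak_nS=0.3, rise_ms=1.0, decay_ms=10.0))

    def __post_init__(self) -> None:
        if self.n_bursts < 0:
            raise ValueError("burst count must be non-negative")
        for name in ("env_rise_ms", "env_decay_ms", "peak_gE_nS",
                     "ibi_mean_s", "ibi_cv", "ratio_mean", "ratio_sd",
                     "event_rate_hz", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_pA < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass
class EpileptiformRecording:
    """Paired synthetic current recordings plus ground-truth annotations."""

    dt: float
    I_E: np.ndarray                  # pA, recorded at −80 mV holding
    I_I: np.ndarray                  # pA, recorded at 0 mV holding
    meta_E: CurrentRecordingMeta
    meta_I: CurrentRecordingMeta
    windows: list                    # true burst windows (start_ms, end_ms)
    true_ratios: np.ndarray          # per-burst Q_I / Q_E actually drawn


def _envelope(cfg: TemplateGenConfig) -> np.ndarray:
    """Normalised (peak 1) difference-of-exponentials burst envelope."""
    tr, td = cfg.env_rise_ms, cfg.env_decay_ms
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    span = t_peak + td * math.log(100.0)
    t = cfg.dt * np.arange(int(round(span / cfg.dt)))
    env = np.exp(-t / td) - np.exp(-t / tr)
    return env / env.max()


def _burst_conductance(cfg, rng, env, wave) -> np.ndarray:
    """Envelope times shot noise of unitary events, normalised peak 1."""
    rate_per_sample = cfg.event_rate_hz * cfg.dt / 1000.0
    counts = rng.poisson(rate_per_sample * env)
    shots = fftconvolve(counts.astype(float), wave)[:env.size]
    g = env * shots
    peak = g.max()
    if peak <= 0:
        g = env.copy()
        peak = 1.0
    return g / peak


def gen_epileptiform_recording(cfg: TemplateGenConfig) -> EpileptiformRecording:
    """Generate paired excitatory/inhibitory epileptiform current traces.

    Returns the traces with their recording metadata, the true burst
    windows and the per-burst charge ratios that were drawn (before
    measurement noise).
    """
    rng = np.random.default_rng(cfg.seed)
    env = _envelope(cfg)
    win_len = env.size * cfg.dt
    wave_E = unitary_epsc_waveform(cfg.unitary_E, cfg.dt)
    wave_E = wave_E / wave_E.max()
    wave_I = unitary_epsc_waveform(cfg.unitary_I, cfg.dt)
    wave_I = wave_I / wave_I.max()

    # onset-to-onset intervals, gamma(mean, CV), floored above the window
    shape = 1.0 / cfg.ibi_cv**2
    scale = cfg.ibi_mean_s * 1000.0 * cfg.ibi_cv**2
    intervals = np.maximum(rng.gamma(shape, scale, size=cfg.n_bursts),
                           win_len + 100.0)
    if cfg.n_bursts:
        onsets = 500.0 + np.concatenate(([0.0], np.cumsum(intervals[1:])))
        total_ms = onsets[-1] + win_len + 500.0
    else:
        onsets = np.empty(0)
        total_ms = 1000.0
    n_samp = int(round(total_ms / cfg.dt))

    df_E = EXCITATORY_META.driving_force      # +93.6 mV
    df_I = INHIBITORY_META.driving_force      # −41.4 mV
    I_E = np.zeros(n_samp)
    I_I = np.zeros(n_samp)
    windows = []
    ratios = np.maximum(
        rng.normal(cfg.ratio_mean, cfg.ratio_sd, size=cfg.n_bursts), 0.1)
    for k in range(cfg.n_bursts):
        g_e = cfg.peak_gE_nS * _burst_conductance(cfg, rng, env, wave_E)
        g_i_raw = _burst_conductance(cfg, rng, env, wave_I)
        q_e = abs((g_e * df_E).sum() * cfg.dt)
        q_i_raw = abs((g_i_raw * df_I).sum() * cfg.dt)
        g_i = g_i_raw * (ratios[k] * q_e / q_i_raw)
        i0 = int(round(onsets[k] / cfg.dt))
        sl = slice(i0, i0 + env.size)
        # currents carry their physiological sign: I = g·(V_m − V_rev)
        I_E[sl] += g_e * -df_E
        I_I[sl] += g_i * -df_I
        windows.append((onsets[k], onsets[k] + win_len))
    if cfg.noise_pA > 0:
        I_E += rng.normal(0.0, cfg.noise_pA, n_samp)
        I_I += rng.normal(0.0, cfg.noise_pA, n_samp)
    return EpileptiformRecording(
        dt=cfg.dt, I_E=I_E, I_I=I_I,
        meta_E=EXCITATORY_META, meta_I=INHIBITORY_META,
        windows=windows, true_ratios=ratios,
    )


def recording_to_template(
    rec: EpileptiformRecording,
    E_E: float = 0.0,
    E_I: float = -56.0,
) -> ConductanceTemplate:
    """Convert a (synthetic or loaded) current recording into a playback
    template.  Default playback reversals are the model values: 0 mV
    excitatory, −56 mV inhibitory (GABA_A equilibrium shifted by the high
    extracellular potassium)."""
    g_E, df_E = current_to_conductance(rec.I_E, rec.meta_E)
    g_I, df_I = current_to_conductance(rec.I_I, rec.meta_I)
    return ConductanceTemplate(
        dt=rec.dt, g_E=g_E, g_I=g_I, E_E=E_E, E_I=E_I,
        windows=list(rec.windows),
        meta={"driving_force_E_mV": df_E, "driving_force_I_mV": df_I},
    )


def gen_template(cfg: TemplateGenConfig) -> ConductanceTemplate:
    """Synthetic recording converted straight to a conductance template."""
    return recording_to_template(gen_epileptiform_recording(cfg))


def gen_mepsc_trace(
    rate_hz: float,
    u: UnitaryEPSC,
    meta: CurrentRecordingMeta = EXCITATORY_META,
    noise_pA: float = 1.0,
    duration_ms: float = 10_000.0,
    seed: int = 0,
    dt: float = DEFAULT_DT,
) -> tuple[np.ndarray, np.ndarray]:
    """Miniature-EPSC current trace with Poisson event times.

    Each event is the unitary conductance waveform converted to current
    at the recording's driving force (I = g·(V_m − V_rev)), plus additive
    Gaussian noise.  Returns (current trace pA, true event times ms).
    """
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms / dt))
    counts = rng.poisson(rate_hz * dt / 1000.0, size=n)
    wave = unitary_epsc_waveform(u, dt) * -meta.driving_force
    I = fftconvolve(counts.astype(float), wave)[:n]
    if noise_pA > 0:
        I += rng.normal(0.0, noise_pA, n)
    event_times = dt * np.flatnonzero(counts)
    return I, event_times


def gen_spiky_voltage(
    spike_times,
    dt: float = DEFAULT_DT,
    baseline_mV: float = -70.0,
    peak_mV: float = 30.0,
    rise_ms: float = 0.7,
    fall_ms: float = 2.0,
    duration_ms: float | None = None,
) -> tuple[VoltageTrace, np.ndarray]:
    """Voltage trace with stereotyped planted action potentials.

    Each spike rises linearly from baseline to ``peak_mV`` over
    ``rise_ms`` and falls back over ``fall_ms``; the planted threshold
    time (the first sample whose forward slope exceeds 10 mV/ms) is the
    rise onset.  Spikes must not overlap.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=np.float64))
    width = rise_ms + fall_ms
    if spike_times.size > 1 and np.any(np.diff(spike_times) <= width + 2 * dt):
        raise ValueError("planted spikes overlap")
    if duration_ms is None:
        duration_ms = (spike_times[-1] + width + 50.0
                       if spike_times.size else 100.0)
    n = int(round(duration_ms / dt))
    V = np.full(n, baseline_mV)
    n_rise = max(1, int(round(rise_ms / dt)))
    n_fall = max(1, int(round(fall_ms / dt)))
    shape = np.concatenate([
        np.linspace(baseline_mV, peak_mV, n_rise + 1)[1:],
        np.linspace(peak_mV, baseline_mV, n_fall + 1)[1:],
    ])
    planted = []
    for ts in spike_times:
        s = int(round(ts / dt))
        if s + 1 + shape.size > n:
            raise ValueError("spike extends past trace end")
        V[s + 1:s + 1 + shape.size] = shape
        planted.append(s * dt)
    return (VoltageTrace(dt=dt, samples=V, t0=0.0,
                         meta={"planted": True}),
            np.asarray(planted))
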