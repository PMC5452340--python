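"""Activity clamp: conductance templates built from voltage-clamp current
recordings and played back into a (model) neuron.

A current recorded at holding potential V_hold isolates one synaptic
component; after subtracting the liquid junction potential (LJP) the true
membrane potential is V_m = V_hold − LJP and the conductance follows
Ohm's law, g = I / (V_rev − V_m).  Playback injects
I = g_E·(E_E − V) + g_I·(E_I − V) every step, so identical synaptic
barrages can be delivered repeatedly across pharmacological conditions.
Template amplitude is normalised per neuron by the conductance threshold:
the smallest number of simultaneous unitary AMPA-shaped conductances that
triggers an action potential.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .neuron import DEFAULT_DT, NeuronState, SimResult, T_NEVER, simulate_neuron
from .params import ReifParams


@dataclass(frozen=True)
class CurrentRecordingMeta:
    """Recording conditions needed to convert a current to a conductance."""

    holding_mV: float          # commanded holding potential
    ljp_mV: float              # liquid junction potential
    V_rev_mV: float            # assumed reversal of the isolated current
    dt_ms: float = DEFAULT_DT  # sampling interval

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def V_m(self) -> float:
        """True membrane potential after LJP correction."""
        return self.holding_mV - self.ljp_mV

    @property
    def driving_force(self) -> float:
        """Signed driving force V_rev − V_m (mV)."""
        return self.V_rev_mV - self.V_m


#: standard recording conditions for the two template components
EXCITATORY_META = CurrentRecordingMeta(holding_mV=-80.0, ljp_mV=13.6, V_rev_mV=0.0)
INHIBITORY_META = CurrentRecordingMeta(holding_mV=0.0, ljp_mV=13.6, V_rev_mV=-55.0)


@dataclass
class UnitaryEPSC:
    """Peak and kinetics of the unitary AMPA conductance, estimated from
    miniature EPSCs."""

    peak_nS: float = 0.3
    rise_ms: float = 0.5
    decay_ms: float = 3.0

    def __post_init__(self) -> None:
        if self.peak_nS <= 0:
            raise ValueError("peak conductance must be positive")
        if not 0 < self.rise_ms < self.decay_ms:
            raise ValueError("need decay > rise > 0")


@dataclass
class ConductanceTemplate:
    """Paired excitatory/inhibitory conductance series with burst windows."""

    dt: float
    g_E: np.ndarray            # nS
    g_I: np.ndarray            # nS
    E_E: float = 0.0           # playback reversal, mV
    E_I: float = -75.0
    windows: list = field(default_factory=list)   # (start_ms, end_ms)
    scale_factor: float = 1.0
    scaled: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.g_E = np.asarray(self.g_E, dtype=np.float64)
        self.g_I = np.asarray(self.g_I, dtype=np.float64)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.g_E.shape != self.g_I.shape:
            raise ValueError("g_E and g_I must have equal length")
        if self.g_E.min(initial=0.0) < 0 or self.g_I.min(initial=0.0) < 0:
            raise ValueError("conductances must be non-negative")
        self.windows = [tuple(map(float, w[:2])) for w in self.windows]
        for (s0, e0), (s1, _) in zip(self.windows, self.windows[1:]):
            if s0 > s1 or e0 > s1:
                raise ValueError("burst windows must be sorted, non-overlapping")

    @property
    def duration(self) -> float:
        return self.dt * self.g_E.size

    @property
    def onsets(self) -> np.ndarray:
        """Excitatory-conductance onset time per burst window (ms)."""
        return np.array([w[0] for w in self.windows])


def current_to_conductance(
    I: np.ndarray, meta: CurrentRecordingMeta
) -> tuple[np.ndarray, float]:
    """Convert a recorded current (pA) to a conductance series (nS).

    Returns ``(g, driving_force)`` with the driving force reported signed
    (V_rev − V_m after LJP correction).  The conductance is computed as
    |I| / |driving force| so it is non-negative regardless of which side
    of the reversal the cell was held on — the sign of the raw current
    only encodes its direction.
    """
    df = meta.driving_force
    if df == 0:
        raise ZeroDivisionError("driving force is zero; conductance undefined")
    g = np.abs(np.asarray(I, dtype=np.float64)) / abs(df)
    return g, df


def compute_charge_ratio(
    I_E: np.ndarray,
    I_I: np.ndarray,
    windows,
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Per-burst excitatory/inhibitory charge (pC) and their ratio.

    Q = |∫ I dt| over each window; ratio = Q_I / Q_E, flagged undefined
    where Q_E vanishes.  Both currents must share one time base.
    """
    I_E = np.asarray(I_E, dtype=np.float64)
    I_I = np.asarray(I_I, dtype=np.float64)
    if I_E.shape != I_I.shape:
        raise ValueError("currents must share one time base")
    rows = []
    for k, (s, e) in enumerate(windows):
        i0, i1 = int(round(s / dt)), int(round(e / dt))
        # rectangle rule matches the fixed-step sampling exactly
        q_e = abs(I_E[i0:i1].sum() * dt) / 1000.0  # pA·ms -> pC
        q_i = abs(I_I[i0:i1].sum() * dt) / 1000.0
        rows.append({
            "burst": k,
            "Q_E_pC": q_e,
            "Q_I_pC": q_i,
            "ratio": q_i / q_e if q_e > 0 else np.nan,
            "undefined": q_e == 0,
        })
    return pd.DataFrame(rows)


def unitary_epsc_waveform(
    u: UnitaryEPSC, dt: float = DEFAULT_DT, duration: float | None = None
) -> np.ndarray:
    """Difference-of-exponentials conductance waveform (nS), zero at t=0
    and normalised so its maximum equals ``u.peak_nS``."""
    tr, td = u.rise_ms, u.decay_ms
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    norm = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    if duration is None:
        duration = t_peak + td * math.log(1e4)
    t = dt * np.arange(int(round(duration / dt)))
    return u.peak_nS * (np.exp(-t / td) - np.exp(-t / tr)) / norm


def find_conductance_threshold(
    p: ReifParams,
    u: UnitaryEPSC,
    dt: float = DEFAULT_DT,
    *,
    V_E: float = 0.0,
    k_max: int = 1000,
    method: str = "scan",
    pad_ms: float = 50.0,
) -> tuple[int, float]:
    """Smallest integer k such that k simultaneous unitary conductances
    elicit at least one spike (deterministic neuron, sigma = 0).

    Returns ``(k, k · peak_nS)``.  ``method`` is ``scan`` (linear, always
    valid) or ``bisect`` (assumes spiking is monotone in k, which holds
    for this model).  Raises if no spike occurs up to ``k_max`` units.
    """
    wave = unitary_epsc_waveform(u, dt)
    pad = np.zeros(int(round(pad_ms / dt)))
    g_unit = np.concatenate([pad, wave, pad])

    def spikes(k: int) -> bool:
        res = simulate_neuron(
            p, {"g_E": k * g_unit, "V_E": V_E}, dt, sigma=0.0,
            state=NeuronState(V=p.V_L0, T=T_NEVER),
        )
        return res.spike_times.size > 0

    if not spikes(k_max):
        raise RuntimeError(
            f"no spike with up to {k_max} unitary conductances "
            f"({k_max * u.peak_nS:.1f} nS)"
        )
    if method == "scan":
        k = 1
        while not spikes(k):
            k += 1
    elif method == "bisect":
        lo, hi = 0, k_max  # lo never spikes, hi always does
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if spikes(mid):
                hi = mid
            else:
                lo = mid
        k = hi
    else:
        raise ValueError(f"unknown method {method!r}")
    return k, k * u.peak_nS


def scale_template(
    t: ConductanceTemplate, threshold_g: float
) -> ConductanceTemplate:
    """Scale both components by one factor so max(g_E) equals the
    neuron's conductance threshold; the factor is recorded."""
    peak = float(t.g_E.max(initial=0.0))
    if peak <= 0:
        raise ValueError("cannot scale a template with flat g_E")
    factor = threshold_g / peak
    return ConductanceTemplate(
        dt=t.dt, g_E=t.g_E * factor, g_I=t.g_I * factor,
        E_E=t.E_E, E_I=t.E_I, windows=list(t.windows),
        scale_factor=t.scale_factor * factor, scaled=True,
        meta=dict(t.meta),
    )


def play_template(
    p: ReifParams,
    t: ConductanceTemplate,
    repeats: int = 1,
    seed: int | None = None,
    *,
    sigma: float | None = None,
    V0: float | None = None,
    ljp_mV: float = 0.0,
) -> list[SimResult]:
    """Deliver the template ``repeats`` times; repeats differ only by
    their position in the noise stream.

    ``ljp_mV`` optionally shifts both playback reversals to the amplifier
    scale (E_eff = E_rev − LJP), mirroring the correction applied when
    driving a real cell; for a model neuron leave it 0.  An unscaled
    template is allowed but flagged in each result's metadata.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    drive = {
        "g_E": t.g_E, "g_I": t.g_I,
        "V_E": t.E_E - ljp_mV, "V_I": t.E_I - ljp_mV,
    }
    out = []
    for rep in range(repeats):
        res = simulate_neuron(
            p, drive, t.dt, rng=rng, sigma=sigma,
            state=NeuronState(V=p.V_L0 if V0 is None else V0, T=T_NEVER),
            meta={"repeat": rep, "unscaled_template": not t.scaled},
        )
        out.append(res)
    return out


def make_current_protocol(
    kind: str,
    amplitude: float,
    duration: float,
    dt: float = DEFAULT_DT,
    baseline_ms: float = 100.0,
    tail_ms: float = 100.0,
) -> np.ndarray:
    """Ramp or square-step current drive (pA) with zero-padded baseline.

    A ramp rises linearly from 0 to ``amplitude`` over ``duration``; a
    step holds ``amplitude`` throughout.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    n = int(round(duration / dt))
    if kind == "ramp":
        pulse = amplitude * np.arange(1, n + 1) / n
    elif kind == "step":
        pulse = np.full(n, amplitude)
    else:
        raise ValueError(f"unknown protocol kind {kind!r}")
    pre = np.zeros(int(round(baseline_ms / dt)))
    post = np.zeros(int(round(tail_ms / dt)))
    return np.concatenate([pre, pulse, post])


def write_template(path: str | Path, t: ConductanceTemplate) -> None:
    """Write columnar text (time_ms, gE_nS, gI_nS) plus a JSON sidecar."""
    path = Path(path)
    times = t.dt * np.arange(t.g_E.size)
    np.savetxt(path, np.column_stack([times, t.g_E, t.g_I]),
               fmt="%.6f", header="time_ms\tgE_nS\tgI_nS", delimiter="\t")
    sidecar = {
        "dt": t.dt, "E_E": t.E_E, "E_I": t.E_I,
        "windows": t.windows, "scale_factor": t.scale_factor,
        "scaled": t.scaled, "meta": t.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def read_template(path: str | Path) -> ConductanceTemplate:
    path = Path(path)
    data = np.loadtxt(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ConductanceTemplate(
        dt=sidecar["dt"], g_E=data[:, 1], g_I=data[:, 2],
        E_E=sidecar["E_E"], E_I=sidecar["E_I"],
        windows=[tuple(w) for w in sidecar["windows"]],
        scale_factor=sidecar["scale_factor"], scaled=sidecar["scaled"],
        meta=sidecar.get("meta", {}),
    )
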