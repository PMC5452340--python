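"""Spike-train and burst analysis.

Action potentials are accepted only if the voltage excursion crosses
0 mV and the maximal dV/dt of its rising slope exceeds 10 mV/ms; AP
timing is the voltage threshold, defined as the first point at which
dV/dt > 10 mV/ms preceding the 0 mV crossing.  Burst-level readouts are
per-window AP counts, first-AP latency from the excitatory-conductance
onset, across-repeat latency jitter (CV = SD/mean) and ordinal AP
reliability (fraction of repeats containing at least the i-th AP), and
interburst interval statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .neuron import VoltageTrace

AP_CROSS_MV = 0.0
AP_SLOPE_MV_PER_MS = 10.0


@dataclass
class SpikeTrain:
    """Accepted APs: threshold times plus per-spike peak and max slope."""

    times: np.ndarray          # ms, strictly increasing
    peak_V: np.ndarray         # mV
    max_dVdt: np.ndarray       # mV/ms

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def detect_aps(
    trace: VoltageTrace,
    cross_mV: float = AP_CROSS_MV,
    slope_thresh: float = AP_SLOPE_MV_PER_MS,
) -> SpikeTrain:
    """Detect action potentials in a voltage trace.

    One event is emitted per contiguous excursion above ``cross_mV``;
    the event is rejected if the maximal first-difference derivative
    between the start of its rising slope and its peak does not exceed
    ``slope_thresh``.  The event time is the first sample of the
    contiguous dV/dt-suprathreshold run leading into the crossing.
    """
    V = trace.samples
    dt = trace.dt
    if dt > 1.0:
        warnings.warn(
            f"dt = {dt} ms is coarse for a derivative criterion of "
            f"{slope_thresh} mV/ms", stacklevel=2,
        )
    times = trace.times
    dVdt = np.diff(V) / dt
    above = V > cross_mV
    edges = np.flatnonzero(np.diff(np.concatenate(
        ([0], above.view(np.int8), [0]))))
    out_t, out_peak, out_slope = [], [], []
    for i0, i1 in zip(edges[0::2], edges[1::2]):
        peak_idx = i0 + int(np.argmax(V[i0:i1]))
        # walk back through the contiguous suprathreshold-slope run
        k = i0
        while k > 0 and dVdt[k - 1] > slope_thresh:
            k -= 1
        seg = dVdt[k:max(peak_idx, k + 1)]
        max_slope = float(seg.max()) if seg.size else -np.inf
        if max_slope <= slope_thresh:
            continue
        out_t.append(times[k])
        out_peak.append(float(V[peak_idx]))
        out_slope.append(max_slope)
    return SpikeTrain(
        times=np.asarray(out_t), peak_V=np.asarray(out_peak),
        max_dVdt=np.asarray(out_slope),
    )


def burst_metrics(
    spikes,
    windows,
    onsets=None,
) -> tuple[pd.DataFrame, int]:
    """Assign APs to burst windows and compute per-burst readouts.

    ``spikes`` is a SpikeTrain or an array of AP times.  ``onsets`` are
    the per-window excitatory-conductance onset times (default: window
    starts); latency is first AP − onset.  Duration is last − first AP
    (0 for a single AP, NaN and flagged for none).  Returns the per-burst
    table and the number of APs falling outside every window.
    """
    t = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(
        spikes, dtype=np.float64)
    windows = [tuple(map(float, w[:2])) for w in windows]
    for (s0, e0), (s1, _) in zip(windows, windows[1:]):
        if e0 > s1:
            raise ValueError("burst windows overlap")
    if onsets is None:
        onsets = [w[0] for w in windows]
    rows = []
    assigned = np.zeros(t.size, dtype=bool)
    for k, ((s, e), onset) in enumerate(zip(windows, onsets)):
        in_w = (t >= s) & (t < e)
        assigned |= in_w
        tw = t[in_w]
        rows.append({
            "burst": k,
            "n_aps": int(tw.size),
            "first_latency_ms": float(tw[0] - onset) if tw.size else np.nan,
            "duration_ms": float(tw[-1] - tw[0]) if tw.size else np.nan,
            "no_ap": tw.size == 0,
        })
    return pd.DataFrame(rows), int((~assigned).sum())


def repeat_metrics(
    counts,
    latencies,
    max_ordinal: int = 5,
) -> dict:
    """Across-repeat statistics for one burst window.

    ``counts``: APs per repeat; ``latencies``: first-AP latency per repeat
    (NaN where no AP).  Jitter is CV = SD/mean of the latency across
    repeats with at least one AP (sample SD, n−1); undefined (NaN) for a
    zero mean or fewer than two latencies.  ``reliability[i-1]`` is the
    fraction of repeats containing at least i APs — monotonically
    non-increasing in i by construction.
    """
    counts = np.asarray(counts, dtype=np.float64)
    lat = np.asarray(latencies, dtype=np.float64)
    valid = lat[~np.isnan(lat)]
    mean = float(valid.mean()) if valid.size else np.nan
    sd = float(valid.std(ddof=1)) if valid.size >= 2 else np.nan
    cv = sd / mean if valid.size >= 2 and mean != 0 else np.nan
    reliability = np.array([
        float((counts >= i).mean()) for i in range(1, max_ordinal + 1)
    ])
    return {
        "n_repeats": int(counts.size),
        "latency_mean_ms": mean,
        "latency_sd_ms": sd,
        "jitter_cv": cv,
        "reliability": reliability,
    }


def interburst_stats(event_times) -> dict:
    """Mean, CV (sample SD / mean) and count of interburst intervals.

    Fewer than 2 events gives an empty result; CV requires at least 3
    events (2 intervals)."""
    t = np.sort(np.asarray(event_times, dtype=np.float64))
    if t.size < 2:
        return {"n_events": int(t.size), "n_intervals": 0,
                "mean_ms": np.nan, "cv": np.nan}
    iv = np.diff(t)
    cv = float(iv.std(ddof=1) / iv.mean()) if iv.size >= 2 else np.nan
    return {"n_events": int(t.size), "n_intervals": int(iv.size),
            "mean_ms": float(iv.mean()), "cv": cv}


def compare_paired(control, treated, test: str = "paired-t") -> dict:
    """Paired two-condition contrast with a recorded normality screen.

    ``test``: ``paired-t``, ``wilcoxon`` or ``sign``.  Effect is the mean
    treated − control difference.  Identical vectors give effect 0 and
    p = 1.  Deterministic given its inputs.
    """
    x = np.asarray(control, dtype=np.float64)
    y = np.asarray(treated, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = y - x
    effect = float(d.mean())
    try:
        normality_p = float(stats.normaltest(d).pvalue)
    except ValueError:
        normality_p = np.nan
    if np.all(d == 0):
        p = 1.0
    elif test == "paired-t":
        p = float(stats.ttest_rel(y, x).pvalue)
    elif test == "wilcoxon":
        p = float(stats.wilcoxon(y, x).pvalue)
    elif test == "sign":
        nz = d[d != 0]
        p = float(stats.binomtest(int((nz > 0).sum()), nz.size).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"test": test, "n": int(x.size), "effect": effect,
            "p": p, "normality_p": normality_p}
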