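"""All-to-all excitatory rEIF network with presynaptic vesicle depletion.

Every neuron's efferent drive is limited by a normalised pool N of
releasable glutamate vesicles: a spike releases the fraction r of the
pool into a postsynaptic conductance that decays with τ_GE, and the pool
refills towards 1 with τ_N,

    dN/dt = (1 − N)/τ_N − r·N·δ_s(t)
    dG_E/dt = −G_E/τ_GE + r·N·δ_s(t)

Each neuron then receives I_in = γ_max·(Γ_E·G_E)·(V_E − V) + I_0 where
Γ_E is a fixed random connectivity matrix with U(0,1) weights.  Slow
vesicle recovery makes population bursts self-limiting and sets the
seconds-scale refractory period between them; fewer spikes per burst
deplete less and shorten the next interburst interval — the mechanism by
which a slower spike-threshold recovery (the CBZ condition) paradoxically
speeds network bursting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import binomtest, pearsonr

from . import _kernels
from .neuron import DEFAULT_DT, T_NEVER
from .params import ReifParams, SynapseParams, apply_condition


@dataclass
class ConnectivityMatrix:
    """Square synaptic weight matrix with its generating seed."""

    W: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("connectivity must be a square matrix")
        if self.W.min() < 0 or self.W.max() > 1:
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class NetworkState:
    """Per-neuron voltage, time-since-spike, vesicle pool and efferent
    conductance."""

    V: np.ndarray
    T: np.ndarray
    N: np.ndarray
    G_E_out: np.ndarray

    @classmethod
    def initial(cls, n: int, p: ReifParams) -> "NetworkState":
        """Rest state: V at the basal leak reversal, never spiked, full
        vesicle pools, no efferent conductance."""
        return cls(
            V=np.full(n, p.V_L0),
            T=np.full(n, T_NEVER),
            N=np.ones(n),
            G_E_out=np.zeros(n),
        )


@dataclass
class NetworkRun:
    """Raster and decimated state traces of one network simulation."""

    n: int
    dt: float
    duration: float            # ms
    condition: str
    spike_times: np.ndarray    # ms
    spike_neurons: np.ndarray
    spike_release: np.ndarray  # vesicle fraction released at each spike
    rec_times: np.ndarray      # ms, decimated
    rec_N: np.ndarray          # (len(rec_times), n)
    rec_G_mean: np.ndarray     # population-mean efferent conductance
    config: dict = field(default_factory=dict)
    bursts: pd.DataFrame | None = None

    def to_hdf5(self, path) -> None:
        import h5py
        import json

        with h5py.File(path, "w") as f:
            ras = f.create_group("raster")
            ras.create_dataset("spike_times", data=self.spike_times)
            ras.create_dataset("spike_neurons", data=self.spike_neurons)
            ras.create_dataset("spike_release", data=self.spike_release)
            tr = f.create_group("traces")
            tr.create_dataset("times", data=self.rec_times)
            tr.create_dataset("N", data=self.rec_N)
            tr.create_dataset("G_mean", data=self.rec_G_mean)
            if self.bursts is not None and len(self.bursts):
                bg = f.create_group("bursts")
                for col in self.bursts.columns:
                    bg.create_dataset(col, data=self.bursts[col].to_numpy())
            cg = f.create_group("config")
            cg.attrs["json"] = json.dumps(
                {"n": self.n, "dt": self.dt, "duration": self.duration,
                 "condition": self.condition, **self.config}
            )

    @classmethod
    def from_hdf5(cls, path) -> "NetworkRun":
        import h5py
        import json

        with h5py.File(path, "r") as f:
            cfg = json.loads(f["config"].attrs["json"])
            bursts = None
            if "bursts" in f:
                bursts = pd.DataFrame(
                    {col: f["bursts"][col][()] for col in f["bursts"]}
                )
            return cls(
                n=cfg.pop("n"), dt=cfg.pop("dt"),
                duration=cfg.pop("duration"), condition=cfg.pop("condition"),
                spike_times=f["raster/spike_times"][()],
                spike_neurons=f["raster/spike_neurons"][()],
                spike_release=f["raster/spike_release"][()],
                rec_times=f["traces/times"][()],
                rec_N=f["traces/N"][()],
                rec_G_mean=f["traces/G_mean"][()],
                config=cfg, bursts=bursts,
            )


def sample_connectivity(n: int, seed: int | None = None) -> ConnectivityMatrix:
    """Draw an all-to-all weight matrix with i.i.d. U(0,1) entries.

    Self-connections are zeroed: autapses are biologically unintended and
    their inclusion would only rescale the recurrent drive.
    """
    if n < 2:
        raise ValueError(f"network needs at least 2 neurons, got {n}")
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.0, 1.0, size=(n, n))
    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(W=W, seed=seed)


def _pack_syn(sp: SynapseParams, normalize_by_n: bool, n: int) -> np.ndarray:
    """Effective coupling: the calibrated per-connection conductance
    ``coupling_scale·gamma_max/n`` by default, or the raw ``gamma_max``
    when per-connection normalisation is disabled."""
    gamma = (sp.coupling_scale * sp.gamma_max / n if normalize_by_n
             else sp.gamma_max)
    return np.array([sp.tau_N_ms, sp.r, sp.tau_GE, gamma, sp.I_0, sp.V_E])


def step_network(
    state: NetworkState,
    p: ReifParams,
    sp: SynapseParams,
    W: ConnectivityMatrix,
    dt: float = DEFAULT_DT,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
    normalize_by_n: bool = True,
) -> tuple[NetworkState, np.ndarray]:
    """Advance the network one step in place; returns (state, spike flags)."""
    n = W.n
    if state.V.size != n:
        raise ValueError("state and connectivity dimensions disagree")
    if noise is None:
        noise = (rng.standard_normal(n) if rng is not None else np.zeros(n))
    pv = _kernels.pack_params(p)
    sv = _pack_syn(sp, normalize_by_n, n)
    ev_step = np.empty(n, dtype=np.int64)
    ev_neuron = np.empty(n, dtype=np.int64)
    ev_release = np.empty(n, dtype=np.float64)
    nev, err = _kernels.network_chunk(
        state.V, state.T, state.N, state.G_E_out, W.W, pv, sv, dt,
        noise[None, :], ev_step, ev_neuron, ev_release,
    )
    if err == -2:
        raise FloatingPointError("vesicle pool left [0, 1]")
    if err >= 0:
        raise FloatingPointError("voltage became non-finite")
    flags = np.zeros(n, dtype=bool)
    flags[ev_neuron[:nev]] = True
    return state, flags


def simulate_network(
    *,
    n: int = 100,
    duration: float = 20_000.0,
    dt: float = DEFAULT_DT,
    condition: str = "control",
    seed: int = 0,
    connectivity: ConnectivityMatrix | None = None,
    connectivity_seed: int | None = None,
    p: ReifParams | None = None,
    sp: SynapseParams | None = None,
    sigma: float | None = None,
    normalize_by_n: bool = True,
    settle_ms: float = 3000.0,
    rec_every: float = 100.0,
) -> NetworkRun:
    """Simulate the network for ``duration`` ms under one condition.

    ``seed`` drives the shared voltage-noise stream (one draw per neuron
    per step, in a fixed order, so a reference implementation can consume
    identical draws); ``connectivity_seed`` (default: ``seed``) draws the
    weight matrix, letting paired condition runs share one structure.
    ``sigma`` overrides the noise intensity (mV/s^1/2).  Vesicle pools and
    the population-mean efferent conductance are recorded every
    ``rec_every`` ms.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if condition not in ("control", "cbz"):
        raise ValueError(f"unknown condition {condition!r}")
    base = ReifParams() if p is None else p
    base = apply_condition(base, condition)
    if sigma is not None:
        base = base.replace(sigma=sigma)
    syn = SynapseParams() if sp is None else sp
    if connectivity is None:
        connectivity = sample_connectivity(
            n, seed if connectivity_seed is None else connectivity_seed
        )
    if connectivity.n != n:
        raise ValueError("connectivity size does not match n")

    pv = _kernels.pack_params(base)
    sv = _pack_syn(syn, normalize_by_n, n)
    state = NetworkState.initial(n, base)
    rng = np.random.default_rng(seed)

    n_steps = int(round(duration / dt))
    # one integration chunk per recording interval
    chunk = max(1, int(round(rec_every / dt)))
    ev_t, ev_j, ev_r = [], [], []
    rec_t, rec_N, rec_G = [], [], []
    cap = chunk * n
    buf_step = np.empty(cap, dtype=np.int64)
    buf_neuron = np.empty(cap, dtype=np.int64)
    buf_release = np.empty(cap, dtype=np.float64)

    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        noise = rng.standard_normal((m, n)) if base.sigma > 0 else np.zeros((m, n))
        nev, err = _kernels.network_chunk(
            state.V, state.T, state.N, state.G_E_out, connectivity.W,
            pv, sv, dt, noise, buf_step, buf_neuron, buf_release,
        )
        if err == -2:
            raise FloatingPointError("vesicle pool left [0, 1]")
        if err >= 0:
            raise FloatingPointError(
                f"voltage became non-finite at t = {(done + err + 1) * dt} ms"
            )
        ev_t.append((done + buf_step[:nev] + 1.0) * dt)
        ev_j.append(buf_neuron[:nev].copy())
        ev_r.append(buf_release[:nev].copy())
        done += m
        rec_t.append(done * dt)
        rec_N.append(state.N.copy())
        rec_G.append(state.G_E_out.mean())

    run = NetworkRun(
        n=n, dt=dt, duration=duration, condition=condition,
        spike_times=np.concatenate(ev_t) if ev_t else np.empty(0),
        spike_neurons=np.concatenate(ev_j) if ev_j else np.empty(0, dtype=np.int64),
        spike_release=np.concatenate(ev_r) if ev_r else np.empty(0),
        rec_times=np.asarray(rec_t),
        rec_N=np.asarray(rec_N),
        rec_G_mean=np.asarray(rec_G),
        config={
            "seed": seed,
            "connectivity_seed": connectivity.seed,
            "neuron": base.to_dict(),
            "synapse": syn.to_dict(),
            "normalize_by_n": normalize_by_n,
            "settle_ms": settle_ms,
        },
    )
    run.bursts = detect_population_bursts(run, settle_ms=settle_ms)
    return run


def detect_population_bursts(
    run: NetworkRun,
    bin_ms: float = 5.0,
    smooth_ms: float = 20.0,
    onset_frac: float = 0.2,
    min_gap_ms: float = 100.0,
    min_spikes: int = 10,
    settle_ms: float = 0.0,
) -> pd.DataFrame:
    """Segment population bursts from the spike raster.

    The population spike count is binned at ``bin_ms``, smoothed with a
    Gaussian of width ``smooth_ms``, and bursts are the maximal intervals
    where the smoothed rate exceeds ``onset_frac`` of its peak; intervals
    separated by less than ``min_gap_ms`` are merged and bursts with fewer
    than ``min_spikes`` raw spikes discarded.  Spikes before ``settle_ms``
    are ignored, discarding the synchronised transient caused by starting
    every neuron at rest with a full vesicle pool (which would otherwise
    dominate the peak-relative threshold).  Deterministic given the
    raster.  Returns one row per burst with boundaries, spike counts,
    participating neurons and the population-mean released vesicle
    fraction.
    """
    cols = ["start_ms", "end_ms", "n_spikes", "n_neurons",
            "spikes_per_neuron", "release_per_neuron"]
    keep = run.spike_times >= settle_ms
    spike_times = run.spike_times[keep]
    spike_neurons = run.spike_neurons[keep]
    spike_release = run.spike_release[keep]
    if spike_times.size == 0:
        return pd.DataFrame(columns=cols)
    n_bins = max(1, int(np.ceil(run.duration / bin_ms)))
    counts, edges = np.histogram(
        spike_times, bins=n_bins, range=(0.0, n_bins * bin_ms)
    )
    rate = gaussian_filter1d(counts.astype(float), smooth_ms / bin_ms)
    peak = rate.max()
    if peak <= 0:
        return pd.DataFrame(columns=cols)
    above = rate > onset_frac * peak
    # contiguous above-threshold segments
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, ends = idx[0::2], idx[1::2]
    # merge segments separated by less than min_gap_ms
    merged = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) * bin_ms < min_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    rows = []
    for s, e in merged:
        t0, t1 = edges[s], edges[e]
        mask = (spike_times >= t0) & (spike_times < t1)
        n_spk = int(mask.sum())
        if n_spk < min_spikes:
            continue
        rows.append({
            "start_ms": t0,
            "end_ms": t1,
            "n_spikes": n_spk,
            "n_neurons": int(np.unique(spike_neurons[mask]).size),
            "spikes_per_neuron": n_spk / run.n,
            "release_per_neuron": float(spike_release[mask].sum()) / run.n,
        })
    return pd.DataFrame(rows, columns=cols)


def burst_release(run: NetworkRun, start_ms: float, end_ms: float) -> float:
    """Population-mean vesicle fraction released in a window (bookkeeping
    sum of r·N over spikes, divided by network size)."""
    mask = (run.spike_times >= start_ms) & (run.spike_times < end_ms)
    return float(run.spike_release[mask].sum()) / run.n


def _run_summary(run: NetworkRun, seed) -> dict:
    b = run.bursts if run.bursts is not None else detect_population_bursts(run)
    intervals = (b["start_ms"].to_numpy()[1:] - b["end_ms"].to_numpy()[:-1]
                 if len(b) >= 2 else np.empty(0))
    return {
        "seed": seed,
        "condition": run.condition,
        "n_bursts": len(b),
        "mean_ibi_ms": float(intervals.mean()) if intervals.size else np.nan,
        "cv_ibi": (float(intervals.std(ddof=1) / intervals.mean())
                   if intervals.size >= 2 else np.nan),
        "mean_spikes_per_neuron_per_burst":
            float(b["spikes_per_neuron"].mean()) if len(b) else np.nan,
        "mean_release_per_burst":
            float(b["release_per_neuron"].mean()) if len(b) else np.nan,
        "flagged_few_bursts": len(b) < 2,
    }


def _release_interval_pairs(runs: list[NetworkRun]) -> np.ndarray:
    """Pooled (per-burst release, following interburst interval) pairs."""
    pairs = []
    for run in runs:
        b = run.bursts
        if b is None or len(b) < 2:
            continue
        rel = b["release_per_neuron"].to_numpy()[:-1]
        nxt = b["start_ms"].to_numpy()[1:] - b["end_ms"].to_numpy()[:-1]
        pairs.append(np.column_stack([rel, nxt]))
    return np.concatenate(pairs) if pairs else np.empty((0, 2))


def summarize_run(
    runs_control: list[NetworkRun],
    runs_cbz: list[NetworkRun],
    seeds: list | None = None,
) -> dict:
    """Per-run burst statistics and paired condition contrasts.

    Runs are paired positionally (same connectivity seed).  Interburst
    intervals are measured end-of-burst to start-of-next.  Returns a dict
    with ``per_run`` and ``pairs`` DataFrames plus pooled release-vs-next-
    interval Pearson correlations and sign-test p-values for the paired
    contrasts (fewer spikes per burst, shorter intervals under cbz).
    """
    if not runs_control or len(runs_control) != len(runs_cbz):
        raise ValueError("need equally many control and cbz runs, >= 1 each")
    if seeds is None:
        seeds = [r.config.get("seed") for r in runs_control]
    per_run = pd.DataFrame(
        [_run_summary(r, s) for r, s in zip(runs_control, seeds)]
        + [_run_summary(r, s) for r, s in zip(runs_cbz, seeds)]
    )
    ctrl = per_run[per_run.condition == "control"].set_index("seed")
    cbz = per_run[per_run.condition == "cbz"].set_index("seed")
    pairs = pd.DataFrame({
        "seed": ctrl.index,
        "d_spikes_per_burst": (
            cbz["mean_spikes_per_neuron_per_burst"]
            - ctrl["mean_spikes_per_neuron_per_burst"]
        ).to_numpy(),
        "d_ibi_ms": (cbz["mean_ibi_ms"] - ctrl["mean_ibi_ms"]).to_numpy(),
    })
    valid = pairs.dropna()

    def _sign_p(d: np.ndarray) -> float:
        d = d[d != 0]
        if d.size == 0:
            return 1.0
        return float(binomtest(int((d < 0).sum()), d.size,
                               alternative="greater").pvalue)

    pooled = {}
    for label, runs in (("control", runs_control), ("cbz", runs_cbz)):
        pts = _release_interval_pairs(runs)
        if pts.shape[0] >= 3:
            r_val, p_val = pearsonr(pts[:, 0], pts[:, 1])
        else:
            r_val = p_val = np.nan
        pooled[label] = {
            "release_interval_corr": float(r_val),
            "release_interval_p": float(p_val),
            "n_pairs": int(pts.shape[0]),
        }
    return {
        "per_run": per_run,
        "pairs": pairs,
        "frac_pairs_fewer_spikes": float(
            (valid["d_spikes_per_burst"] < 0).mean()) if len(valid) else np.nan,
        "frac_pairs_shorter_ibi": float(
            (valid["d_ibi_ms"] < 0).mean()) if len(valid) else np.nan,
        "sign_p_spikes": _sign_p(valid["d_spikes_per_burst"].to_numpy()),
        "sign_p_ibi": _sign_p(valid["d_ibi_ms"].to_numpy()),
        "pooled_correlation": pooled,
    }
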