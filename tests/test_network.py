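"""Vesicle-depletion network: connectivity sampling, release bookkeeping,
equivalence with a pure-Python reference, burst detection and summaries."""

import copy
import math

import numpy as np
import pandas as pd
import pytest

from reifburst import (
    ConnectivityMatrix,
    NetworkRun,
    NetworkState,
    ReifParams,
    SynapseParams,
    detect_population_bursts,
    sample_connectivity,
    simulate_network,
    step_network,
    summarize_run,
)
from reifburst import _kernels

from _oracles import reference_network


class TestConnectivity:
    def test_shape_range_and_zero_diagonal(self):
        W = sample_connectivity(100, seed=0)
        assert W.W.shape == (100, 100)
        off = W.W[~np.eye(100, dtype=bool)]
        assert off.min() >= 0 and off.max() <= 1
        assert np.all(np.diag(W.W) == 0)

    def test_reproducible_for_fixed_seed(self):
        assert np.array_equal(sample_connectivity(50, seed=9).W,
                              sample_connectivity(50, seed=9).W)

    def test_off_diagonal_mean_is_uniform(self):
        W = sample_connectivity(200, seed=4)
        off = W.W[~np.eye(200, dtype=bool)]
        se = math.sqrt(1 / 12 / off.size)
        assert abs(off.mean() - 0.5) < 3 * se

    def test_too_small_network_rejected(self):
        with pytest.raises(ValueError):
            sample_connectivity(1)

    def test_out_of_range_weights_rejected(self):
        with pytest.raises(ValueError):
            ConnectivityMatrix(W=np.full((3, 3), 1.5))


class TestVesicleDynamics:
    def test_single_spike_releases_fixed_fraction(self, p_control, sp_default):
        """A spike from a full pool releases r = 0.3, leaving N = 0.7."""
        W = sample_connectivity(2, seed=0)
        state = NetworkState.initial(2, p_control)
        state.V[0] = -36.0  # above the absolute threshold after any step
        p0 = p_control.replace(sigma=0.0)
        state, flags = step_network(state, p0, sp_default, W)
        assert flags[0] and not flags[1]
        assert state.N[0] == pytest.approx(0.7, abs=1e-6)
        assert state.G_E_out[0] == pytest.approx(0.3, abs=1e-6)
        assert state.V[0] == p_control.V_r

    def test_recovery_follows_closed_form(self, p_control, sp_default):
        """After depletion to 0.7 the pool recovers as 1 − 0.3·exp(−t/τ_N)."""
        n, dt = 2, 0.1
        pv = _kernels.pack_params(p_control.replace(sigma=0.0))
        sv = np.array([sp_default.tau_N_ms, sp_default.r, sp_default.tau_GE,
                       0.0, 0.0, sp_default.V_E])  # no coupling, no tonic drive
        V = np.full(n, -75.0)
        T = np.full(n, np.inf)
        N = np.full(n, 0.7)
        G = np.zeros(n)
        steps = int(round(8000.0 / dt))
        noise = np.zeros((steps, n))
        buf = (np.empty(steps, np.int64), np.empty(steps, np.int64),
               np.empty(steps, np.float64))
        nev, err = _kernels.network_chunk(V, T, N, G, sample_connectivity(
            n, 0).W, pv, sv, dt, noise, *buf)
        assert nev == 0 and err == -1
        expected = 1.0 - 0.3 * math.exp(-1.0)  # τ_N = 8 s, t = 8 s
        assert N[0] == pytest.approx(expected, abs=1e-4)

    def test_quiet_network_recovers_without_conductance(self, p_control,
                                                        sp_default):
        run = simulate_network(n=5, duration=2000.0, seed=0, sigma=0.0,
                               sp=sp_default.replace(I_0=0.0),
                               settle_ms=0.0)
        assert run.spike_times.size == 0
        assert np.all(run.rec_G_mean == 0.0)
        assert np.all(run.rec_N == 1.0)  # full pools stay full without spikes

    def test_state_invariants_on_recorded_traces(self):
        run = simulate_network(n=30, duration=10_000.0, seed=2)
        assert run.rec_N.min() >= 0.0 and run.rec_N.max() <= 1.0
        assert run.rec_G_mean.min() >= 0.0
        assert np.all((run.spike_release > 0) & (run.spike_release <= 0.3))


class TestReferenceEquivalence:
    def test_trajectories_match_pure_python_reference(self, p_control,
                                                      sp_default):
        """The compiled simulator and an independent pure-Python
        transcription consuming the same noise stream must agree
        trajectory-for-trajectory."""
        n, dur, seed = 6, 2000.0, 3
        W = sample_connectivity(n, seed=seed)
        run = simulate_network(n=n, duration=dur, seed=seed, connectivity=W,
                               settle_ms=0.0)
        V, T, N, G, spikes = reference_network(
            n, dur, 0.1, seed, ReifParams(), sp_default, W.W)
        assert run.spike_times.size == len(spikes)
        np.testing.assert_allclose(run.spike_times,
                                   [s[0] for s in spikes], rtol=0, atol=1e-9)
        np.testing.assert_array_equal(run.spike_neurons,
                                      [s[1] for s in spikes])
        np.testing.assert_allclose(run.spike_release,
                                   [s[2] for s in spikes], rtol=1e-9)
        np.testing.assert_allclose(run.rec_N[-1], N, rtol=1e-9)

    def test_conditions_differ_only_in_tau_vt(self):
        W = sample_connectivity(10, seed=1)
        a = simulate_network(n=10, duration=500.0, seed=1, connectivity=W,
                             condition="control")
        b = simulate_network(n=10, duration=500.0, seed=1, connectivity=W,
                             condition="cbz")
        na, nb = a.config["neuron"], b.config["neuron"]
        assert {k for k in na if na[k] != nb[k]} == {"tau_VT"}
        assert a.config["synapse"] == b.config["synapse"]


def _synthetic_run(burst_times, n=50, duration=30_000.0, rng=None,
                   spikes_per_burst=400, background_hz=0.5):
    """Raster with planted population bursts plus sparse background."""
    rng = rng or np.random.default_rng(0)
    times, neurons = [], []
    for bt in burst_times:
        times.append(bt + rng.uniform(0.0, 60.0, spikes_per_burst))
        neurons.append(rng.integers(0, n, spikes_per_burst))
    n_bg = rng.poisson(background_hz * n * duration / 1000.0)
    times.append(rng.uniform(0, duration, n_bg))
    neurons.append(rng.integers(0, n, n_bg))
    t = np.concatenate(times)
    order = np.argsort(t)
    return NetworkRun(
        n=n, dt=0.1, duration=duration, condition="control",
        spike_times=t[order],
        spike_neurons=np.concatenate(neurons)[order],
        spike_release=np.full(t.size, 0.1)[order],
        rec_times=np.array([duration]), rec_N=np.ones((1, n)),
        rec_G_mean=np.array([0.0]),
    )


class TestBurstDetection:
    def test_silent_raster_yields_no_bursts(self):
        run = NetworkRun(n=10, dt=0.1, duration=1000.0, condition="control",
                         spike_times=np.empty(0),
                         spike_neurons=np.empty(0, dtype=np.int64),
                         spike_release=np.empty(0),
                         rec_times=np.array([1000.0]),
                         rec_N=np.ones((1, 10)), rec_G_mean=np.array([0.0]))
        assert len(detect_population_bursts(run)) == 0

    def test_planted_bursts_recovered_with_tight_boundaries(self, rng):
        planted = np.array([2000.0, 7000.0, 13_000.0, 19_000.0, 26_000.0])
        run = _synthetic_run(planted, rng=rng)
        bursts = detect_population_bursts(run)
        assert len(bursts) == 5
        np.testing.assert_allclose(bursts["start_ms"], planted, atol=50.0)
        np.testing.assert_allclose(bursts["end_ms"], planted + 60.0,
                                   atol=50.0)

    def test_detected_bursts_recruit_most_of_the_network(self):
        run = simulate_network(n=100, duration=10_000.0, seed=5)
        bursts = run.bursts
        assert len(bursts) >= 2
        # occasional partial-recruitment flickers are allowed, but the
        # bulk of detected bursts must engage most of the network
        assert (bursts["n_neurons"] > 50).mean() >= 0.8

    def test_release_bookkeeping_matches_raster_sum(self):
        run = simulate_network(n=50, duration=8000.0, seed=6)
        for _, row in run.bursts.iterrows():
            mask = ((run.spike_times >= row.start_ms)
                    & (run.spike_times < row.end_ms))
            assert row.release_per_neuron == pytest.approx(
                run.spike_release[mask].sum() / run.n)


def _run_with_bursts(bursts_df, condition="control", seed=0):
    run = NetworkRun(
        n=10, dt=0.1, duration=60_000.0, condition=condition,
        spike_times=np.empty(0), spike_neurons=np.empty(0, dtype=np.int64),
        spike_release=np.empty(0), rec_times=np.array([0.0]),
        rec_N=np.ones((1, 10)), rec_G_mean=np.array([0.0]),
        config={"seed": seed},
    )
    run.bursts = bursts_df
    return run


class TestSummaries:
    def test_release_proportional_to_next_interval_gives_unit_correlation(self):
        starts = np.array([0.0, 2000.0, 5000.0, 9000.0, 14_000.0, 20_000.0])
        ends = starts + 100.0
        releases = np.empty(starts.size)
        releases[:-1] = (starts[1:] - ends[:-1]) / 10_000.0
        releases[-1] = 0.5
        df = pd.DataFrame({
            "start_ms": starts, "end_ms": ends,
            "n_spikes": 100, "n_neurons": 10,
            "spikes_per_neuron": 10.0, "release_per_neuron": releases,
        })
        out = summarize_run([_run_with_bursts(df)],
                            [_run_with_bursts(df, condition="cbz")])
        corr = out["pooled_correlation"]["control"]
        assert corr["n_pairs"] == 5
        assert corr["release_interval_corr"] == pytest.approx(1.0)

    def test_single_burst_run_is_flagged_and_excluded(self):
        df = pd.DataFrame({
            "start_ms": [100.0], "end_ms": [200.0], "n_spikes": [50],
            "n_neurons": [10], "spikes_per_neuron": [5.0],
            "release_per_neuron": [0.2],
        })
        out = summarize_run([_run_with_bursts(df)],
                            [_run_with_bursts(df, condition="cbz")])
        assert out["per_run"]["flagged_few_bursts"].all()
        assert out["pooled_correlation"]["control"]["n_pairs"] == 0
        assert np.isnan(
            out["pooled_correlation"]["control"]["release_interval_corr"])


class TestSimulateNetworkContracts:
    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            simulate_network(n=100, duration=-1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_network(n=100, duration=100.0, condition="placebo",
                             seed=0)

    def test_hdf5_round_trip(self, tmp_path):
        run = simulate_network(n=20, duration=3000.0, seed=1)
        path = tmp_path / "run.h5"
        run.to_hdf5(path)
        back = NetworkRun.from_hdf5(path)
        np.testing.assert_array_equal(back.spike_times, run.spike_times)
        np.testing.assert_array_equal(back.rec_N, run.rec_N)
        assert back.condition == run.condition
        assert back.config["seed"] == run.config["seed"]
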