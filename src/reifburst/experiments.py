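"""The two headline in-silico experiments.

``run_activity_clamp_experiment`` mirrors the paired single-neuron
protocol: calibrate the conductance threshold, scale an epileptiform
template to it, play it back repeatedly under control and under the
CBZ-like condition (tau_VT 13 -> 15 ms), and tabulate per-burst AP
counts, first-AP latencies, jitter and ordinal AP reliability.

``run_network_experiment`` mirrors the paired network protocol: for each
seed draw one connectivity matrix, simulate both conditions on the same
structure and noise stream, and summarise burst frequency, spikes per
burst and vesicle release against the following interburst interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clamp, metrics, network
from .params import ReifParams, SynapseParams, apply_condition
from .synth import TemplateGenConfig, gen_template

CONDITIONS = ("control", "cbz")


@dataclass
class ExperimentConfig:
    """Resolved configuration embedded verbatim in every report."""

    name: str
    seeds: list = field(default_factory=lambda: list(range(10)))
    conditions: tuple = CONDITIONS
    neuron: dict = field(default_factory=lambda: ReifParams().to_dict())
    synapse: dict = field(default_factory=lambda: SynapseParams().to_dict())
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("need at least one seed")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")


def _playback_tables(results, template, condition):
    """Per (repeat, burst) AP counts and latencies from playback runs."""
    onsets = template.onsets
    rows = []
    for rep, res in enumerate(results):
        table, outside = metrics.burst_metrics(
            res.spike_times, template.windows, onsets)
        table["repeat"] = rep
        table["condition"] = condition
        table["aps_outside_windows"] = outside
        rows.append(table)
    return pd.concat(rows, ignore_index=True)


def run_activity_clamp_experiment(
    template_cfg: TemplateGenConfig | None = None,
    template: clamp.ConductanceTemplate | None = None,
    p: ReifParams | None = None,
    u: clamp.UnitaryEPSC | None = None,
    repeats: int = 30,
    seed: int = 0,
    conditions: tuple = CONDITIONS,
) -> dict:
    """Paired control-vs-CBZ activity-clamp playback on the model neuron.

    Per condition the protocol is: calibrate the conductance threshold
    (deterministically, sigma = 0), scale the template so max(g_E) meets
    it, run one deterministic playback (the noise-free paired comparison)
    and ``repeats`` stochastic playbacks (30, as in the paired recording
    protocol), then compute burst metrics and paired contrasts across
    bursts.
    """
    if template is None:
        if template_cfg is None:
            template_cfg = TemplateGenConfig(seed=seed)
        template = gen_template(template_cfg)
    if not template.windows:
        raise ValueError("template carries no burst windows")
    base = ReifParams() if p is None else p
    u = clamp.UnitaryEPSC() if u is None else u

    thresholds = {}
    det_tables = []
    rep_tables = []
    rel_rows = []
    for ci, condition in enumerate(conditions):
        pc = apply_condition(base, condition)
        k, g_thr = clamp.find_conductance_threshold(pc, u, template.dt,
                                                    method="bisect")
        thresholds[condition] = {"k_units": k, "threshold_nS": g_thr}
        scaled = clamp.scale_template(template, g_thr)
        det = clamp.play_template(pc, scaled, repeats=1, sigma=0.0)
        det_tables.append(_playback_tables(det, scaled, condition))
        sto = clamp.play_template(pc, scaled, repeats=repeats,
                                  seed=seed * 1000 + ci)
        rep_table = _playback_tables(sto, scaled, condition)
        rep_tables.append(rep_table)
        for burst, grp in rep_table.groupby("burst"):
            rm = metrics.repeat_metrics(grp["n_aps"].to_numpy(),
                                        grp["first_latency_ms"].to_numpy())
            rel_rows.append({
                "condition": condition, "burst": burst,
                "latency_mean_ms": rm["latency_mean_ms"],
                "jitter_cv": rm["jitter_cv"],
                "reliability_1": rm["reliability"][0],
                "reliability_2": rm["reliability"][1],
                "reliability_3": rm["reliability"][2],
            })

    det = pd.concat(det_tables, ignore_index=True)
    rep = pd.concat(rep_tables, ignore_index=True)
    rel = pd.DataFrame(rel_rows)

    piv = det.pivot_table(index="burst", columns="condition",
                          values="n_aps", aggfunc="first")
    lat = det.pivot_table(index="burst", columns="condition",
                          values="first_latency_ms", aggfunc="first")
    contrasts = {
        "aps_per_burst": metrics.compare_paired(
            piv["control"], piv["cbz"], test="wilcoxon"),
        "frac_bursts_cbz_not_more": float(
            (piv["cbz"] <= piv["control"]).mean()),
        "mean_aps_control": float(piv["control"].mean()),
        "mean_aps_cbz": float(piv["cbz"].mean()),
        "mean_latency_control_ms": float(lat["control"].mean()),
        "mean_latency_cbz_ms": float(lat["cbz"].mean()),
        "second_ap_rate_control": float((piv["control"] >= 2).mean()),
        "second_ap_rate_cbz": float((piv["cbz"] >= 2).mean()),
    }
    relp = rel.pivot_table(index="burst", columns="condition",
                           values="reliability_2")
    if set(relp.columns) == set(CONDITIONS):
        contrasts["reliability_2_control"] = float(relp["control"].mean())
        contrasts["reliability_2_cbz"] = float(relp["cbz"].mean())
    return {
        "thresholds": thresholds,
        "deterministic": det,
        "repeats": rep,
        "repeat_summary": rel,
        "contrasts": contrasts,
        "report": {
            "experiment": "activity_clamp",
            "seed": seed,
            "repeats": repeats,
            "conditions": list(conditions),
            "neuron": base.to_dict(),
            "unitary": vars(u),
            "template_windows": list(template.windows),
        },
    }


def run_network_experiment(
    seeds=tuple(range(10)),
    n: int = 100,
    duration: float = 20_000.0,
    p: ReifParams | None = None,
    sp: SynapseParams | None = None,
    conditions: tuple = CONDITIONS,
    **sim_kwargs,
) -> dict:
    """Paired control-vs-CBZ network simulations across seeds.

    For each seed one connectivity matrix is drawn and both conditions
    are simulated on that structure with identical noise streams, so the
    contrast isolates the tau_VT change.  ``duration`` is in ms (20 s
    quick mode by default; pass 200_000 for the full-length protocol).
    Runs with fewer than two bursts are flagged and excluded from
    interval statistics.
    """
    runs = {c: [] for c in conditions}
    for seed in seeds:
        W = network.sample_connectivity(n, seed=seed)
        for condition in conditions:
            runs[condition].append(network.simulate_network(
                n=n, duration=duration, condition=condition, seed=seed,
                connectivity=W, p=p, sp=sp, **sim_kwargs,
            ))
    summary = network.summarize_run(runs["control"], runs["cbz"],
                                    seeds=list(seeds))
    summary["report"] = {
        "experiment": "network",
        "seeds": list(seeds),
        "n": n,
        "duration_ms": duration,
        "conditions": list(conditions),
        "neuron": (ReifParams() if p is None else p).to_dict(),
        "synapse": (SynapseParams() if sp is None else sp).to_dict(),
        "sim_kwargs": {k: v for k, v in sim_kwargs.items()},
    }
    summary["runs"] = runs
    return summary
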