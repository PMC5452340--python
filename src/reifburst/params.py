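"""Model parameter containers and condition handling.

Internal unit system: mV / ms / pA / nS / pF, which is self-consistent
(nS * mV = pA and pF * mV / ms = pA).  Two constants are conventionally
quoted on a seconds base — the vesicle recovery constant ``tau_N`` (s) and
the voltage noise intensity ``sigma`` (mV / s^1/2) — and are converted to
the ms base on access, never stored twice.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

#: tau_VT (ms) for the two experimental conditions.  Carbamazepine (CBZ) is
#: modelled purely as a slower post-spike recovery of the soft spike
#: threshold, reflecting slower recovery of sodium channels from
#: inactivation under use-dependent block.
CONDITION_TAU_VT = {"control": 13.0, "cbz": 15.0}

_MS_PER_S = 1000.0


@dataclass(frozen=True)
class ReifParams:
    """Single-neuron constants of the refractory exponential
    integrate-and-fire (rEIF) model.

    Four parameters — leak conductance ``G_L``, leak reversal ``V_L``, soft
    spike threshold ``V_T`` and spike-width parameter ``Delta_T`` — relax
    exponentially back to their basal values as a function of the time
    since the last spike; the amplitudes ``a_*`` (and the second leak
    reversal term ``b_VL``) are the deviations imposed at the moment of a
    spike.
    """

    C: float = 170.0          # membrane capacitance, pF
    V_Tabs: float = -37.0     # absolute spike threshold, mV
    V_r: float = -43.0        # reset voltage, mV
    G_L0: float = 6.8         # basal leak conductance, nS
    a_GL: float = 9.0         # leak conductance increment after a spike, nS
    tau_GL: float = 30.0      # its decay constant, ms
    V_L0: float = -75.0       # basal leak reversal, mV
    a_VL: float = 16.0        # first leak-reversal deviation, mV
    tau_VLa: float = 25.0     # its decay constant, ms
    b_VL: float = -10.0       # second leak-reversal deviation, mV
    tau_VLb: float = 100.0    # its decay constant, ms
    V_T0: float = -52.0       # basal soft spike threshold, mV
    a_VT: float = 15.0        # threshold deviation after a spike, mV
    tau_VT: float = 13.0      # threshold recovery constant, ms (control)
    DeltaT0: float = 2.0      # basal spike-width parameter, mV
    a_DeltaT: float = 0.0     # its deviation, mV
    tau_DeltaT: float = 0.005  # its decay constant, ms
    # Calibrated: gives a stationary membrane-voltage SD of ~2.8 mV and a
    # sub-Hz spontaneous rate under the tonic network input, consistent
    # with quiescent interburst traces (see docs/methods.md).
    sigma: float = 25.0       # voltage noise intensity, mV / s^1/2

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"capacitance must be positive, got {self.C}")
        if self.G_L0 < 0 or self.G_L0 + self.a_GL < 0:
            raise ValueError("leak conductance must stay non-negative")
        for name in ("tau_GL", "tau_VLa", "tau_VLb", "tau_VT", "tau_DeltaT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.DeltaT0 <= 0:
            raise ValueError("DeltaT0 must be positive")
        if not self.V_r < self.V_Tabs:
            raise ValueError("reset voltage must lie below the absolute threshold")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def sigma_ms(self) -> float:
        """Noise intensity on the ms base, mV / ms^1/2."""
        return self.sigma / math.sqrt(_MS_PER_S)

    def replace(self, **changes) -> "ReifParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReifParams":
        return cls(**d)


@dataclass(frozen=True)
class SynapseParams:
    """Constants of the all-to-all excitatory vesicle-depletion network."""

    tau_N: float = 8.0        # vesicle recovery constant, s
    r: float = 0.3            # fraction of available vesicles released per spike
    tau_GE: float = 10.0      # efferent conductance decay constant, ms
    gamma_max: float = 267.0  # scaling of the connectivity matrix, nS
    # Calibrated multiplier on the per-connection conductance
    # gamma_max / n; with it the control network shows self-limiting
    # recurrent population bursts (see docs/methods.md).
    coupling_scale: float = 5.0
    I_0: float = 128.0        # tonic current input to all neurons, pA
    V_E: float = 0.0          # excitatory reversal, mV
    V_I: float = -56.0        # inhibitory reversal, mV (playback only)

    def __post_init__(self) -> None:
        if not 0 < self.r < 1:
            raise ValueError(f"release fraction r must lie in (0, 1), got {self.r}")
        if self.tau_N <= 0 or self.tau_GE <= 0:
            raise ValueError("time constants must be positive")
        if self.gamma_max < 0 or self.coupling_scale <= 0:
            raise ValueError("coupling must be non-negative")

    @property
    def tau_N_ms(self) -> float:
        return self.tau_N * _MS_PER_S

    def replace(self, **changes) -> "SynapseParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynapseParams":
        return cls(**d)


def apply_condition(p: ReifParams, condition: str) -> ReifParams:
    """Return a copy of ``p`` with ``tau_VT`` set for the given condition.

    ``control`` restores the baseline recovery (13 ms); ``cbz`` slows it
    (15 ms).  Every other field is untouched, so paired simulations differ
    in exactly one parameter.  Idempotent.
    """
    try:
        tau = CONDITION_TAU_VT[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of "
            f"{sorted(CONDITION_TAU_VT)}"
        ) from None
    return p.replace(tau_VT=tau)


def load_params(path: str | Path) -> tuple[ReifParams, SynapseParams]:
    """Load both parameter sets from a JSON config.

    The file holds two objects under the keys ``neuron`` and ``synapse``;
    either may be partial, in which case defaults fill the gaps.
    """
    with open(path) as fh:
        cfg = json.load(fh)
    neuron = {**ReifParams().to_dict(), **cfg.get("neuron", {})}
    synapse = {**SynapseParams().to_dict(), **cfg.get("synapse", {})}
    return ReifParams.from_dict(neuron), SynapseParams.from_dict(synapse)


def save_params(path: str | Path, p: ReifParams, sp: SynapseParams) -> None:
    with open(path, "w") as fh:
        json.dump({"neuron": p.to_dict(), "synapse": sp.to_dict()}, fh, indent=2)
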