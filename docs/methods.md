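# Methods

## Scope

`reifburst` reproduces, on synthetic data, a two-level analysis of how a
use-dependent sodium-channel blocker (carbamazepine, CBZ) can *reduce*
the spiking of individual neurons during epileptiform bursts and yet
*increase* the frequency of population bursts. The pipeline has four
stages: (1) construction of excitatory/inhibitory conductance templates
from voltage-clamp current recordings ("activity clamp"); (2) playback
of those templates into a refractory exponential integrate-and-fire
(rEIF) point neuron under paired control/CBZ conditions; (3) a
100-neuron all-to-all excitatory network in which presynaptic glutamate
vesicle depletion makes bursts self-limiting; (4) spike- and burst-level
metrics with paired statistics.

## Single-neuron model

The membrane voltage obeys

    C dV/dt = −G_L(T)·(V − V_L(T)) + G_L(T)·Δ_T(T)·exp[(V − V_T(T))/Δ_T(T)]
              + I_in(V, t) + σ dW/dt,

with a spike registered when V reaches the absolute threshold
V_Tabs = −37 mV, followed by reset to V_r = −43 mV. T is the time since
the last spike; the four parenthesised parameters relax exponentially
from post-spike values back to basal ones:

    G_L(T)  = G_L0 + a_GL·e^(−T/τ_GL)                  (6.8 + 9 nS, τ 30 ms)
    V_L(T)  = V_L0 + a_VL·e^(−T/τ_VLa) + b_VL·e^(−T/τ_VLb)
                                                       (−75 + 16 − 10 mV, τ 25/100 ms)
    V_T(T)  = V_T0 + a_VT·e^(−T/τ_VT)                  (−52 + 15 mV, τ 13 ms)
    Δ_T(T)  = Δ_T0 + a_ΔT·e^(−T/τ_ΔT)                  (2 + 0 mV)

Immediately after a spike the soft threshold V_T sits exactly at the
absolute threshold (−52 + 15 = −37 mV) and recovers with τ_VT. CBZ is
modelled by one change only: τ_VT 13 → 15 ms (`apply_condition`),
phenomenologically capturing slower recovery of sodium channels from
inactivation. Both exponential terms of V_L act additively from T = 0.

Units are mV / ms / pA / nS / pF throughout; the vesicle recovery
constant (8 s) and noise intensity (mV/s^1/2) are converted on access.
"Never spiked" is encoded as T = ∞, which yields exactly the basal
parameter values.

### Integration

Euler–Maruyama with a fixed 0.1 ms step: deterministic drift as above,
plus an additive voltage increment σ·√dt·ξ with ξ ~ N(0, 1) per neuron
per step. The exponential argument (V − V_T)/Δ_T is capped at 20 before
exponentiation; since a spike fires anyway once V ≥ V_Tabs, the cap
cannot alter spike times for the default parameters. A non-finite
voltage raises an error naming the offending step inputs. Against an
adaptive RK45 reference with event-based spike handling, the fixed-step
trajectory stays within ~0.01 mV sup-norm over 1 s of subthreshold
drive and matches the spike count of a 500 ms suprathreshold step.

Spike times are the step times at which the reset fired; splitting one
simulation into consecutive calls with carried-over state and a shared
RNG reproduces the unsplit run exactly.

### Noise intensity (calibrated)

With the plain Euler–Maruyama scheme above, a noise intensity of
170 mV/s^1/2 would give a stationary voltage SD near 19 mV and ~30 Hz
spontaneous firing under the network's tonic input — neurons would never
be quiescent between bursts and vesicle pools could never refill. The
package default is σ = 25 mV/s^1/2, set once so that the stationary
voltage SD is ~2.8 mV (the fluctuation scale seen in slice recordings)
and the spontaneous rate under tonic drive stays below ~1 Hz. All
simulations accept an explicit `sigma` override, and σ = 0 gives fully
deterministic runs.

## Activity clamp

A current recorded at holding potential V_hold isolates one synaptic
component; subtracting the liquid junction potential (LJP, 13.6 mV)
gives the true membrane potential V_m = V_hold − LJP, and the
conductance is g = I/(V_rev − V_m). The standard recording conditions
give driving forces of +93.6 mV (excitatory: −80 mV holding, 0 mV
reversal) and −41.4 mV (inhibitory: 0 mV holding, −55 mV reversal, the
GABA_A equilibrium shifted by high extracellular potassium).
Conductance output is |I|/|driving force| — necessarily non-negative —
while the driving force is reported signed. Playback injects
I = g_E·(E_E − V) + g_I·(E_I − V) per step with model reversals 0 /
−56 mV; an optional LJP shift of both reversals (E_eff = E_rev − LJP)
mirrors the correction applied when driving a real cell and is a logged
switch, not a default.

Template amplitude is normalised per neuron: a difference-of-
exponentials unitary AMPA conductance (default 0.3 nS peak, 0.5 ms
rise, 3 ms decay, from miniature-EPSC kinetics) is multiplied by an
integer k until one spike fires (deterministically, σ = 0); the
template is then scaled by a single factor so max(g_E) equals the
threshold conductance k·peak. For the default neuron this yields 78
units ≈ 23.4 nS, the same order as thresholds measured in CA1 pyramidal
cells. Spiking is monotone in k, so linear scan and bisection agree.

## Network model

100 neurons, all-to-all excitatory coupling with weights Γ_E drawn
i.i.d. from U(0, 1) (self-weights zeroed). Each neuron carries a
normalised releasable vesicle pool N ∈ [0, 1] and a normalised efferent
conductance G_E:

    dN/dt   = (1 − N)/τ_N − r·N·δ_s(t)        τ_N = 8 s, r = 0.3
    dG_E/dt = −G_E/τ_GE + r·N·δ_s(t)          τ_GE = 10 ms
    I_in    = γ_eff·(Γ_E·G_E)·(V_E − V) + I_0  I_0 = 128 pA, V_E = 0 mV

Update order per step: pool recovery and conductance decay (forward
Euler), synaptic currents from start-of-step conductances, voltage
update, then release jumps for this step's spikers — so a spike
influences the network from the next step on, identically for every
neuron. The recorded per-spike release r·N makes the bookkeeping
identity (window release = Σ r·N over its spikes) exact by
construction, and the kernel enforces N ∈ [0, 1] every step.

### Coupling normalisation (calibrated)

Read literally, γ_max = 267 nS multiplying the full weight matrix gives
a first spike at full pools a postsynaptic kick of order 2 nA to every
neuron; the network produces one ~kHz synchronized discharge and then
settles into a stable self-sustained tonic state that never bursts
again. The package therefore couples per connection:
γ_eff = coupling_scale·γ_max/n, with coupling_scale = 5 (13.35 nS per
connection) calibrated once, jointly with σ above, so that the control
network shows recurrent self-limiting population bursts — a few spikes
per neuron per burst, ~0.5 s interbursts, near-total vesicle discharge
per burst followed by seconds-scale refilling. The literal
un-normalised coupling remains available (`normalize_by_n=False`) for
robustness experiments. This calibration used only the control
condition's qualitative behaviour; the condition contrast below is an
outcome, not a target, of the calibration.

### Bursting mechanism and the CBZ contrast

Between bursts neurons sit ~4 mV below the soft threshold (rest
≈ −56 mV under I_0) and fire rare noise-driven spikes. Each stray spike
excites the whole population in proportion to the sender's vesicle
content, so as pools refill the network's effective gain rises until a
stray ignites a regenerative burst; the burst exhausts most of the
releasable pool and terminates within ~100 ms. Slowing only the soft-
threshold recovery (τ_VT 13 → 15 ms) removes the marginal late spikes
within each burst; smaller bursts release fewer vesicles; pools refill
to ignition level sooner; bursts recur faster. Across 10 paired
connectivity matrices (identical noise streams per pair), 20 s runs
give fewer spikes/neuron/burst and shorter mean interburst intervals
under CBZ in 10/10 and ≥9/10 pairs respectively (sign test p < 0.05),
with the per-burst release vs next-interval correlation strongly
positive in both conditions.

### Burst detection and summaries

Bursts are detected from the raster: 5 ms bins, Gaussian smoothing
(20 ms), onset/offset at 20 % of the post-settle peak rate, gaps
< 100 ms merged, events with < 10 spikes dropped. The first 3 s of each
run are excluded as settling time: initialising all neurons at rest
with full pools produces one artificially synchronized discharge.
Interburst intervals are measured end-of-burst to start-of-next. All
detection parameters are explicit function arguments recorded in run
configs.

## Spike metrics

An accepted action potential must cross 0 mV and show a maximal rising
slope above 10 mV/ms (first differences over dt); its time is the first
sample of the contiguous dV/dt-suprathreshold run preceding the
crossing. Model traces use the integrator's own reset events instead
(EIF spikes are truncated at V_Tabs and never cross 0 mV). Latency is
first AP minus the window's excitatory-conductance onset; jitter is the
across-repeat CV (sample SD / mean) of that latency; AP reliability is
ordinal — reliability_i is the fraction of repeats containing at least
i APs in the window — which is parameter-free and monotone in i.
Interval CV uses the n−1 sample SD. Paired contrasts offer paired t,
Wilcoxon and sign tests with a recorded normality screen.

## Synthetic data

The generator emulates the recorded protocol: 24 consecutive bursts,
each an alpha-like envelope (15 ms rise, 80 ms decay) multiplying a
shot-noise sum of unitary synaptic events (400 Hz at envelope peak),
with onset-to-onset intervals gamma-distributed (mean 2 s, CV 0.4) and
the per-burst inhibitory/excitatory charge ratio drawn from
N(1.2, 0.4) truncated at 0.1. Excitatory currents are emitted at
−80 mV holding (inward), inhibitory at 0 mV (outward), plus 2 pA
Gaussian noise. Envelope parameters were chosen so that a scaled
template evokes 1–5 APs per burst in the control neuron, the range seen
in slice playback. Every generator is a pure function of
(config, seed). What the generator does **not** emulate: NMDA
components, electrode/access artefacts, within-burst correlation
between excitatory and inhibitory barrages beyond their shared
envelope, or slow drift across the protocol — so passing tests show the
pipeline's operators are correct on data with the assumed structure,
not that the biological templates have exactly this structure.

## Known limitations

- **No deterministic first-AP delay under CBZ.** With σ = 0 the paired
  playback trajectories are identical up to each burst's first spike:
  the τ_VT mechanism acts only within a few time constants (~75 ms) of
  a *preceding* spike, and interburst gaps erase all state differences.
  The model therefore reproduces the loss of late APs and reduced
  second-AP reliability, but cannot delay a burst's first AP without a
  recent-spike history; an observed first-AP delay in real neurons
  presumably reflects tonic sodium-channel modulation outside this
  single-parameter phenomenology. The corresponding acceptance check is
  asserted strictly and fails by design (delay = 0).
- The network is excitatory-only; V_I is used in playback mode only.
- Network burst statistics at the 20 s "quick" duration are noisier
  than at the 200 s protocol length (`duration` is a parameter; the
  defaults keep the full paired experiment near a minute of
  computation). Problem sizes used by the test-suite and the acceptance
  script: 10 paired seeds × 20 s network runs, 24-burst templates,
  30 playback repeats.
- Experimental cohort statistics from slice recordings (absolute burst
  frequencies, t/F statistics) are not reproducible from synthetic
  data and are out of scope; the directional and property-level
  signatures above are the reproduction surface.
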