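# Methods

`flexsim` simulates a spiking-network account of how midbrain dopamine
responses during classical conditioning can arise from *learned* —
rather than pre-wired — temporal representations of each cue. This note
documents the model, its parameters and numerics, what the synthetic
protocols emulate, and the design choices made where the architecture left
room.

## Model overview

The network has two modules. A cortical module holds one feature-specific
column per conditioned stimulus, each containing three populations of 100
conductance-based leaky integrate-and-fire (LIF) neurons: **Timers**
(recurrently connected through slow, NMDA-like synapses), **Inhibitory**
cells (driven by the Timers; they inhibit both the Timers and the
Messengers), and **Messengers** (slow Timer excitation plus fast
feed-forward inhibition, so they fire only while the Timer envelope is
collapsing). A reward module ("VTA") holds 100 dopaminergic (DA) and 100
GABAergic neurons, both kept near a 5 Hz baseline by calibrated white
current noise. Rewards reach DA through a fixed sparse excitatory
projection from the reward input channel; the GABA pool inhibits DA.

Membrane dynamics per neuron:

    C dv/dt = gL (EL − v) + gE (EE − v) + gI (EI − v) + gA (EA − v) + σ ξ(t)

with synaptic activation `ds/dt = −s/τs + ρ(1 − s) Σ δ(t − t_spike)` (one
fast channel, τs = 5 ms, and one slow channel, τs = 100 ms, per neuron;
projections choose which channel they read), conductances `g_i = Σ_j W_ij
s_j`, and an online rate estimate `τr dr/dt = −r + Σ δ(t − t_spike)`
(τr = 50 ms; a unit-area filter, so its mean equals the firing rate).

`gA` is a spike-triggered adaptation conductance (increment `b` per spike,
decay τ_adapt, K-like reversal −90 mV), enabled only in Timer populations —
see "Timer mechanism" below.

Dopamine is summarized by the population-mean DA rate `r_DA(t)` passed
through a piecewise-linear threshold with a neutral band of half-width θ
around the baseline r0:

    D(t) = (r_DA − r0 + θ)·[r_DA ≤ r0−θ]  +  (r_DA − r0 − θ)·[r_DA ≥ r0+θ]

D(t) is broadcast globally to every plastic synapse (dopamine as a volume
transmitter).

## Two-trace learning (dTTL)

Each plastic synapse carries two Hebbian-activated eligibility traces,

    τa dTa/dt = −Ta + ηa H (Tmax_a − Ta),      a ∈ {p, d}

and weights change competitively, `dW/dt = η D(t) (Tp − Td)`, clipped to
[0, W_max]. H is the product of pre- and postsynaptic rate estimates; for
cortical synapses it is divided by (1 + α·max(D, 0)).

The trace constants are chosen so that the **depression trace decays fast**
(τ_d = 200 ms) while the **potentiation trace persists** (τ_p = 2000 ms);
rise speeds are set by η_a·H. Consequences:

* a *delayed* dopamine bump (~1 s after a burst of presynaptic activity)
  sees Tp > Td and potentiates — this is how the cue→DA pathway acquires a
  response from reward delivered a second after the cue;
* a dopamine bump *concurrent* with the activity sees Td > Tp and
  depresses — this is what makes the cue→DA weights self-limiting once the
  cue itself evokes dopamine, and what pulls Timer recurrence back when the
  Timers are still active at reward time.

The convergence condition per synapse is `∫ D(t)(Tp − Td) dt = 0` over a
trial (`fixed_point_residual`), reached either because D has been
suppressed to zero or because the positive and negative dopamine-weighted
contributions cancel.

Cortical (Timer→Timer) synapses differ from VTA synapses in three ways,
each exposed as a trace parameter:

* **Event-boundary gating** (α = 12): trace generation is attenuated by
  1/(1 + αD⁺) during large positive dopamine transients.
* **Event-boundary erasure** (`boundary_erase` = 1e-4 per Hz·ms): positive
  dopamine also actively erodes *existing* traces. Without it, the LTD
  trace formed in the ~50 ms before the rate-filtered dopamine crosses
  threshold systematically depresses the recurrence once a cue response
  exists, and interval learning stalls. Because erasure acts during the
  bump, it preferentially removes bump-formed traces while sparing (most
  of) the standing traces carried into the bump — standing traces are what
  let an ongoing Timer be *depressed* by a misplaced dopamine bump, the
  mechanism that aligns Timer duration with the cue-reward (or cue-cue)
  interval.
* **Hebbian saturation** (`h_sat` = 1200 Hz²): the pre×post product is
  clipped before entering the trace dynamics. H grows as rate², so without
  the clip the LTP trace's rise accelerates with firing rate and overtakes
  the LTD trace within a few hundred ms at high Timer rates, inverting the
  interval brake. With the clip, the LTP/LTD crossing time (~1-2 s of
  sustained activity) depends only on the trace constants: any Timer still
  active when reward arrives has T^d > T^p and is pushed back, while a
  Timer that stopped shortly before reward has T^p > T^d (the LTD trace
  decays faster after offset) and is pulled forward — so each Timer relaxes
  to its own cue-reward interval.

The Messenger→GABA pathway uses the simpler dopamine-modulated Hebbian rule
`dW/dt = η D r_pre r_post`; because this pathway's function is to suppress
reward-evoked dopamine, it imposes its own fixed point at D = 0.

## Timer mechanism

The recurrent weight must map *smoothly* onto a persistence duration for the
trace-crossing fixed point to express an interval. Recurrent excitation with
saturating synapses alone is a bistable switch (activity either dies with
the cue or persists indefinitely), so Timers combine three ingredients:

1. slow recurrent excitation (learned weight, the interval variable;
   initialized at ~1/3 of its ceiling so that the naive transient
   (~300 ms) outlasts the cue — the post-cue tail is where eligibility
   traces form unimpeded by the boundary gate, which is what lets a naive
   Timer start learning at all),
2. strong fast feedback inhibition from the column's Inhibitory pool,
   which clamps the plateau rate to roughly 40–100 Hz regardless of the
   recurrent weight,
3. a slow adaptation conductance (b = 0.06, τ_adapt = 1.4 s) that
   accumulates during the plateau and eventually collapses it.

With the rate clamped, the time for adaptation to reach the collapse
threshold grows monotonically with the recurrent weight: durations range
from ~300 ms (naive) to ~1.15 s at the weight ceiling — the ceiling also
bounds the longest learnable cue-reward interval. The Messengers, released
from fast inhibition as the plateau collapses, fire in a burst of
~50–80 Hz confined to the collapse window — the model's prediction signal
for "expected reward now".

## Learning timeline (single-cue protocol)

With the default rates (η_cue→DA = 1.2e-4, η_recurrent = 1.2e-3,
η_M→GABA = 8e-8, all in total-conductance units) the 40-trial session
unfolds as: reward responses (~20 Hz over baseline) from trial 1; Timer
recurrence grows to its fixed point within trials 2–7 (duration ≈ 1 s);
the cue-evoked dopamine response crosses half of its final ~16 Hz size
around trial 7; the Messenger burst then overlaps the reward window and
the Messenger→GABA pathway suppresses the reward response below half of
its initial size around trial 17 and to ~1–2 Hz by trial 30, while the cue
response persists. The cue response therefore potentiates *before* the
reward response depresses — the model's characteristic learning order —
and the per-trial integral of D(t) transiently exceeds the unexpected-
reward integral by ~50–90%, which no temporal-difference learner can do.
The cue response's stability rests on the VTA trace rise speeds: the LTP
trace overtakes the LTD trace midway through the cue's own dopamine bump,
so the bump is roughly weight-neutral and the cue pathway neither runs
away nor self-extinguishes once the reward response is gone.

## Reference models

* **TD(λ)** over a complete serial compound (one microstate per 50 ms bin
  after cue onset) or a two-Gaussian cue/reward basis. Updates are
  trial-synchronous by default (deltas computed against weights frozen at
  trial start), which makes the γ = 1 conservation of integrated RPE exact;
  a step-online mode is provided. TD(0) shows the backward-moving RPE bump;
  λ = 0.9 does not.
* **Fixed random RNN** (τ = 50 ms, gain 1.5, tanh, N(0, g²/K) weights):
  driven with three-stimulus sequences it demonstrates that a frozen
  network's post-cue trajectory depends on stimulus history, so it cannot
  serve as a reusable cue-relative clock.

## Numerics

Forward Euler throughout; network default dt = 0.5 ms (the LIF core is
first-order convergent, verified against closed-form subthreshold
solutions; the fastest time constant under load is the 5 ms synapse).
Noise is Euler–Maruyama. Baseline σ values were calibrated by bisection to
give 5 Hz at dt = 0.5 ms including the tonic GABA→DA inhibition. Euler
trace updates match an adaptive-step ODE oracle within 1% at dt = 0.05 ms.
Eligibility traces and neuronal state reset between trials (the inter-trial
interval is treated as long relative to every trace constant); synaptic
weights persist.

Timer duration is read out as the time from cue onset until the smoothed
population rate last exceeds half its plateau, with the plateau estimated
as the median rate over the active period (robust to the onset transient
and the adaptation sag; for a rectangular rate of width w the readout is
exactly w). Response *peak times* are measured on trial-averaged spike-count
PSTHs (50 ms bins) rather than on the exponentially filtered online rate,
which lags by ~τr.

## Problem sizes

Default sessions follow the protocol definitions: 40 trials for single-cue
conditioning (cue at 100 ms, reward at 1100 ms, 1.6 s trials), 50–60 trials
for sequential conditioning (cues at 100 and 800 ms, reward at 1500 ms, 2 s
trials), 40-trial extinction blocks, and 40 + 25 trials for
blocking/unblocking, the latter run at half-size populations (50 per pool)
in the test suite; the mechanisms under test are population-level and
survive the reduction. The integrated-signal comparison driver prepends 20
reward-only trials as its pre-learning reference block.

## What the synthetic protocols do and do not capture

The event schedules reproduce the *timing structure* of head-fixed trace
conditioning: discrete cues, fixed cue–reward delays, trial independence.
They do not model licking or other behavior, probabilistic reward
schedules, inter-trial dynamics, context, or satiety; stimulus intensity
maps linearly onto input-channel Poisson rates. Passing tests show the
circuit-level learning dynamics are as described above under these
idealized conditions — not that the parameter values are those of any
biological circuit.

## Known limitations

* Timer plateau rates (up to ~100 Hz) are stylized; the model's claims
  concern population timing, not single-neuron firing statistics.
* The reward response is suppressed toward, but not exactly to, baseline:
  the onset transient before the GABAergic burst catches up survives, and
  the Messenger→GABA weight oscillates mildly around the D = 0 fixed point.
* Near its duration ceiling the Timer collapse time is noise-sensitive, so
  converged durations scatter by roughly ±10%.
* In sequential conditioning the model reproduces initialization,
  acquisition and the serial-transfer end state (only the first cue drives
  dopamine; both the inserted cue's response and the reward response are
  suppressed, the former via the cue-cue Timer's Messengers), but the pure
  reward-depression stage — reward suppressed while the second cue still
  responds — does not appear as a distinct stage: suppression of the
  inserted cue consistently leads suppression of the reward, because the
  first column's Messengers sit directly on the second cue's window while
  the second column's Messengers must first grow out to the reward time.
  The stage classifier reports 'transitional' during that phase rather
  than guessing.
* Blocking/unblocking uses a compressed timing (inserted cue at 600 ms,
  reward at 1100 ms) so that phase-1 training converges within the
  learnable-interval range.
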