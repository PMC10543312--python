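# flexsim

A spiking-network simulator for studying how dopamine neurons can come to
signal reward predictions **without a pre-wired representation of time**.
Classical temporal-difference (TD) accounts of conditioning assume that
every cue triggers a fixed chain of "microstates" tiling the cue–reward
delay. `flexsim` implements the alternative: feature-specific temporal
basis functions (persistently active **Timer** neurons and decay-triggered
**Messenger** neurons) are *learned* during conditioning, under a
dopamine-gated two-trace plasticity rule, alongside the dopamine responses
themselves. The package also includes the two reference models the
framework is contrasted against — TD(λ) on a complete-serial-compound
basis, and a fixed random RNN as a would-be universal clock — plus the
analysis toolkit (auROC response maps, per-trial integrated reinforcement,
learning-stage classification) used to compare them.

Intended users: computational neuroscientists studying reinforcement
learning, midbrain dopamine, or interval timing.

## The model in brief

All neurons are conductance-based LIF units,

    C dv/dt = gL(EL − v) + gE(EE − v) + gI(EI − v) + σξ(t),

with synaptic activations `ds/dt = −s/τs + ρ(1−s)Σδ(t−t_k)` and
conductances `g_i = Σ_j W_ij s_j`. Dopamine reinforcement is a thresholded
version of the DA population rate, zero inside a neutral band of width
2θ around the 5 Hz baseline:

    D(t) = (r_DA − r0 ∓ θ)  outside the band,  0 inside.

Plastic synapses carry two competing eligibility traces
(`τ_a dT_a/dt = −T_a + η_a H (Tmax_a − T_a)`, a ∈ {LTP, LTD}, H the
pre×post rate product) and update as `dW/dt = η D(t)(T^p − T^d)`. Three
pathways learn: Timer→Timer recurrence (the interval), cue→DA (the
cue-evoked dopamine response), and Messenger→GABA (suppression of the
reward-evoked response). Convergence is the trial fixed point
`∫ D(t)(T^p − T^d) dt = 0`.

See `docs/methods.md` for assumptions, parameter tables and numerics.

## Worked example

Forty trials of single-cue trace conditioning (cue at 100 ms, reward at
1100 ms) and a post-training probe:

```python
import copy
from flexsim import (NetworkSpec, build_network, trace_conditioning,
                     run_session, probe_trial, Session, timer_duration,
                     peak_response_time, response_magnitudes)

net = build_network(NetworkSpec(), 1)
recs = run_session(net, trace_conditioning(40))

first = response_magnitudes(recs[0],  {"cs": (100, 350), "us": (1100, 1350)})
last  = response_magnitudes(recs[-1], {"cs": (100, 350), "us": (1100, 1350)})
print(f"trial  1: cue {first['cs']:+5.1f} Hz   reward {first['us']:+5.1f} Hz")
print(f"trial 40: cue {last['cs']:+5.1f} Hz   reward {last['us']:+5.1f} Hz")

probe_net = copy.deepcopy(net)
probes = Session([probe_trial(trace_conditioning(1).trials[0])] * 3, "probe")
precs = run_session(probe_net, probes, record_counts=("da", "msg_cs1"))
print(f"timer duration : {timer_duration(precs[0].times, precs[0].rates['timer_cs1'], 100):.0f} ms")
print(f"messenger peak : {peak_response_time(precs, 'msg_cs1'):.0f} ms")
```

Typical output (seed 1):

```
trial  1: cue  +0.4 Hz   reward +19.5 Hz
trial 40: cue +13.7 Hz   reward  +0.9 Hz
timer duration : 998 ms
messenger peak : 1125 ms
```

The dopamine response has migrated from the reward to the cue; the learned
Timer envelope spans the 1000 ms delay and the Messenger burst marks the
expected reward time. The same run shows the framework's signature
departures from TD: the cue response potentiates *before* the reward
response depresses, and the per-trial integral of D(t) transiently exceeds
the integral evoked by the very first unexpected reward.

From the shell, each of the package's standard simulation experiments
can be regenerated end to end:

```
flex reproduce fig6 --seed 1 --out out/fig6     # single-cue conditioning + auROC maps
flex reproduce fig7 --seed 1 --out out/fig7     # integrated D(t) vs TD(λ) integrated RPE
flex reproduce fig8 --seed 1 --out out/fig8     # sequential conditioning stages
flex rnn-demo --seed 0 --out out/rnn            # fixed-RNN history dependence
```

Each output directory contains plotting-ready CSVs plus a manifest with
the resolved configuration and seed for bit-identical re-runs.

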