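# Methods

`cereblearn` simulates a reduced cerebellar circuit — mossy fibres (MF),
granule cells (GC), Purkinje cells (PC), climbing fibres (CF) and deep
cerebellar nuclei (DCN) — with spike-timing-dependent plasticity at three
sites (PF–PC, MF–DCN, PC–DCN), closed through two motor-learning
benchmarks. This note records the model, the numerical choices, and the
places where the design was genuinely open.

## Circuit and coding model

The granular layer is not simulated as a recurrent network; it is replaced
by a deterministic *state generator*: the 2000 GCs are partitioned into
500 disjoint quadruples, one quadruple emitting a single spike per cell in
each 2 ms step of the 1 s trial, so a state uniquely labels a trial time.
The 100 MFs form the same construction at coarser resolution (25 states of
40 ms); inside its window the active MF quadruple fires a deterministic
100 Hz comb, and all MFs are silent between trials. This is the
liquid-state-machine "passage of time" reading of the granular layer; it
deliberately discards any dependence of GC activity on input content.

PCs and DCN cells are leaky integrate-and-fire neurons with conductance
synapses (single-exponential decay, τ_exc = 0.5 ms, τ_inh = 10 ms). Each of
the two (Case A) or six (Case B) *microcomplexes* is one CF driving a group
of 10 PCs that inhibit one DCN cell; microcomplexes come in
agonist/antagonist pairs, one pair per controlled degree of freedom. Each
DCN cell is excited by every MF; each GC contacts every PC.

Climbing fibres encode the error probabilistically: with the normalized
error ε∈[0,1] of their sign channel, they fire in a step with probability
ε·r_max·dt, i.e. the "fire if ε exceeds a uniform draw" rule with the rate
cap r_max = 10 spikes/s per fibre. The error reaches the olive through a
100 ms delay line (the sensorimotor pathway). DCN spike trains are decoded
into analog output by a recursive exponential filter
y[n] = e^(−1/τ)·y[n−1] + g·count[n] (τ = 16 taps = 32 ms by default); the
per-spike gain g is calibrated so that a channel firing steadily at
250 Hz decodes to the configured full-scale output. The loop output is
always the agonist channel minus the antagonist channel.

## Membrane parameters

The model itself does not pin neuron constants, so they are config-first
with per-population defaults:

| population | C (pF) | g_leak (nS) | E_rest (mV) | other |
|---|---|---|---|---|
| PC | 100 | 12 | −70 | threshold −50, reset −70, refractory 1 ms |
| DCN | 30 | 3 | **−60** | same threshold/reset |
| MF/GC/CF (pass-through) | 2 | 0.2 | −70 | |

Two properties of these values are load-bearing. First, the PC parameters
put the simple-spike rate near ~100 Hz at the 5 nS initial PF
weight, i.e. on the same scale as the DCN operating range — the inhibitory
pair rule balances potentiation (per DCN spike) against depression (per PC
spike), which is only possible when the two rates are commensurate.
Second, DCN cells rest 10 mV below threshold: a small MF drive is enough
to start them (MF drive is what brings the nuclei into operation) and PC
inhibition gates them effectively, so postsynaptic spikes remain available
to the nuclear plasticity rules instead of vanishing for thousands of
trials whenever inhibition transiently dominates.

Membrane integration uses the exponential-Euler update on 10 substeps per
2 ms clock step: exact for conductances held constant within a substep and
unconditionally stable. Explicit Euler is not an option here — plastic
conductances transiently exceed its stability bound (g > 2C/h), and the
threshold/reset mechanism then masks the numerical instability as
ceiling-rate firing, which the inhibitory learning rule happily consumes.
Synaptic delays are one clock step everywhere; the 100 ms sensorimotor
delay lives only on the error pathway.

## Plasticity rules

* **PF–PC.** LTD on each CF spike: every PF spike in the past 300 ms
  contributes −ltd_scale·k(Δt/τ_LTD) with k(x) = e^(−x)·sin(x)^20. The
  kernel peaks at x* = arctan 20 ≈ 1.5208 with a secondary lobe < 5 % of
  the peak. τ_LTD is set by `calibrate_tau_ltd` so the peak eligibility
  sits at the *total* teaching latency — 100 ms sensorimotor delay plus
  ~25 ms decoder lag, 125 ms by default. LTP is +α per PF spike
  (α = 0.004 nS), clipped at w_max = 10 nS.
* **MF–DCN.** LTD on each PC spike over the two-sided window kernel
  e^(−|xβ|)cos²x (σ = 10 ms, β = 2, truncation 30 ms); LTP +α per MF spike
  (α = 0.008 nS, ltd_scale = 0.003 nS), clipped at w_max = 110 nS.
* **PC–DCN**, two alternatives: a Hebbian exponential pair rule
  (nearest-neighbour pairing; post-after-pre potentiates the inhibitory
  weight with τ1 = 20 ms, pre-after-post depresses with τ2 = 15 ms, scale
  0.01 nS, coincidence counts as potentiation), and a symmetric
  coincidence rule (every presynaptic spike depresses by LTD_max = 0.005;
  pre/post pairs within the ±60 ms window potentiate by
  LTP_max·e^(−|u|)cos²u, LTP_max = 0.025, u = Δt/σ, σ = 20 ms).

All weights are non-negative conductances clipped at zero; inhibition is a
projection property. The two saturation bounds are additions relative to
the bare rule equations: constant LTP has no equilibrium at states that
never receive teaching spikes (PF–PC) and leaves the absolute
excitation/inhibition level of the nuclei unconstrained (MF–DCN, where
excitatory and inhibitory gains otherwise co-escalate indefinitely while
the *difference* tracks the task). Conductance ceilings are the standard
resolution in clock/event-driven simulators, and they restore the
two-timescale weight convergence the model is meant to exhibit.

The closed-loop engine evaluates these rules from precomputed kernel
tables over the deterministic schedules inside a compiled (numba) trial
kernel; the per-event implementations in `cereblearn.plasticity` define
the semantics and the engine is tested for spike-exact / 1e-8-weight
agreement against a transparent step-by-step reference loop, as well as
against brute-force double-loop summation on random spike sets.

## Case A: set-point tracking

The cerebellar output itself is the controlled variable; the reference is
e^(−(t−T/4)²/σ²) − e^(−(t−3T/4)²/σ²) with T = 1 s, σ_ref = T/10. Error
normalization 1.0 (the curve's amplitude), output full scale 1.3.

Learning unfolds exactly as the distributed-plasticity hypothesis
predicts: CF-driven LTD carves the reference shape into the PF–PC weights
(the fast memory); the resulting PC pauses disinhibit the nuclei while
PC-spike-driven LTD stops braking MF–DCN growth precisely at those states,
so the MF–DCN profile becomes a 25-state discretized *counter-phase* copy
of the 500-state PF–PC profile (the slow, consolidated memory); PC–DCN
plasticity balances the nuclear input gains.

## Case B: feed-forward torque control

Rather than a full light-weight-robot dynamic model, the plant
is a documented substitute: a planar 3-link arm (distal point masses
2.0/1.5/1.0 kg, lengths 0.4/0.4/0.3 m, viscous friction 0.1 N·m·s,
gravity), payload a 6 kg point mass at the end effector. Inverse dynamics
is exact Newton–Euler for point-mass chains; forward dynamics solves
M(q)q̈ = τ − h(q, q̇) with M assembled by unit-acceleration inverse-dynamics
calls, integrated by semi-implicit Euler (10 substeps per 2 ms by
default; the passive frictionless arm conserves energy to < 0.1 % over
1 s at a 10 µs substep). The trajectory is the eight-shaped curve
Q_n = A_n sin(−4πs³ + 6πs² + nπ/4), s = t/1 s, with A = (0.3, 0.2,
0.15) rad — amplitudes chosen so the payload's corrective torque stays in
a plausible actuator range (≲ 320 N·m at the shoulder).

The arm always runs under a low-level joint servo
(K_p = 400/250/80 N·m/rad, K_d = 120/64/13 N·m·s/rad, near-critically
damped for the loaded arm), present identically in baseline and learned
runs — as on any physical light-weight robot, whose joint controller runs
at kHz rates. The servo is evaluated at the plant substep rate: holding
it at the 2 ms network clock produces an artificial zero-order-hold limit
cycle that corrupts the teaching signal, and without any servo the purely
feed-forward arm is open-loop unstable within a trial, so across-trial
learning has no stable plant to learn against.

The crude controller computes feed-forward torques for the *unloaded* arm
along the desired trajectory; the cerebellum adds corrective torque per
joint (agonist − antagonist channel, full scale 330/220/100 N·m). The
taught error is the joint-angle error plus 0.1 s times the joint-velocity
error (a configurable phase-lead term). The PF–PC eligibility peak for
this case is calibrated to 260 ms: the 100 ms sensorimotor delay plus the
~160 ms torque-to-position-error response of the servo-held arm, measured
by lagged correlation of the baseline error against the needed corrective
torque. Error normalization is 0.3 rad per joint.

## Analysis definitions

* **Counter-phase score**: Pearson correlation between the PF–PC per-state
  weight profile (block-averaged 500→25) and the MF–DCN 25-state profile
  of the same microcomplex; consolidation success is a strongly negative
  score.
* **Reverse cross-correlation**: both spike trains binned at 10 ms; the
  summary is max over lags in ±100 ms of *minus* the Pearson correlation
  (PC inhibits DCN, so coupling appears as anti-correlation). There is no
  canonical estimator for this quantity; the operational definition above
  is this package's.
* **Convergence trial**: first trial after which the 50-trial moving mean
  stays within ±5 % of its final value; a series that never does is
  reported as not converged.
* **Error-reduction percentage**: 100·(baseline-window mean MAE − final-
  window mean MAE)/baseline.

## Reconstruction choices on the comparison experiments

Because the learning-rate constants are free parameters of the model, two
of the comparison claims required explicit operational choices:

* The *gain-control convergence* experiment (identical final PC–DCN gains
  from zero/random/high initial weights) is run with the **symmetric**
  kernel. In this reconstruction the nearest-neighbour Hebbian pair rule
  has no initialization-independent attractor at any (τ1, τ2, scale) we
  explored — it either collapses to zero coupling or co-grows with the
  MF–DCN gain along a path-dependent trajectory — whereas the symmetric
  rule's unconditional per-pre-spike depression pins the nuclear firing
  point and erases the initial condition within tens of trials.
* *Kernel convergence speed* is measured as the early-phase gain advance
  (the averaged PC–DCN gain attained inside the first 1000 trials). The
  Hebbian rule is structurally faster from zero initial weights: every
  postsynaptic spike potentiates immediately, while the symmetric rule
  must first overcome its own depression term. No canonical speed
  estimator exists; only the ordering is treated as meaningful.

## What the synthetic benchmarks do and do not show

All inputs are generated internally: the deterministic state schedules,
the analytic reference curve and trajectory, and the seeded CF draws are
the *only* stochastic element. Passing tests therefore demonstrate the
internal consistency of the distributed-plasticity mechanism — carving,
counter-phase consolidation, gain balancing, and error reduction under
model mismatch — under idealized timing signals. They say nothing about
recurrent granular-layer dynamics, about robustness to noisy or
content-dependent MF input, about plasticity at the granular sites the
model omits, or about a physical 7-DoF arm; the substitute plant preserves
the *logic* of the manipulation experiment (crude unloaded model vs.
loaded plant), not its dynamics. Error-reduction percentages on the
robot task therefore depend on the substitute arm's parameters and are
meaningful only relative to its own frozen-controller baseline.

## Problem sizes used by the test-suite and acceptance script

Case A experiments run 2500 trials (consolidation) and 5000 trials
(gain-control, two-timescale, kernel comparison); Case B runs 4000
learning trials against a 20-trial frozen baseline (the frozen loop is
deterministic up to CF draws that never fire, so a short baseline
suffices). These match or approach the model's reference horizons
(2500 / 5000 / 10,000 trials) and complete in a few minutes on one CPU because
the trial kernel is compiled and the schedules are precomputed.
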