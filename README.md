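# cereblearn

A spiking cerebellar model with **distributed plasticity** — learning at
three synaptic sites instead of the classical one — embedded in closed-loop
motor-learning benchmarks.

## The scientific problem

The cerebellum learns fast in its cortex and remembers slowly in its
nuclei. Parallel-fibre → Purkinje-cell (PF–PC) synapses acquire corrective
motor programs within tens of trials under climbing-fibre (CF) teaching
signals, yet motor memories survive in deep cerebellar nuclei (DCN) long
after cortical traces fade. This package implements a mechanistic account:
spike-timing-dependent plasticity (STDP) at the two DCN afferent systems —
excitatory mossy-fibre (MF–DCN) and inhibitory Purkinje (PC–DCN) synapses —
acting together as a *gain controller* and as the vessel of *learning
consolidation*, with the cortical pattern transferred in counter phase to
the nuclear synapses.

The model is built for computational neuroscientists who want to probe
these learning rules in closed loop, at desk scale, with every spike and
weight observable.

## The model in brief

* Leaky integrate-and-fire neurons with conductance synapses, advanced
  clock-driven at Δt = 2 ms (exponential-Euler substeps).
* Granular layer as a deterministic **state generator**: 2000 granule
  cells in 500 disjoint quadruples tick off the 1 s trial; 100 mossy
  fibres form 25 coarser states.
* Probabilistic CF error coding: a fibre fires when the normalised error
  ε exceeds a uniform draw, rate-capped below 10 spikes/s; positive and
  negative error go to the agonist/antagonist microcomplex of each joint.
* Plasticity (weight change per event):
  - PF–PC LTD under the eligibility kernel `k(x) = e^(−x)·sin(x)^20`,
    whose peak at `x* = arctan 20` is calibrated to the sensorimotor
    delay; constant LTP per PF spike.
  - MF–DCN LTD under the symmetric window kernel `e^(−|xβ|)·cos²x`,
    driven by PC spikes; constant LTP per MF spike.
  - PC–DCN inhibitory STDP, either a Hebbian exponential pair rule or a
    symmetric coincidence rule (`LTP_max·e^(−|u|)·cos²u − LTD_max`).
* Case A closes the loop on a two-lobed Gaussian set-point; Case B adds a
  planar 3-link arm with a 6 kg payload whose crude (unloaded)
  inverse-dynamics controller the cerebellum must correct.

See `docs/methods.md` for assumptions, parameter tables and numerical
choices.

## Worked example

```python
import cereblearn as cb

topo = cb.build_network(cb.CaseConfig(case="A", pcdcn_init_mode="fixed"), seed=1)
cfg = cb.RunConfig(output_full_scale=(1.3,), error_norm=(1.0,),
                   enable_pcdcn=False)          # the consolidation setup
sim = cb.Simulation(topo, cfg, seed=1)
log = sim.run(2500)

first, last = log.table.mae.iloc[0], log.table.mae.iloc[-100:].mean()
print(f"trial-1 MAE {first:.3f} -> final MAE {last:.3f}")

pf = cb.weight_profile(sim.w_pfpc, sim.gc_schedule, columns=range(10))
mf = cb.weight_profile(sim.w_mfdcn, sim.mf_schedule, columns=[0])
print(f"counter-phase score {cb.counter_phase_score(pf, mf):+.2f}")
```

prints

```
trial-1 MAE 0.354 -> final MAE 0.077
counter-phase score -0.84
```

The trial-1 error is the open-loop mean |reference| (the untrained
cerebellum outputs nothing); 2500 trials later the tracking error has
dropped by ~78 %. The strongly negative counter-phase score is the
consolidation signature: the Gaussian-shaped depression carved into the
500-state PF–PC weight profile has been copied, inverted and discretized,
into the 25-state MF–DCN profile.

The same experiments are available from the shell:

```bash
cereblearn run --case A --trials 2500 --seed 1 --freeze pcdcn --out runs/a1
cereblearn analyze runs/a1
```

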