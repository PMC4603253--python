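# cpgnet

Simulation and analysis of the bilateral mammalian locomotor central
pattern generator (CPG): conductance-based spiking populations with
persistent-sodium-current (I_NaP) bursting, the commissural interneuron
pathways (V0_D, V0_V via V2a, V3) that coordinate the left and right
hindlimb rhythm generators, and the ipsilateral V1/V2b circuits that secure
flexor–extensor alternation and gate locomotor frequency.

The package is for computational neuroscientists who want to run and probe
the classic in-silico experiments on this circuit family: excitability
ramps of an isolated rhythm-generating population (silence → bursting →
tonic), drive ramps of the intact bilateral cord, genetic-style ablations
of commissural populations, axon-guidance knockouts (Netrin-1, DCC, EphA4)
modeled as partial midline rerouting, hemisections, and burst-deletion
probes — all from declarative, seeded, fully reproducible experiment
configurations.

## The model in brief

Each neuron is a Hodgkin–Huxley-style point cell

    C dV/dt = −I_Na − I_K − I_NaP − I_L − I_synE − I_synI

with `I_NaP = g_NaP · mp∞(V) · hp · (V − E_Na)` whose slow inactivation
`hp` (τ up to 3 s) terminates bursts; recovery of `hp` times the interburst
interval.  Excitability is set by a drive α ∈ [0,1) mapped onto the leak
reversal per neuron, `E_L = E_L0(1 − gain·α)`, emulating neuroactive-drug
concentration.  A population of such cells with sparse recurrent
excitation is silent, bursts, or fires tonically depending on α — the
conditional rhythmogenic unit from which the flexor/extensor half-centers
and the bilateral architectures (Model 1, Model 2, and the unified V1/V2b
extension) are assembled.  See `docs/methods.md` for the full model
description, frozen parameter choices, and known limitations.

## Worked example

```python
from cpgnet import run_experiment

# intact bilateral Model 1 under a slow drive ramp (population scale 0.25)
result = run_experiment("model1_ramp", seed=1)
print(result.summary["left_right_labels"])
print(round(result.summary["mean_frequency_hz"], 2))
```

prints

```
['alternation', 'alternation', 'alternation', 'alternation', 'alternation', 'alternation']
1.06
```

— left–right alternation holds in every analysis window of the ramp, with
the locomotor-like rhythm near 1 Hz.  Removing both V0 commissural classes
flips the cord to synchrony (the hopping phenotype):

```python
r = run_experiment("ablate_v0_both", seed=1)
print(r.summary["left_right_labels"][:3])
# ['synchrony', 'synchrony', 'synchrony']
```

The same machinery is exposed on the command line:

```
cpgnet report --list                 # preset catalog
cpgnet run --preset isolated_rg_ramp --seed 1 --out out/
cpgnet build --architecture unified  # edge-list TSV of the circuit
cpgnet sweep --architecture model1 --alphas 0.06,0.08,0.10
```

Each run writes spikes (TSV), per-population rate traces (TSV), analysis
reports (JSON) and a manifest carrying the config digest, so results are
self-describing and byte-reproducible for a fixed seed.

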