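# Methods

## The model

`cpgnet` simulates the mammalian hindlimb locomotor central pattern
generator as a bilateral network of conductance-based spiking populations.
Rhythm generation rests on the persistent (slowly inactivating) sodium
current: each rhythm-generating (RG) neuron carries

* fast sodium `I_Na = g_Na m_inf(V)^3 h (V − E_Na)` (instantaneous
  activation, first-order inactivation),
* delayed-rectifier potassium `I_K = g_K n^4 (V − E_K)`,
* persistent sodium `I_NaP = g_NaP mp_inf(V) hp (V − E_Na)` whose slow
  inactivation gate `hp` (τ up to 3 s) terminates bursts and whose recovery
  times the interburst interval,
* ohmic leak `I_L = g_L (V − E_L)` and conductance-based synapses with
  instantaneous rise and single-exponential decay (τ_E = 5 ms,
  τ_I = 15 ms).

Gate steady states are sigmoids `1/(1+exp((V−V½)/k))`; gate time constants
are bell-shaped `τ_max/cosh((V−V½)/2k)`.  All parameter values are a
calibrated, frozen default set (`MembraneParameters`), chosen so that a
single RG neuron is silent below ≈ −67 mV leak reversal, bursts
intrinsically in ≈ [−67, −64.5] mV with monotonically increasing burst
frequency, and fires tonically above — the conditional-bursting structure
the architecture requires.  They are model choices, not measured constants.

Excitability is driven by a dimensionless drive α ∈ [0, 1) standing in for
neuroactive-drug concentration, mapped per neuron onto the leak reversal as
`E_L = E_L0 (1 − gain·α)`.  Population-specific gains implement the
drive-sensitivity asymmetries that make the commissural pathway balance
frequency-dependent: the flexor centers follow the drive fully (gain 1),
the extensor centers and the inhibitory V0_D commissural population barely
(gain 0.1–0.3 with depolarized baselines), the V2a relay strongly
(hyperpolarized baseline, gain 2), so that the V2a → V0_V pathway is
recruited only at high drive.

## Architectures

Three builders express the circuit diagrams as declarative specs
(populations + Bernoulli projections):

* **Model 1** — per side, flexor (RG-F) and extensor (RG-E) centers with
  sparse recurrent excitation, coupled by inhibitory Inrg populations
  (strong flexor→extensor, deliberately weak extensor→flexor: the rhythm is
  flexor-dominated and extensor activity is carved out of tonic firing by
  flexor-phase inhibition).  Left and right interact through three
  commissural pathways: V0_D (flexor-driven inhibition of the contralateral
  flexor, dominant alternation pathway), V3 (flexor-driven crossed
  excitation, the synchronizing pathway), and V2a → V0_V → contralateral
  inhibitory relay (InV0V), the drive-recruited alternation pathway.
* **Model 2** — identical except V2a is driven by the ipsilateral extensor
  center and V0_V excites the contralateral flexor center directly.
* **Unified** — either core extended with: V2b populations carrying the
  bulk of flexor→extensor inhibition (the core Inrg weights are scaled to
  0.10 in this build); V1 populations held tonically active by a constant
  excitatory conductance of contralateral origin (removed by hemisection),
  phasically inhibited by the contralateral V0_D, inhibiting the
  ipsilateral extensor center and an interposed, intrinsically tonic
  inhibitory population (InV1) whose disinhibition brakes the flexor
  center.  V1 thereby gates locomotor frequency: silencing it (or
  hemisection) releases InV1 and slows the rhythm severalfold.  A weak
  direct mutual excitation between the flexor and extensor centers is
  included; it is functionally silent under normal inhibition and becomes
  the carrier of flexor–extensor synchrony when the V1/V2b inhibition is
  removed.

Lesions (role removal, hemisection) and axon-guidance knockouts are pure
spec→spec transforms.  Knockouts act through `crossing_fraction`: the
fraction of a projection's axons that reach the named target; the
remainder synapse on the homologous population across the midline
(Netrin-1: V0_D/V0_V axons fail to cross; DCC: V0_D/V0_V/V3; EphA4: V2a
axons aberrantly cross to the contralateral V0_V).

## Simulation

Fixed-step exponential-Euler integration (default dt = 0.1 ms) of all
neurons, synaptic events delivered with a one-step delay, spikes detected
as upward crossings of −10 mV with a 1.5 ms refractory gate.  Initial
voltages are drawn uniformly within ±5 mV of the initial `E_L`, gates at
their steady states; everything (connectome, initial state, optional
Ornstein–Uhlenbeck conductance noise, off by default) derives from explicit
seeds, making runs bit-reproducible.  A high-accuracy adaptive integration
of the single-neuron equations (scipy LSODA at rtol 1e-8) serves as the
independent oracle for the fixed-step scheme; fixed-step trajectories
converge to it as dt → 0, and the intrinsic burst period matches it to
within 2% at dt = 0.01 ms.  Near regime boundaries burst periods are
dt-sensitive (at dt = 0.1 the boundary positions shift by a fraction of a
mV); all frozen defaults were calibrated at dt = 0.1.

### Scaling

`scale_network(spec, s)` multiplies population sizes by `s` and connection
probabilities by `1/s` (folding any excess above 1 into the weight), which
preserves the expected in-degree and summed synaptic conductance per
neuron.  All presets run at scale 0.25 (RG centers 50 neurons, others 12);
this keeps every preset in the seconds-to-a-minute range on one CPU.  The
cost of scaling is coherence: the 50-neuron rhythm generators have visibly
noisier cycles than 200-neuron ones, which sets the lower usable drive
bound discussed under Limitations.

## Measurements

Spike records are reduced to population rate histograms
(spikes/(neuron·s), 100 ms bins; the histogram exactly conserves spike
counts).  Bursts are detected by hysteresis thresholding against a running
reference (90th percentile over a sliding 20 s window; onset at 30%,
offset at 15% of the reference; bursts < 200 ms discarded).  Regime labels:
*silence* below 1 spike/(neuron·s) mean rate, *bursting* with ≥ 3 detected
bursts, *tonic* otherwise, over windows ≥ 10 s.  Left–right and
flexor–extensor relations are labelled from the circular statistics of
burst-onset phases within the reference (left flexor) cycle: *synchrony*
with mean phase within ±0.2 of 0 and concentration R ≥ 0.7, *alternation*
within ±0.2 of 0.5 at the same concentration, *uncoordinated* otherwise
(including concentrated but intermediate phases).  Deletions are classified
against an expected-cycle grid fitted on ≥ 5 pre-probe cycles (refused if
period CV > 20%): a deletion is an expected onset with no burst within
±0.25 cycle; the ipsilateral antagonist is *sustained* if its rate stays
above its own burst-on threshold throughout the expected burst window
(clipped to the probe); post-probe onsets deviating > 0.25 cycle from the
extrapolated grid flag the deletion as resetting.  Phase-duration
asymmetry is the pair of least-squares slopes of flexor-burst duration and
inter-burst gap against cycle period.

Deletions are elicited with controlled conductance pulses rather than
spontaneous variability: the flexor probe inhibits one flexor center for
~1.5 cycles (placed on the rhythm's own expected-onset grid fitted from an
initial unperturbed run with the same seed); the extensor probe excites the
ipsilateral Inrg-F population, which suppresses the extensor center without
directly touching the flexor.

## What the presets emulate, and what they do not

The preset catalog maps one-to-one onto the study's in-silico experiments:
the isolated-RG excitability ramp; intact ramps of both bilateral models;
the four commissural ablations; the three axon-guidance knockouts; the
V1/V2b lesion and hemicord experiments; and the two deletion probes.  The
drive protocols (ramp spans, constant-drive levels, durations) are frozen
preset properties — the study conditions — chosen once inside the
coherently locked regime of the scaled network.  The synthetic inputs are
entirely model-generated; nothing is fitted to experimental recordings, so
agreement with the in-vivo literature is qualitative (regime structure and
label patterns), never quantitative.

Known limitations, all consequences of the desk-scale calibration and
documented here deliberately:

* The locked left–right regime sits on the model's frequency plateau, so
  intact ramps change frequency far less than 2-fold.  Slower coherent
  modes exist at lower drive but lock in quadrature (phase ≈ ±0.25), which
  the fixed label bands call uncoordinated.
* In-network flexor burst amplitude does not decline at high drive (the
  half-center protects it), so the V0_D pathway does not fade with drive;
  the V0_V/V2a-ablation and EphA4 phenotypes that depend on V3 overtaking
  V0_D at high drive are not reproduced.  The V3 pathway cannot simply be
  strengthened: above a loop-gain bound its mutual excitation tonically
  locks the V0-ablated cord.
* Model 2's extensor-phase commissural pathway carries little phase
  information under the flexor-dominated calibration; Model 1 is the
  demonstrated configuration.
* Ipsilaterally rerouted V0_D axons in the Netrin-1/DCC knockouts impose a
  strong self-inhibition that fragments the scaled rhythm, so those presets
  document rhythm disruption rather than clean hopping.
* A deletion probe at the rhythm-generator level withdraws commissural
  drive, and the tightly locked contralateral side re-anchors with a
  ~half-cycle slip; contralateral invariance would require the
  pattern-formation layer, which is out of scope.  With the extensor
  calibrated at its bursting edge (required by the V1/V2b experiments), the
  extensor also fires intrinsic bursts rather than threshold-exceeding
  sustained activity during a flexor deletion, so the deletion report
  labels it rhythmic.
* The same extensor calibration removes the tonic extensor-to-flexor brake
  that kept the flexor duty cycle low, so flexor burst duration grows with
  the cycle period along the ramp and the phase-duration slopes are nearly
  equal instead of extensor-dominated.

The engineering properties — seeded bit-determinism, dt-refinement
convergence against the adaptive reference, spike conservation, frozen
edge-table audits of all three architectures — are exact and seed-robust.
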