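# Methods

## The model

Turtles produce several distinct rhythmic scratch patterns from
non-rhythmic skin stimulation.  Two of them, pocket and rostral scratch,
share the same three motoneuron (MN) pools — hip extensor (HE), hip
flexor (HF) and knee extensor (KE) — but differ in timing: pocket is
hip-extensor dominant with KE firing together with HE (and switching on
slightly *before* it, during the last part of HF activity), while
rostral is hip-flexor dominant with KE switching on only after a clear
delay from HF onset and switching off together with HF.  The package
implements a central pattern generator (CPG) model in which one fixed
network produces both rhythms, selected purely by the strengths of tonic
external drives.

Each neuronal pool is a single "population" unit with three state
variables: membrane potential `V` (mV), the slow deinactivation `h` of a
persistent sodium current, and a synaptic gating variable `s`:

    C_m dV/dt = -I_NaP(V, h) - I_L(V) - Σ_j g_ij s_j (V - e_syn,j) - i_ext V
    dh/dt     = (h_inf(V) - h) · τ_h(V)
    ds/dt     = α (1 - s) s_inf(V) - β s

with `I_NaP = g_NaP m_inf(V) h (V - e_Na)`, `I_L = g_L (V - e_L)`,
sigmoidal steady states `x_inf(v) = (1 + exp((v - x_half)/θ_x))^-1` and
the voltage-dependent *rate* `τ_h(v) = ε cosh((v - h_half)/(2 θ_h))`.
The rate multiplies the relaxation term as written: h moves faster the
further the voltage is from the half-inactivation point.  This is
essential — "fixing" it to a division changes every time scale in the
model.  Default parameters (shared by all populations): C_m = 0.21 pF,
g_NaP = 10 nS, e_Na = 50 mV, g_L = 2.8 nS, e_L = −65 mV,
m: (−37, −6) mV, h: (−30, 6) mV, s: (−43, −0.1) mV, ε = 0.01 ms⁻¹,
α = 1 ms⁻¹, β = 0.08 ms⁻¹, e_syn^inh = −80 mV, e_syn^exc = 0 mV.  α and
β are printed without units in the source material and are treated as
ms⁻¹ throughout, consistently with ε.  All values are carried as plain
numbers in these units; no unit-conversion layer exists.

Because spikes are omitted, "activity" is read through the population
activity transform `PA(V) = (1 + exp(-(V+30)/2))^-1`; a population is
called active where PA > 0.5.

The synaptic gate saturates at `s_max = α/(α+β) ≈ 0.926` during
activity and decays exponentially at rate β in silence.  θ_s = −0.1 mV
makes `s_inf` nearly a step function; sigmoids are evaluated with a
clamped exponent to avoid overflow.

## Network

Seven populations: four interneuron pools (excitatory EP and inhibitory
IR promote the pocket side; excitatory ER and inhibitory IP promote the
rostral side) and three MN pools (HE, KE, HF) that receive input but
project nowhere.  The interneuron wiring is reciprocal inhibition
within each hip unit generator (EP↔IP, ER↔IR) plus cross-excitation
from each excitatory pool to the inhibitory pool of its own side
(EP→IR, ER→IP).  HE receives excitation from EP and inhibition from IP;
HF mirrors this (ER, IR); KE receives all four.

Two weight classes are shipped.  Both share the interneuron→MN weights;
they differ in the interneuron layer:

| synapse | S (nS) | SCE (nS) |
|---|---|---|
| EP→IP, ER→IR (inh) | 1.4 | 1.8 |
| IP→EP, IR→ER (inh) | 1.0 | 1.0 |
| EP→IR, ER→IP (exc) | 0.5 | 0.8 |
| E→hip MN (exc) | 0.6 | 0.6 |
| I→hip MN (inh) | 2.0 | 2.0 |
| EP→KE / IP→KE / ER→KE / IR→KE | 0.05 / 0.7 / 0.2 / 1.48 | same |

The cross-excitation difference (0.8 vs 0.5 nS) defines the
strong-cross-excitation (SCE) class; the stronger E→I inhibition in SCE
belongs to the same design idea (the whole stimulated side is strongly
recruited) and is what suppresses pocket/rostral bistability in that
class (see below).  **All numeric weights are calibrated, not printed**:
they were recovered by a seeded constrained search
(`experiments.calibrate_weights`) against the qualitative constraints
the architecture must satisfy — reciprocal inhibition strong enough for
a partner to be silenced, escape possible for the excitatory pools, the
rostral-side KE weights strictly stronger than the pocket-side ones,
baseline quiescence, and both rhythm labels under the standard drives.

Drives: uniform baselines of 0.17 nS (S) and 0.16 nS (SCE) elicit no
rhythm.  Scratch stimulation is modeled as a boost of the stimulated
side's two pools: +0.02 nS for S (pocket: {IP 0.17, EP 0.19, ER 0.17,
IR 0.19}; rostral mirrored) and +0.03 nS for SCE.  The SCE boost is the
package's own convention (only the SCE baseline is constrained); +0.03
is the smallest round value for which the SCE pocket rhythm's knee
extensor survives the hand-over race described below.

## How the rhythm works

Every population is intrinsically tonically active (its uncoupled
V-nullcline meets the h-nullcline in a single stable point on the right,
depolarized branch).  Rhythmicity is a network property:

1. **Escape.**  A silenced excitatory pool sits on the left branch of
   its V-nullcline while `h` recovers.  Its inhibition (≈ w·s_max) is
   weak enough that the left branch ends at a jump-up knee below
   h = 1; when `h` reaches the knee the pool escapes into the active
   phase.  The escape time — and hence the antagonist's active-phase
   duration — depends on the escaping pool's drive, which is how ±0.02 nS
   selects the duration ordering (T_HE > T_HF in pocket, reversed in
   rostral).
2. **Partner recruitment.**  The inhibitory pool of the escaping side
   waits at a genuinely stable left fixed point; the escaping E pool's
   fast gate activation adds cross-excitation that removes that fixed
   point, so the pair jumps up together (which is why the I pools'
   drives barely matter).
3. **Hand-over.**  The newly active pair inhibits the previously active
   pair, whose `h` has decayed below the jump-down knee during its
   burst, knocking it to the silent phase.

Elicitation matters.  The rhythm and the non-oscillating tonic state
coexist over the whole working drive range (this coexistence is also
what makes the input-switching and bistability experiments possible).
Applying tonic drives to the resting network symmetrically recruits
every pool and locks the network in tonic activity — this is the
baseline "no oscillation" condition.  A rhythm is elicited by the
stimulus onset itself: simulations of stimulation start with the
stimulated side's pair transiently active (`init="auto"` kicks the pair
whose excitatory pool has the stronger drive).  Consequently the
baseline check runs from rest while rhythm protocols use the kick; this
is the package's operational reading of "no oscillations are elicited"
and is recorded as a deliberate protocol choice.

## Knee extensor timing and the slow phase plane

KE receives overlapping excitation and inhibition from both sides.  In
the reduced module the co-active pairs are lumped (`s_IP = s_ER`,
`s_IR = s_EP`), collapsing KE's slow space to `(h_KE, s_EP, s_ER)` and
its synaptic input to

    I_syn^KE = s_ER[(g_IP+g_ER)V − g_IP e_inh] + s_EP[(g_IR+g_EP)V − g_IR e_inh].

Fixing one gate at `s_max` gives a one-parameter family of fast (V, h)
subsystems per context (rostral unit active: "ER"; pocket unit active:
"EP").  The module computes nullcline branches, knee (fold) curves,
fixed-point curves, and the saddle-node `(s_SN, h_SN)` where the left
and middle fixed points of the ER-active family coalesce (calibrated S
values: s_SN ≈ 0.265, h_SN ≈ 0.992, jump-down ceiling h_max ≈ 0.315).

* **Rostral delay**: at HF onset KE's `h` is high (recovered over the
  whole HE phase); the left fixed point exists and traps it until the
  decaying gate `s_EP` crosses `s_SN` — KE activates *at the
  saddle-node*, typically ≈ 16 ms after HF onset, and jumps down with
  HF.  During the following HE phase the EP-active family has no
  jump-up knee anywhere in range, so KE stays silent.
* **Pocket onset**: KE enters the HF phase with low `h` (it jumped down
  at HF onset), recovers along the left branch and reaches the jump-up
  knee segment late in the short HF phase — before HE starts.  If its
  `h` still exceeds `h_max` when HE takes over (no jump-down knee
  available), KE remains active through the whole HE phase.
* **Key differentiator**: whether `h_KE` at the end of the rostral
  unit's phase lies above or below `h_max` decides pocket- vs
  rostral-type KE synchronization.  Because the HF-phase duration is
  drive-dependent, drives select the rhythm; because the comparison is
  a race with hysteresis, nearby drive sets can be bistable.

The sufficiency conditions are inequalities between slow-flow images of
landmark points (the saddle-node and the endpoints of the jump-up
segment, with forward images over measured phase durations and backward
images to the `s = s_max` line).  One numerical subtlety: the compressed
single-plane notation assigns a single gate minimum to both phase
planes, valid when the two phases have similar durations.  The
calibrated rhythms are strongly asymmetric (≈ 50 vs 37 ms in S), so the
landscape carries both minima: `s_er_min` (minimum of `s_ER` during the
EP/HE phase; defines the intervals I_s, I_h and the printed decay time
T(I)) and `s_red_min` (minimum of the gate that decays during the
ER/HF phase), which sets the forward-flow duration from the saddle-node
(`t_red`).  Without this split the forward flow overshoots the phase
end and the conditions contradict the very simulations they certify.

## Numerical choices

* Integration: LSODA with rtol 1e-8 / atol 1e-10 (the near-Heaviside
  `s_inf` makes the system stiff); halving tolerances moves measured
  phase durations by < 0.5%.
* Phase detection: PA threshold 0.5 with linear interpolation of
  crossing times.  Classification needs ≥ 3 full cycles; the rostral
  "delayed onset" criterion is 5% of the period, and KE/HF offset
  coincidence is judged within 15% of the HF phase.
* Knees: local extrema of the nullcline h(V) on a dense V grid refined
  by bisection on the derivative; samples with h outside [0, 1] are
  reported absent.  Saddle-node: bisection on the existence of the left
  fixed point, cross-checked against the knee/fixed-point intersection.
* Slow flows are integrated in original time; the ε-rescaled slow time
  appears only in derivations.  Flows started exactly on a knee are
  nudged 1e-6 into the branch.  Backward flows that exit the physical
  window (h < 0) are clamped to 0 — meaning no physical silent-phase
  trajectory reaches that endpoint, which renders the corresponding
  condition vacuously satisfiable.
* Default simulation span for classification protocols is 2.5–3 s
  (≈ 25–30 cycles), analyzed after discarding the first half; the
  oscillation detector discards the first 25%.

## What the tests do and do not show

All quantitative tests run on the calibrated networks under the
standard drive sets — they validate the mechanism (escape timing,
saddle-node delay, the h_max race, condition/simulation agreement), not
any fitted correspondence to recorded turtle data, of which the model
uses none.  Each population is a single deterministic unit: population
heterogeneity, spiking, stochastic cycle-to-cycle variability and
sensory feedback are all outside the model, so passing tests say
nothing about those aspects of real scratch rhythms.

## Known limitations and deviations

* The hip-extensor deletion phenomenon cannot be reproduced without
  additional input sources; it is out of scope by design.
* Removing the inhibitory pools' external drive preserves the synchrony
  pattern of both rhythms (the E pools recruit their partners through
  cross-excitation), but in this calibration the rostral KE delay also
  survives — the saddle-node wait depends on the saturating gates, not
  on the inhibitory drives.  The source material reports (without data)
  that the delay is lost; this calibration does not reproduce that
  observation and the experiment's report carries the measured flag.
* The SCE class suppresses bistability over the documented probe grid
  of rostral-eliciting drive sets (excitatory drives ≤ 0.175 nS); a set
  within 0.01 nS of the pocket stimulus still retains pocket.  Relative
  to the stimulus span the bistable band is about three times narrower
  than in the S class; the probe reports its grid coverage rather than
  claiming exhaustiveness.
* The weight calibration search evaluates the shipped defaults first
  ("warm start"), so small-budget reruns reproduce them; a cold search
  with the same seed and a larger candidate budget explores the
  documented log-uniform boxes (interneuron inhibition 0.8–2.4 nS,
  E-side/I-side KE weights 0.02–0.3 / 0.2–1.2 nS and 0.08–0.8 /
  0.8–2.5 nS).
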