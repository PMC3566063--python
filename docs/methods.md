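# Methods

## Scope and model class

`obtriad` simulates an elementary microcircuit of the olfactory bulb: one
mitral cell, one periglomerular (PG) cell coupled to it by reciprocal
dendrodendritic synapses inside the glomerulus (mitral primary dendrite ↔
PG gemmule), and one granule cell coupled to the mitral lateral dendrite
(mitral lateral ↔ granule peripheral dendrite).  All three cells are
reduced multicompartment conductance-based models; each compartment is an
isopotential cylinder and carries Hodgkin–Huxley-formalism currents
`I = ḡ · Πx^p · (V − E)` (positive outward).  External odorant input is
represented by rectangular current pulses: into the mitral glomerular
tuft and the PG gemmule (receptor-neuron input) and into the granule soma
(average bulbar input).

## Numerics

- **Scheme.**  Fixed-step backward Euler at `dt = 0.05 ms` with operator
  splitting: gating variables and graded-synapse activations are advanced
  first by their *exact exponential* update using the previous voltage
  (stable for any step, preserves fixed points); the voltages of all
  compartments are then solved simultaneously from the linear system with
  conductances frozen at the updated gate values, by Gaussian elimination
  in tree (Hines) order.  The scheme is unconditionally stable and
  first-order accurate; the test suite verifies clean first-order
  convergence against an adaptive-step oracle (`scipy.solve_ivp`,
  tolerance 1e-10) and a <1% match to the closed-form passive RC step
  response.
- **Units.**  mV, ms, nA, µS, nF internally; configuration files use
  S/cm², µF/cm², Ω·cm and µm.  All conversions happen in `cable.py`.
- **Calcium.**  Currents flagged as calcium sources drive a submembrane
  shell: `d[Ca]/dt = max(0, −I_Ca/(2F·depth)) + ([Ca]_rest − [Ca])/τ_r`,
  integrated implicitly, floored at 1e-8 mM so the Nernst reversal
  `E_Ca = (RT/2F)·ln([Ca]_out/[Ca]_in)` stays defined.  The PG shell uses
  depth 1 µm, τ_r 5 ms, rest 2.4e-4 mM, external 2 mM: a 1-µm shell keeps
  the Nernst driving force from collapsing during the low-threshold spike
  of this very small cell.
- **Degenerate inputs / blow-up.**  A voltage outside (−150, +100) mV
  aborts with a diagnostic naming the compartment and time; the solver
  never clamps voltages.  Stimuli extending past `t_stop` warn and are
  truncated.  Gate states and synaptic activations are clamped to [0, 1].
- **Determinism.**  The dynamics contain no randomness; repeated runs are
  bitwise identical (tested).  The only stochastic element in the package
  is the optional Gaussian noise of the synthetic fitting targets, which
  is seeded.

## Ionic channel catalog

Kinetics live in `configs/channels.yaml` as data (rate functions are
assembled from a small registry of closed forms), so every constant can
be inspected and overridden without code changes.  The formulations
follow the standard lineages for these cell types — Traub-type Na and
delayed-rectifier rates, a Huguenard–McCormick/Destexhe-form T-type Ca
current with calcium shell, an HCN (h) current, A-type K currents,
an M-type K current and a Bhalla–Bower-form high-threshold Ca and
Ca-activated K pair for the mitral cell.  The published source of the
cell models prints only maximum conductance densities, not kinetics, so
the kinetic constants here were set within their standard forms and then
**calibrated** so that each cell reproduces its printed benchmark
behavior (below).  They are model parameters of this package, not
transcriptions of any particular laboratory fit.

## Cells

### Periglomerular cell

Six compartments: soma 8×8 µm, axon 50×1 µm, two primary dendrites
20×1 µm, dendritic shaft and gemmule 1×1 µm (lateral areas; total
~490 µm²).  Five currents on every compartment, distributed uniformly;
the per-compartment maximum conductances of the fitted parameter table
(`configs/pg_table1.yaml`) are area-proportional, so the soma row divided
by the soma area fixes the densities:

| current | density (S/cm²) |
|---|---|
| HCN (h) | 5.02e-5 |
| K delayed rectifier | 2.21e-2 |
| Na | 1.54e-2 |
| K A-type | 3.08e-2 |
| Ca T-type | 4.84e-3 |

plus a graded GABAergic autapse on the gemmule (0.016 µS).

The passive constants are calibration values: leak 6e-4 S/cm² (input
resistance ~340 MΩ, in the high-resistance range reported for
juxtaglomerular cells), leak reversal −77 mV, C_m 1 µF/cm², R_a
150 Ω·cm; the cell rests near −76 mV.  The hyperpolarized rest is a
deliberate choice: it keeps the T-type current partly de-inactivated so
that a depolarizing step can evoke a low-threshold Ca spike.

**Response mechanism** (100 pA, 600 ms somatic step): the A-type current
activates quickly at −45 mV and clamps the depolarization below the
T-current ignition point; its 12-ms inactivation releases the clamp, the
T-current (activation shifted to −50 mV and slowed ×1.5, availability
midpoint −68 mV) ignites a low-threshold spike that triggers one Na
spike; afterwards the T-current is inactivated, the autapse and the
rectifier hold a depolarized plateau (~25 mV above rest), and no further
spikes occur.  This reproduces, with the table densities, the fitted
cell's qualitative behaviors: one delayed spike then a plateau; no spike
without the T-current; multiple spikes when the T-current is several-fold
larger; and an autapse progression from repetitive firing (weak) through
one increasingly delayed spike to suppression (strong).  The spike
overshoot of this small, heavily clamped cell is modest (~−7 mV), which
is why the package-wide spike-detection threshold defaults to −25 mV
(config-exposed; it separates every spike from every subthreshold
plateau in the modeled protocols).

### Mitral cell

Four compartments (diameter×length, µm): soma 16.2×100, glomerular tuft
26.7×100, primary dendrite 104.4×100, lateral dendrite 170.9×100, chained
tuft–primary–soma–lateral.  Channel densities per compartment follow the
published table (`configs/mitral_table3.yaml`): fast Na, slow K, fast
delayed rectifier, Ca-activated K, A-type K, L-type Ca (the L-current
loads the calcium shell that drives the somatic KCa current).  Passive
constants are calibration values — C_m 1.25 µF/cm², leak 2.5e-5 S/cm²,
R_a 70 Ω·cm — chosen so that a 0.37 nA pulse into the tuft starting at
50 ms produces repetitive firing whose **first spike falls at 103.0 ms**,
the printed benchmark of the study.  At this operating point the model
fires 4 spikes in the 600-ms window (6.7 Hz); the window-based frequency
measure is therefore quantized in steps of 1.67 Hz.

### Granule cell

Three compartments: soma 0.72×50, peripheral dendrite 16.4×50, deep
dendrite 36.1×50 µm.  Densities per the published table
(`configs/granule_table4.yaml`): fast Na, delayed rectifier, A-type K,
M-type K.  Passive calibration: leak 2e-5 S/cm², R_a 70 Ω·cm.  At the
benchmark 0.0625 nA somatic step the cell fires repetitively at ~5 Hz —
deliberately comparable to the mitral rate, so that granule inhibition
(which is largely driven by mitral activity through the reciprocal
synapse) saturates at partial suppression instead of silencing the
mitral cell.  This is what produces the asymmetry between the two
interneurons in the triad.

## Synapses

One mechanism for every contact: `I = g_max · s · (V_post − E)` with
`ds/dt = (s∞(V_pre) − s)/1 ms` and a sigmoidal `s∞`.  Reversals: 0 mV
(combined AMPA/NMDA, no Mg block) and −80 mV (GABA-A).  The release
thresholds/slopes are not printed in the source and are the central
calibration of the circuit:

- mitral terminals: θ = −45 mV, σ = 2 mV — release engages during the
  late subthreshold ramp of the mitral dendrite, so the reciprocal
  mitral↔PG loop operates *before* the mitral spike; this is what lets a
  strong PG synapse silence the mitral cell completely;
- interneuron (PG→mitral) terminal: θ = −43 mV, σ = 1.2 mV — release
  tracks the PG plateau's upper range and switches off cleanly as the
  plateau decays;
- granule terminal: θ = −30 mV (spike-gated; the granule has no release
  plateau), and the mitral→granule terminal is likewise spike-gated at
  −40 mV;
- PG autapse: θ = −38 mV, σ = 6 mV (it senses the locally depolarized
  gemmule).

With these values the coupled pair reproduces the study's qualitative
structure: the mitral frequency decreases monotonically and roughly
linearly with g(PG→M) (Spearman ρ ≈ −0.96 over 21 points on [0, 0.2] µS)
and reaches zero near 0.15–0.2 µS; in the full triad the zero-frequency
band at high g(PG→M) spans the entire g(Gr→M) range, the granule alone
cannot depress the mitral rate below 40% of maximum, and intermediate
g(Gr→M) widens the silenced region (granule facilitation of PG
inhibition).

## Experiments module

Measurement conventions (all config-exposed): spikes are upward
crossings of −25 mV refined to the local maximum of each suprathreshold
excursion, minimum separation 2 ms; firing frequency is the spike count
inside the stimulus window divided by its duration; the plateau level is
the mean voltage over the last 100 ms of the stimulus excluding ±10 ms
around spikes; ΔL is the coupled-minus-isolated first-spike time with
the isolated reference measured once under the identical mitral
protocol; first-spike times are absolute (from t = 0).  Sweep defaults:
g axes 21–30 linear points over [0, 0.2] µS (PG) and [0, 2] µS
(granule); onset-interval steps 5 ms (ΔT_PM) and 10 ms (ΔT_PG).  The
problem sizes used by the shipped studies (1-s simulations; 30×30
conductance grids; 39-point onset sweeps) keep every experiment at desk
scale.

## Fitting module

Error criterion between a target and a model trace of N aligned samples:

    error = sqrt( (1/N) Σ_i (V_target,i − V_model,i)² )

Region-weighted fitness, with the weight *inside* the sum (so uniform
weights w scale the error by √w — this placement is asserted by tests):

    fitness = sqrt( (1/N) Σ_i w(t_i) (V_target,i − V_model,i)² )

The default weight schedule partitions the 1000-ms fit protocol (100 pA
at the soma from 200 to 800 ms): weight 1 during the no-injection
periods and before the spike, 10 in a ±5 ms window auto-located around
the target's spike peak, 5 during the injected period after the spike
(whose level is the plateau feature).  The search is a plain exhaustive
grid over the five conductance densities plus the autapse conductance,
evaluated in deterministic lexicographic order with ties kept at the
first minimum; a combination that blows up numerically scores infinity
and the scan continues.  Because only maximum conductances vary, the
cell is assembled once and conductances are rewritten in place between
grid points, keeping a 3⁶ = 729-point scan around one second per target
on one core.

The experimental recording behind the original fit is not available, so
targets are synthesized from the model itself with known ("planted")
parameters, optionally with seeded Gaussian noise.  Such targets share
the model's sampling grid and have exactly realizable optima — they test
that the search machinery is correct and noise-robust (planted on-grid
parameters are recovered exactly without noise and in ≥90% of seeded
trials at 0.5 mV noise), but they cannot certify that the model family
would fit a real recording, nor reproduce the original fit's printed
error value.

## Known limitations

- **Rate discretization.**  The calibrated mitral cell fires ~4 spikes
  per 600-ms window, so the frequency measure moves in 1.67 Hz steps and
  the "bands" of the conductance-plane grids are few and coarse.
- **Latency-shift curve shape.**  In the onset-interval study the model's
  ΔL(ΔT_PM) rises monotonically up to a cutoff at positive ΔT_PM instead
  of plateauing over [−60, −40] ms: with its shallow suprathreshold
  margin (~0.1 nA) the mitral cell is held by PG inhibition in an
  essentially binary fashion, and its first spike is gated by the decay
  of the PG plateau rather than by graded overlap of a bounded
  inhibition pulse with its charging ramp.  The qualitative facts — an
  optimal onset interval range and loss of effect once the PG input
  arrives too late — are present, but the plateau edge is not
  quantitatively reproduced.
- **Kinetics provenance.**  Channel kinetics are standard-form
  formulations calibrated to printed benchmark behaviors, not verbatim
  transcriptions of the original models' rate tables.
- **Scope.**  A single deterministic triad; no receptor-input noise, no
  network-level lateral inhibition, no temperature dependence, no
  NMDA voltage dependence, and spatial resolution fixed at the published
  compartment counts.
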