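# Methods

This note documents the model equations as implemented, the choices made
where the published description leaves room, the numerical scheme, what the
synthetic inputs do and do not emulate, and known limitations.

## Neurons and synapses

Both populations are leaky integrate-and-fire neurons with conductance-based
synapses; E neurons additionally carry an adaptation current *z* (pA) with
subthreshold coupling *a* (nS) and spike-triggered increment *b* (pA).
Parameters (membrane time constant, resting conductance and potential,
reversal potentials, threshold, reset, 8 ms refractory period, adaptation
constants) follow the published table for E, I and the "simple" variant;
the I population carries no adaptation term at all.  All internal arithmetic
uses nS, mV, ms and pA; the effective capacitance is `g_rest * tau_m`
(nS·ms = pF), so no unit conversions appear inside the integrator.

Two single-neuron constraints were verified against the implementation: a
500 ms step current of 15 pA elicits no spike, and 100 pA drives ~22 Hz
firing.  The unitary E→E EPSP at the set-A weight (128 pS) peaks at
1.04 mV, inside the 0.2–2 mV plausibility band that constrained the
published weights; `measure_psp` agrees with an independent 1 µs-step
integration to 0.13%.

## OB input

Odors activate exactly 10% and inhibit exactly 5% of the 1500 mitral cells
(150/75 at full scale).  Onset rates are discrete uniform 8–32 Hz (1 Hz
steps), latencies 0–200 ms (1 ms steps), inhibited rates 0–5 Hz; decay time
constants 1, 2, 4 s are assigned in exactly equal proportions.

*Decay anchor.*  The published description says activated-cell rates
"decrease exponentially" without stating the asymptote.  We anchor the
decay at baseline — `rate(t) = 6 + (onset − 6) · exp(−(t − latency)/tau)` —
because the time-averaged activated-cell rate then matches the published
~15 Hz (decay to zero gives ~12 Hz).  Inhibited cells step to their reduced
rate at latency and hold it for the rest of the presentation.

*Subspace construction.*  The 11×11 mixture grid follows the two printed
lookup tables (concentration per pure odor; availability pool C = table
value × 1.5).  Cell counts round half-*down* (half-up would push per-pixel
totals one cell past the 150 + 10% bound at the 32 pixels where the printed
percentages sum to 110%); availability pools round half-up (matching the
worked value 45 × 1.5 = 67.5 → 68).  When two pure odors' selections
collide on a cell, a replacement is drawn from the remaining pool;
validation enforces the ±10% per-pixel totals with integer-outward bounds
plus half-a-cell rounding slack per pure odor.  Correlated pure-odor
quartets share cell *identities* (half of each set with each square-edge
neighbor) but draw rates and latencies independently per odor; this
reproduces the published adjacent-odor correlation range (~0.25–0.45),
whereas shared attributes would overshoot it.

*Morphs* keep a fraction (1 − x) of one parent's affected cells and take x
of the other's, each cell retaining its parent-odor attributes; cells
present in both parents are never duplicated.

## Connectivity

Each target neuron receives exactly `round(p · N_src)` inputs per pathway
(uniform sampling without replacement, no autapses).  Out-degrees are then
regularized into ±5% of the pathway mean by reassigning edges from over- to
under-connected sources — unlike deletion/addition, reassignment keeps every
in-degree exact.  We verified that true Bernoulli sampling is incompatible
with the published behavior: its in-degree spread alone drives the baseline
E rate to ~0.7 Hz, far above the published <0.1 Hz.

## Assemblies

Assembly E members are the 100 E neurons with the largest
multiplicity-weighted count of OB connections from the odor's activated
cells (ties broken uniformly at random, seeded); assembly I members are the
25 I neurons receiving the most E→I connections from those E members.
Rewiring adds within-group connections (uniform draws; a draw landing on an
existing pair increments its multiplicity, doubling the effective weight)
and deletes an equal number of inputs from outside the group, so in-degrees
are conserved exactly — a property asserted for every pathway and variant.

*Reference density for the factors.*  A rewiring factor scales the group's
*current* mean within-connectivity (floored at `p · group size`).  For α
(E→E) and β (I→E) this equals the naive `factor · p` because the
memberships are unbiased with respect to those pathways.  For γ (E→I) it
matters: the assembly I neurons are *selected* for dense input from the
assembly (~24 of 160 E inputs vs 4 expected by chance), so γ = 3 raises
that enriched density (24 → 72).  Under the naive reading γ-rewiring would
be a no-op (target 12 < 24 already present) and Tuned E+I networks ignite
into Scaled-I-like attractors; with the implemented reading they show the
published phenomenology — learned-odor population rates within a few
percent of novel-odor and random-network rates, modest (~2×) within-assembly
amplification, and fully transient responses.

Overlapping assemblies are rewired sequentially; compensating deletions
exclude only the current assembly's members.

## Numerical scheme

Forward Euler with dt = 0.1 ms for all state variables (conductance decay
uses the Euler factor `1 − dt/tau` for consistency).  Spikes detected at
step *n* reach their targets at step *n* + 1; OB spikes are injected at
their own step.  During the refractory period the membrane is clamped to
the reset potential while conductances and adaptation keep evolving.
Initial conditions: V uniform within 5 mV above rest, conductances and z at
zero, with a 500 ms discarded warm-up.  The JIT-compiled loop is verified
spike-for-spike against an independent dense-matrix integrator on a small
network.

Single-neuron trajectories converge under dt refinement to ~0.1%.  The
*population* rate of the full balanced network is far more sensitive: the
recurrent loop amplifies the O(dt) integration bias roughly 30-fold
(dt = 0.1 → 0.05 ms moves the mean odor rate by ~15%), the same knife-edge
sensitivity that ±10% changes of a single synaptic weight show (0.7 → 2 Hz).
Tests therefore check strict convergence at the single-neuron level and
regime stability (silent baseline, sparse odor response) at the population
level.  This sensitivity also bounds how closely any independent
reimplementation can be expected to match published population rates: with
the exact printed parameters this implementation yields odor-evoked E rates
of 0.70–0.93 Hz across parameter sets A–D (published: ~1 Hz), with all
bound-type observables (baseline < 0.1 Hz, recurrent fraction > 80%,
instability at α ≈ 6, >10 Hz without inhibition) reproduced.

## Inhibition-shuffle probe

The probe records a control run, redistributes each I neuron's spike times
uniformly over the recording, and replays them as frozen inhibition while E
and OB evolve freely (injected spikes are aligned so that an identity
replay reproduces the control exactly).  Shuffling within the odor window
only — which preserves the mean odor-window inhibition — never produces
runaway in this network (it suppresses E activity instead), so the
whole-recording shuffle, which also spreads odor-locked inhibition into
baseline, is used.  Runaway is declared when the E-population rate exceeds
10 Hz for 200 ms (an order of magnitude above the odor regime), or when a
run exhausts its spike budget.  Measured probability across sets A–D is
0.15–0.33, below the published 0.79 ± 0.20 — consistent with this
implementation's slightly cooler operating point (see above); the direction
of the effect (stable with intact inhibition, runaway risk once inhibition
is decorrelated) reproduces.

## Analysis conventions

Observables are E-population quantities time-averaged over the first 1.5 s
of each presentation; conductance measures subtract the 500 ms pre-odor
baseline per neuron, and small negative changes are retained.  Windowed
per-neuron conductance means for all 4000 E neurons are accumulated inside
the integration loop (cumulative sums snapshotted at window edges), so
co-tuning analyses need no trace storage.  The balanced axis is the
no-intercept least-squares fit of I on E conductance over all neuron×odor
pairs; per-neuron dispersion ratios cap at 100 when the counter-balanced
spread vanishes.  Mahalanobis distances use plain sample covariances
(no shrinkage — singular covariances are a *diagnostic* for attractor
dynamics and raise, as does QDA).  QDA training classes take half-window
(0.5 s) averages of epochs whose OB correlation to a pure odor exceeds 0.6;
test epochs are below 0.6 for all pure odors; both readouts subsample
80-neuron subsets (50 draws) from the assembly pool or the whole
population.  Concentration readouts equilibrate sample counts across
concentration values by keeping more trials of rare values (the published
4-or-8 / 2-to-6-trial device); the regression reports in-sample MSE, the
linear SVM mean two-fold cross-validated accuracy over 15%-wide classes
spanning (0, 90].

## Synthetic data: scope

The OB generator emulates rate statistics, latencies, slow adaptation and
trial-to-trial Poisson variability of mitral cells, but not glomerular
dynamics, oscillations, correlated noise across cells, or
concentration-dependent latency coding.  Passing tests therefore show that
the *network* transforms idealized afferent patterns as described — not
that these patterns capture all structure of biological OB activity.

## Problem sizes

The reproduction script uses desk-scale problem sizes: one full-size
network (set A) with 5 s baseline and 5 odors for the rate observables;
one network per set A–D × 5 odors for the shuffle probe; 5 connectivity
seeds for assembly statistics; 10 odor-set seeds for subspace correlations;
one full-size Tuned E+I network × 10 learned odors for the balance slope.
The test suite runs structured-network dynamics at quarter scale
(1000 E / 250 I / 375 OB) with in-degrees preserved by raising connection
probabilities — conductance statistics then match the full model, at the
price of coarser population averages; all quarter-scale qualitative
dichotomies (attractor persistence, co-tuning ordering, dimensionality
ordering) were spot-checked against full-size runs.

## Known limitations

* Quantities that sit on the balanced-state knife edge (absolute
  population rates, the runaway probability) land near but not on the
  published values; bound-type and structural quantities reproduce tightly.
* No conduction delays, short-term plasticity, or online learning rules;
  assemblies are constructed, not learned.
* The "simple" parameter set produces a much quieter network than sets A–D
  under identical drive; it is provided for completeness (biophysical
  E/I-equalization controls) and not used by the reproduction script.
* Event bookkeeping assumes at most one spike per neuron per 0.1 ms step
  (enforced by the refractory period and the rate·dt < 1 check on inputs).
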