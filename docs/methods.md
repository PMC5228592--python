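# Methods

## Scope and model

`bgnet` simulates a spiking network model of the rodent basal ganglia
(BG): the two striatal projection populations (MSN D1, MSN D2), striatal
fast-spiking interneurons (FSN), the subthalamic nucleus (STN), the two
globus pallidus externa populations (arkypallidal TA and prototypical TI)
and the output nucleus SNr.  The model addresses two linked questions:
how tonic dopamine loss reshapes synchrony and beta-band (15–25 Hz)
oscillations across the circuit, and how the same circuit transmits
learned cortico-striatal "action" signals to its output (selection =
suppression of an SNr subpopulation).

## Neuron models

Two hybrid point-neuron families are used, each with one fast (membrane
potential `V`, mV) and one slow (recovery/adaptation current `u`/`w`, pA)
state variable.

**Quadratic integrate-and-fire with adaptation** (MSN, FSN):

    C dV/dt = k (V - v_r)(V - v_th) - u + I
    du/dt   = a [ b (V - v_r) - u ]            (MSN)
    du/dt   = a [ b (V - v_b)^3 - u ]  if V <= v_b, else  -a u   (FSN)

with reset `V <- c`, `u <- u + d` at the cutoff `v_peak`.  The FSN's
cubic recovery below the kink voltage `v_b = -55 mV` produces type-2
onset: a hard step from silence to spiking with brisk, brief
afterhyperpolarizations.  The recovery rate `a` is stored in 1/ms (0.2
for FSN, 0.01 for MSN — the standard convention for these parameter
sets; the catalogue documents the unit).  MSN D2 differs from D1 only in
its resting potential (-80 vs -78.2 mV) and spike-triggered increment
(91 vs 66.9 pA), making D2 slightly more excitable.

**Adaptive exponential integrate-and-fire** (STN, GPe TA/TI, SNr):

    C dV/dt    = -g_L (V - E_L) + g_L Δ_T exp((V - V_T)/Δ_T) - w + I
    τ_w dw/dt  = a (V - E_L) - w

with reset `V <- V_r`, `w <- w + b` at the cutoff `t_f`.  Two
population-specific variants:

* STN: the subthreshold adaptation conductance `a = 0.3 nS` applies only
  below -70 mV (it is zero above), and the post-spike reset is
  depolarized to `V_r + max(w - 15, 20)` whenever `w < 0` at spike time.
  This is the printed rule implemented literally; because `max(w-15, 20)`
  equals 20 for any negative `w`, the effective rebound reset is -50 mV.
  A `stn_reset_mode="min"` switch implements the alternative reading.
  Negative `w` (and hence rebound bursting) arises only after sustained
  hyperpolarization below `E_L = -80.2 mV`, e.g. release from a strong
  hyperpolarizing step.
* GPe TA vs TI: TA has 150% of TI's capacitance, slope factor and
  spike-triggered adaptation, giving the flatter current-frequency curve
  of arkypallidal cells.  With their tonic biases (TI 12 pA, TA 1 pA) the
  models pace at ~18 and ~8 Hz.  Both are *bistable* at low drive: a
  stable subthreshold fixed point coexists with the spiking limit cycle.
  `fi_curve` therefore starts the membrane just above threshold so that
  pacemakers are measured on the spiking branch; in the network, synaptic
  noise performs the same role.

**Heterogeneity.** Within a population, capacitance is Gaussian with a
CV of 10% (resampled when non-positive) and the spike threshold Gaussian
with SD 1 mV; all other parameters are shared.

## Synapse models

Static synapses are conductance-based single exponentials: an arriving
spike increments `g` by the peak conductance `g0`; between events `g`
decays with `τ_syn`; the current is `g (E_rev - V)`.  NMDA receptors are
additionally weighted by the Jahr–Stevens magnesium block

    B(V) = 1 / (1 + [Mg2+]/3.57 * exp(-0.062 V)),   V in mV,

with `[Mg2+] = 1 mM` by default (a standard physiological choice; the
catalogue treats it as configurable).  Cortical input to MSN and STN
co-activates AMPA and NMDA components from the same event stream.

Short-term facilitation/depression uses the Tsodyks–Markram three-pool
resource formalism (recovered `x`, active `y`, inactive `z`, utilization
`u`).  At a spike, facilitation precedes release (`u <- u + U(1-u)`, then
`r = u x` moves from `x` to `y`), so the first event from rest releases
exactly `U`.  `τ_fac = 0` rows denote the no-facilitation limit (`u`
pinned to `U`).  Between events the states relax by their closed-form
exponentials, evaluated lazily at event times; `x + y + z` is conserved
to machine precision.  The postsynaptic conductance jump per spike is
`g0 · r`.

The row of the short-term-plasticity table labelled as the MSN D2→SNr
synapse (U = 0.24, τ_rec = 11 ms, τ_fac = 73 ms) is applied to the MSN
D2→GPe TI projection: MSN D2 does not contact SNr in this circuit, and
the indirect-pathway synapse is the one the parameters describe.

## Dopamine

Tonic dopamine is a scalar receptor occupancy `α ∈ [0, 1]`; every
catalogued parameter is scaled as `p <- p (1 + β (α - 0.8))`, the
identity at the normal occupancy 0.8 and maximal depletion at `α = 0`
(the 6-OHDA model).  Each `β` is derived in closed form from an
experimental constraint: an amplitude ratio `R` between zero and full
occupancy gives `β = (1-R)/(0.8 + 0.2R)`; a resting-potential shift `Δ`
gives `β = -Δ/base`.  The catalogue stores each `β` with the constraint
it came from, and the solvers re-derive them in tests.  Fan-in targets
(MSN collaterals, FSN→MSN D2) are scaled in the same form and rounded
half-up with a floor of zero.  Depletion is applied to a *configuration*
(pure, idempotent), and individual targets can be restored to their
control values — the one-parameter restoration mode used in the lesion
experiments.  The MSN D1→SNr entry uses the standard form with β = 0.56
(reproducing its 0.5× ratio); the literal `1 - β α` variant is available
behind a switch.

## Connectivity

Population sizes are fixed fractions of the total (anchored at the
80,000-neuron reference: 37,971 MSNs of each type, 1,599 FSN, 388 STN,
329 TA, 988 TI, 754 SNr).  Connectivity is specified as an exact
in-degree per postsynaptic neuron; partners are drawn uniformly without
replacement, with no self-connections and no duplicate edges.  Striatal
connections are spatially restricted on a 1-D index ring: windows are
stored in MSN-count equivalents (the ~2,800-MSN axonal/dendritic field
for MSN collaterals and FSN→MSN, the ~540-MSN FSN axonal field for
FSN→FSN) and converted to eligible-pre counts by population fraction.
Scaled-down networks keep *absolute* fan-ins, because firing rates
depend on the number of inputs per neuron, not on connection
probability; when a scaled pool is smaller than the requested fan-in the
builder caps the in-degree at the pool size with a loud warning.  One
tenth of GPe TI neurons (the striatum-projecting subpopulation) supplies
all TI→FSN edges.

**Nonconnected clusters.** For the lateral-inhibition contrast
experiments, collateral edges between members of a designated low-index
MSN cluster are removed and redrawn from outside the cluster, preserving
every in-degree exactly.

**Action channels.** Selection experiments embed two (or more)
channels: each action claims a `pool_fraction` of one half of MSN D1
(Go pool) and of MSN D2 (NoGo pool), half of SNr, and a fraction of GPe
TI.  Go_i projects only to the SNr pool of action i; NoGo_i projects to
the TI pool of action i, which projects to the *other* action's SNr pool
(disinhibition of the competitor's output).  Two construction choices
were genuinely open and are fixed as follows:

* `channel_share` (default 0.75): the fraction of a mapped post neuron's
  in-degree drawn from its pool, the rest from unassigned neurons.  It
  encodes the learned concentration of a pool's output onto its mapping
  (a pool whose targets are restricted to one SNr subpopulation delivers
  its whole axonal budget there); the share is capped by pool
  availability, so small scaled networks degrade gracefully.
* NoGo-pool placement: the NoGo pool of action i occupies the ring
  segment of action (i+1) mod n in MSN D2.  Because MSN collaterals are
  spatially windowed, a NoGo pool co-located with its own action's Go
  pool would laterally inhibit it during co-activation; placing it over
  the competitor's territory makes the collateral field act on the
  competing channel, consistent with the functional role of the
  indirect pathway.

## Extrinsic drives

Each population receives an independent Poisson stream per neuron at the
catalogued rate for the cortical regime: slow-wave (rest under
anesthesia) or activation (sensory-evoked).  Square-wave modulation
alternates the rate between `v(1+a)` and `v(1-a)` every half cycle: 1 Hz
in the slow-wave state (both dopamine conditions), 20 Hz (beta) in the
activation state of the *depleted* condition only; control activation is
unmodulated.  Drives can carry a modulation phase offset (modelling the
source→target conduction delay) and transient episodes: multiplicative
bursts on labelled subsets (selection trials: 100-ms burst + 900-ms
rest) and additive pulses (the 100-ms hyperdirect STN stop signal).
Selection trials co-burst the FSN drive (FSNs share the cortical
afferents); the STN drive is bursted only in the explicit stop-signal
arms, where the hyperdirect excitation of SNr opposes selection.

## Engine

Clock-driven forward Euler at `dt = 0.1 ms` (configurable).  Spikes are
detected at step end (membrane clamped to the cutoff, which also guards
the AdEx exponential), queued per connection in a ring buffer of its
delay (rounded to the dt grid, all catalogued delays are representable),
and delivered as conductance increments into per-(population, channel)
accumulators; static channels exploit linear superposition, dynamic
edges keep per-edge Tsodyks state updated lazily at event times.
Randomness comes from named streams (per population and per drive)
derived from the master seed, so adding probes or drives never perturbs
unrelated dynamics; records are bit-reproducible given the seed.  The
engine audits emitted versus delivered events and aborts with a
diagnostic on non-finite state.  Initial membrane potentials are
jittered between reset and threshold to avoid artificial synchrony
(disable with `init_jitter=False` for deterministic single-neuron work).

## Analysis

Spike trains are binned at 256 Hz (bin 1000/256 ≈ 3.9 ms), the sampling
rate of the reference in vivo recordings.  Synchrony is the Fano factor
of the summed population count per bin (1 for Poisson firing).  The
oscillation index is the fraction of spectral power in a band (default
15–25 Hz) of the unit-averaged Welch spectrum of mean-subtracted binned
trains (flat spectrum ⇒ band width / Nyquist ≈ 0.078).  Coherence uses
Hanning-windowed *disjoint* segments so the analytic null threshold
`1 - (1-p)^(1/(L-1))` applies; window lengths of 256 and 2048 samples
give 1-Hz and 0.125-Hz resolution for beta and slow-wave bands (the
printed window values in milliseconds conflict with those stated
resolutions; the resolutions win).  Phase relations band-pass the binned
trains (zero-phase forward–backward Butterworth, order 3 sections),
take Hilbert instantaneous phases, and histogram the pointwise
difference over 100 bins in [-π, π); circular means summarize.
Unit-pair coherence is the default (population-level trains are used
for phase, where the population signal is the object of interest).
Selection outcome: an action is selected when its SNr pool's mean rate
during the 100-ms selection phase drops below 50% of the control
baseline; outcomes are none / action 1 / action 2 / dual.

## Numerical and protocol choices

* Euler at dt = 0.1 ms tracks a 10× finer reference to <1% in rate for
  the AdEx pacemakers at their tonic biases and to ~2% for the QIF
  models at strongly suprathreshold currents; network-level rates at
  dt = 0.05 ms agree within 2% plus Poisson counting error.
* Tie-breaks: delays round to the nearest grid point (minimum one
  step); fan-in scaling rounds half-up; infeasible pools cap with a
  warning rather than resampling silently.
* The `α_k` MSN parameter (a D2 effect on the I–V coefficient) is
  stored but disabled: no postsynaptic D2 dopamine effect is included.
* The "static FSN→MSN" inhibition arm replaces the dynamic synapse by a
  static one matched to the first-event conductance (`U·g0`).
* Silencing currents are found by bisection on the injection amplitude
  in probe runs.

## Experiment scales

Tests and the acceptance script run deliberately scaled-down protocols,
chosen as the smallest sizes at which the studied quantities are
meaningful: the network baseline at N = 10,000 with full fan-ins (5 s,
1 s discarded); beta-band phase/coherence contrasts at N = 5,000 (4.5 s)
over five replicate seeds with sign-test-style orderings; selection
grids at N = 5,000 with `pool_fraction = 0.2` and a handful of trials
per cell.  N = 5,000 is the smallest scale at which the collateral
window (2,800 MSN-equivalents) no longer spans a whole MSN ring, so the
NoGo-pool placement retains its meaning; depleted selection arms are
classified against a control-network baseline computed at the same seed.
The full-scale protocol (80,000 neurons, 7×7 factor grids, 80 trials
per cell) is reachable through the same interfaces.

## What the synthetic conditions do and do not show

All inputs are synthetic Poisson processes with the catalogued rates;
there is no learned cortico-striatal weight structure (channels are
embedded by construction), no thalamo-cortical feedback, and no phasic
dopamine.  Passing tests therefore demonstrate the circuit-level
consequences of the catalogued physiology — depletion-induced beta
synchrony, its phase structure, inhibitory control of striatal gating,
and selection transmission — not behaviour of the real circuit under
natural inputs.

## Known limitations

* With the catalogued activation-state drive, the FSN population sits
  near 100 Hz, well above the 10–20 Hz in vivo range the drive tables
  aim for: the printed cortical rate (787 Hz through a 0.5 nS / 12 ms
  AMPA synapse) delivers ~5× rheobase, and the pallido-striatal
  inhibition onto FSN is strongly depressing (U = 0.29, τ_rec = 902 ms),
  retaining too little steady-state efficacy to balance it.  The
  mechanism catalogue is implemented as printed; the discrepancy is
  surfaced by the acceptance suite rather than papered over.  Because
  FSN→MSN synapses are depressing, the elevated FSN rate further reduces
  their per-spike efficacy, weakening feed-forward inhibition arms.
* Euler integration limits accuracy for the fast QIF upstroke; spike
  times carry O(dt) jitter.
* At desk scales some in-degrees (notably STN→GPe at N < 8,000) are
  capped by population size; metrics depending on those pathways are
  read comparatively (control vs lesioned at the same scale), never as
  absolute predictions.
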