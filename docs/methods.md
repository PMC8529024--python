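# Model and methods

## The circuit

The package simulates the antennal lobe (AL) of a moth as six glomeruli,
each containing 10 excitatory projection neurons (PNs, cholinergic) and 6
inhibitory local neurons (LNs, GABAergic): 96 cells in all.  Connectivity
is random but frozen per seed.  Within a glomerulus, ordered pairs connect
with probabilities PN→PN 0.75, PN→LN 0.75, LN→PN 0.38, LN→LN 0.25; across
glomeruli only LN→PN synapses exist (probability 0.38).  Autapses are
excluded (the convention adopted here; at these densities the effect is
negligible).  Every candidate ordered pair is an independent Bernoulli
draw.

## Neuron dynamics

Both cell classes follow conductance-based integrate-and-fire dynamics in
non-dimensional voltage units (leak/reset V_L = 0, threshold V_thres = 1,
excitatory/stimulus reversal 14/3, inhibitory/SK reversal −2/3):

    dV/dt = −(V − V_L)/τ_V − g_SK (V − V_SK) − g_stim (V − V_stim)
            − g_exc (V − V_exc) − g_inh (V − V_inh) − g_slow (V − V_inh)

with τ_V = 20 ms; the SK term exists only for PNs.  A threshold crossing
records a spike and clamps V at V_L for τ_ref = 2 ms.

Synaptic and stimulus conductances are kernel sums over presynaptic or
external event times with instantaneous-rise exponential kernels
(1/τ)·e^(−t/τ): fast excitation, fast inhibition and stimulus share τ = 2
ms; slow (GABA_B-like) inhibition has τ_slow = 750 ms.  Coupling strengths
select on the postsynaptic class: PN→PN 0.01, PN→LN 0.006; fast inhibition
0.0169 (onto PN) / 0.015 (onto LN); slow inhibition 0.0338 / 0.04;
stimulus jumps 0.004 / 0.0031.  Fast and slow inhibition are driven by the
same LN spike set.

The SK current is an intrinsic, spike-triggered potassium current of PNs:
g_SK = S_SK · Σ β(t − s) over the cell's own spikes, where β rises
sigmoidally to 1/τ_SK over 2·τ_rise = 50 ms (half-rise 25 ms) and then
decays with τ_SK = 250 ms.  β has a small discontinuity at the branch
point (the sigmoid attains e⁵/(1+e⁵) ≈ 0.9933 of 1/τ_SK); the piecewise
definition is implemented exactly, not smoothed.  S_SK is drawn once per
PN from N(0.5, 0.2) clamped at zero; the fixed-SK network variant sets
every PN to the mean (used for the conductance sweeps of the
pulse-following rate).

The `scale_*` multipliers (SK, fast inhibition, slow inhibition,
excitation, stimulus) scale the corresponding strengths uniformly in both
cell classes; 1 is the standard strength.  The SK multiplier is applied at
network construction (it scales `sk_strength`), the others at simulation
setup.

## Stimulus model

Every cell receives an inhomogeneous Poisson stream of external events,
each an instantaneous g_stim jump.  The rate is

    λ(t) = λ_back + Σ_pulses [ gain_g · λ_odor · O(t) + mech · λ_mech · M(t) ]

with λ_back = 3.6 /ms, λ_odor = 3.6 /ms, λ_mech = 1.8 /ms.  Scenarios:
background (no pulses), odor-only (odor to glomeruli 0–2), mech-only
(mechanosensory drive to all glomeruli), additive (literal sum of the two
pulse terms).  The graded-odor paradigm replaces the 1/1/1/0/0/0 gain
vector with (0, 0.2, 0.4, 0.6, 0.8, 1.0), keeping total odor drive equal.

The envelopes O and M rise at pulse onset and decay exponentially
(τ = 384 ms, anchored at offset); rise style depends on cell class —
odor: PN sigmoidal (half-rise 35 ms), LN instantaneous; mechanosensory:
PN instantaneous, LN sigmoidal (half-rise 300 ms).  Tails of earlier
pulses persist and superpose, which is what ultimately degrades
high-frequency tracking.  The decay branch starts at 1 regardless of the
value the rise had attained by offset, exactly as the piecewise model is
defined.  For the standard 50 ms pulses this makes the LN mechanosensory
envelope (whose rise spans 600 ms) jump from ≈ 0.015 to ≈ 1 at offset:
the global LN population effectively receives its mechanosensory drive
right after each pulse.  The idealization is load-bearing — it keeps
fast LN inhibition from smothering the PN onset burst while the delayed
LN surge, acting through the slowly accumulating inhibitory synapses,
truncates PN firing between pulses: the mechanism behind brief,
high-frequency-trackable mechanosensory responses.  Two alternative
resolutions of the piecewise overlap were evaluated and rejected: a
continuous decay from the attained value leaves LNs without meaningful
mechanosensory drive for short pulses and inverts the
odor-vs-mechanosensory tracking ordering, and letting the rise continue
past offset (rise-branch precedence) smooths global inhibition so much
that the non-odor PN's pulse locking in the combined scenario falls
below the tracking cutoff at all frequencies.

## Numerics

Forward Euler with Δt = 0.1 ms for the membrane equation.  The
exponential conductances are stored as single accumulators decayed by the
exact factor e^(−Δt/τ) (unconditionally stable; identical to the kernel
sum to rounding error) with per-event jumps S/τ.  The non-exponential SK
kernel is evaluated exactly by splitting each spike's contribution:
while a spike is younger than 50 ms its sigmoid value is read from a
table on the Δt grid; at the step its age exceeds 50 ms its remaining
contribution is pure exponential and is folded into one decaying
accumulator.  No truncation is involved at any age.

Spikes are detected at end-of-step without sub-step interpolation, and
reach postsynaptic conductances on the next step (one-step latency,
removing within-step order dependence).  External events land on bin
boundaries; per bin, a Poisson count with mean λ·Δt is drawn (counts, not
a Bernoulli flag — λ·Δt reaches 0.9 at stimulus peak).  The inner loop is
compiled with numba; a fixed stimulus seed makes a trial byte-identical
across runs, and the one-step `step()` API drives the same compiled
kernel, so chunked stepping equals a single run bit for bit.

State starts from rest (V = V_L, all conductances zero).  Protocols carry
a pre-stimulus window so background activity develops before pulses;
because slow inhibition has τ = 750 ms, experiments that compare against
baseline activity (the AHP measurement) use a 4000 ms pre window and read
the baseline from its final second, when the network is equilibrated.

## Metrics

**Response length** — spikes from stimulus onset; the response ends at
the spike preceding the first interspike interval exceeding three times
the mean of the train's first three ISIs; length = end − first spike.
Trains with fewer than four spikes fall back to last − first (0 for ≤ 1
spike), keeping the metric continuous as responses fade.

**Response slope** — ordinary least-squares slope of response length
against pulse length over the pulse-length grid (default 25–500 ms, step
25).  Each trial contributes one sweep across the grid, so the mean of
per-trial slopes equals the slope of mean response lengths.

**Pulse-following index** — the raster (one PN over trials, or the
pooled PNs of a glomerulus) is binned at 5 ms from the first pulse onset
to the end of the pulse window; each trial's count vector is z-scored; the
correlogram is the mean cross-correlation over distinct trial pairs,
symmetrized over lag sign.  This equals the cross terms of the
trial-pooled raster's autocorrelation: modulation locked to the pulse
train survives pooling, while firing rhythms with trial-random phase
(notably the intrinsic SK adaptation cycle) cancel, and excluding the
within-trial diagonal terms removes the small-sample bias a windowed
extremum search would otherwise inherit.  The index is the correlogram
peak within one pulse duration of the period lag minus its trough at the
intermediate lags, floored at 0.  A tonic or Poisson raster scores ≈ 0; a
raster that bursts once per pulse scores far above the 0.05 cutoff.

**Pulse-following rate** — the highest tested frequency whose
trial-mean index is ≥ 0.05 (ties count as following); 0 if none.

**AHP suppression duration** — after the final pulse the decaying odor
tail still drives firing above baseline; the suppressed phase begins when
the trial-averaged rate (non-overlapping 200 ms windows) first falls
below the equilibrated baseline and ends at the first sustained return
(two consecutive windows within 10 % of baseline).  The reported duration
runs from final pulse offset to that recovery.  Because the rate
approaches baseline asymptotically (slow inhibition decays with τ = 750
ms toward its background level), an exact-threshold first crossing is
ill-conditioned; the 10 % tolerance and the two-window requirement make
the estimate stable against window noise at 50 trials.

## Experiments and problem sizes

The standard experiments use the published design: 50 trials per
condition with fresh stimulus seeds (structural seed fixed), 50 ms
pulses, a 3000 ms pulse window with 500 ms pre and 1500 ms post, pulse
frequencies 1–12 Hz, pulse lengths 25–500 ms, conductance multipliers
0–3.  Probe cells are the first PN of glomerulus 0 (odor-receiving) and
the first PN of glomerulus 3 (non-odor).  The test suite runs the same
experiments on reduced grids (15–20 trials, coarser multiplier and
frequency grids, 5-point length grids), chosen so the full suite stays
desk-scale; the acceptance script uses the full 50-trial conditions.

## What the synthetic rasters do and do not show

`make_synthetic_raster` produces pulse-locked (Poisson bursts inside
pulses only), tonic/Poisson (homogeneous) and empty trains.  They validate
the metric contracts — locked structure scores high, structureless firing
scores ≈ 0 — but carry none of the model's burst shapes, latencies or
adaptation, so metric tests on them say nothing about network dynamics;
the simulation-backed tests cover that.

## Known limitations

* The AL is reduced to six glomeruli of identical composition;
  multiglomerular PNs, centrifugal feedback and receptor-neuron dynamics
  are out of scope.
* The envelope offset jump for incomplete rises (above) is a modelling
  idealization of delayed LN recruitment, not a physiological claim.
* The exact autocorrelation recipe behind the published index is not
  recoverable from its one-sentence description; absolute index values
  here are on this package's own scale, and conclusions should rest on
  the 0.05-cutoff rates and their orderings, which are robust to that
  scale.
* The post-train suppression estimate depends on the recovery tolerance;
  with the asymptotic approach to baseline, tighter tolerances lengthen
  the reported duration (see the AHP section).
* Plain Euler at Δt = 0.1 ms over-estimates interspike intervals by a few
  percent relative to a fine-grid integration (checked in the tests); all
  published-design comparisons use the same step.
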