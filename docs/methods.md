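# Methods

## The model

`stngpe` simulates a small subthalamo-pallidal circuit: 10 subthalamic
(STN) and 10 external-pallidal (GPe) conductance-based model cells on a
ring.  Each STN cell projects to its corresponding GPe cell; each GPe cell
inhibits its corresponding STN cell and that cell's two ring neighbors.
Every cell is a five-variable system (v, n, h, r, [Ca]):

    C dv/dt  = -I_Na - I_K - I_L - I_Ca - I_T - I_AHP + I_app - I_syn + I_ext(t)
    dx/dt    = phi_x (x_inf(v) - x) / tau_x(v),        x in {n, h, r}
    d[Ca]/dt = epsilon (-I_Ca - I_T - k_Ca [Ca])

with spike currents I_Na = g_Na m_inf^3 h (v - v_Na) and
I_K = g_K n^4 (v - v_K), leak I_L, high-threshold calcium
I_Ca = g_Ca s_inf^2 (v - v_Ca), low-threshold T current
I_T = g_T a_inf^3 b_inf(r)^2 (v - v_Ca), and the calcium-activated
potassium current I_AHP = g_AHP [Ca]/([Ca]+k1) (v - v_AHP).  I_AHP is a
K+ current and reverses at v_AHP = v_K; a formulation with the calcium
reversal here would be depolarizing and destroys the cells' pacemaker
behavior.  Synapses are first-order kinetic gates,
ds/dt = alpha H_inf(v_pre - theta_g)(1 - s) - beta s, with
I_syn = g_syn (v - v_syn) * sum of afferent gates.  The external current
I_ext(t) is applied to STN cells only.

All gating curves are sigmoids with midpoint/slope pairs; all constants
live in `src/stngpe/data/default_params.yaml` and nothing is hard-coded.
STN and GPe cells share the equations and differ only in parameter
values.  b_inf(r) is a sigmoid-difference gate normalized to zero at
r = 0 and increasing in r (negative slope parameter), so the T current
de-inactivates under hyperpolarization and supports rebound — the slope
sign is configurable.

### Parameter provenance and calibration

The STN cell uses the canonical Terman-type constants; an isolated STN
cell is an autonomous pacemaker (~3 Hz at I_app = 0) with a nearly linear
f-I curve (~1.3 Hz per current unit).  Two ingredients were calibrated
rather than transcribed, because no printed source fixes them for this
network:

- **GPe excitability.** The GPe leak is g_L = 1.0 toward v_L = -65 mV.
  At the default striato-pallidal drive I_app = 5 the GPe cell is then
  essentially input-driven (silent in isolation, firing when excited by
  its STN afferent); at I_app = 7 and 9 it becomes progressively
  autonomous.  This makes the loop a single forced oscillator whose
  coherence degrades as I_app grows — the behavior the applied-current
  parameter is meant to control.  With a weak GPe leak the GPe cell is a
  ~65 Hz autonomous pacemaker whose pulse train blocks beta-band
  entrainment of the ring entirely.
- **Cell heterogeneity.** STN applied currents carry per-cell offsets:
  the Gaussian quantiles of the population size scaled by a jitter
  parameter (SD scale 2.0 current units, ~2.5 Hz of intrinsic-rate
  spread), assigned around the ring by a fixed maximal-spread schedule
  so that neighboring cells receive dissimilar drives.  The profile is
  deterministic — the run seed randomizes initial conditions and input
  noise, not the heterogeneity — which keeps the autonomous synchrony
  level a property of the parameter point rather than of the draw.
  Identical cells lock completely (1-2 principal components) for any
  coupling; the heterogeneity keeps the autonomous network in the
  partially synchronized regime (4-6 components) in which the coupling
  strength g_syn and the input amplitude have something to do.  GPe
  cells are homogeneous: their afferent is what synchronizes STN, and
  jittering it converts shared rhythm into per-cell noise.

With these defaults (STN I_app = 18, pallido-subthalamic pulse rates
alpha = 2, beta = 0.2) the autonomous network at (g_syn, I_app) =
(0.7, 5) or (0.9, 5) oscillates near 19-20 Hz, spiking in short
beta-locked bursts (often single spikes per cycle) whose timing
interleaves across cells within the cycle, and responds resonantly to
beta-band input: near the indigenous rhythm a sine amplitude of ~6-7
current units locks the population (<= 3 principal components), while
off-resonant frequencies need larger amplitudes or fail within the
studied range.  The component count at zero amplitude is 6 / 6 / 5 at
g_syn = 0.5 / 0.7 / 0.9 (I_app = 5) and rises with GPe I_app, matching
the direction of both control parameters in the study design.

## Inputs

Three input classes, all bounded by the amplitude A:

- `sine`: A sin(2 pi omega0 t / 1000), t in ms, omega0 in Hz.
- `noisy_sine`: A sin(2 pi omega0 t / 1000 + xi) with xi ~ N(0, 0.08)
  drawn independently at each integrator output grid point and held
  constant across the RK4 sub-stages of the step.  The variance is per
  draw; the spectral peak stays at omega0.
- `phase_derived`: A sin(phi(t)) where phi is the beta-band Hilbert phase
  of a supplied single-channel signal.  The band-pass and phase
  operations are the same implementations the analysis chain uses.

The `synthetic_cortical_signal` generator stands in for recorded
motor-cortex EEG: Gaussian white noise shaped by a resonant peak filter
(default peak 13 Hz, bandwidth 6 Hz, i.e. Q ~ 2.2), plus a 30% white
floor, normalized to unit variance.  It reproduces the two spectral
facts that matter for the phase-derived input path — broad spectrum,
beta peak — and nothing else about real EEG (no 1/f background, no
artifacts, no nonstationarity), so results obtained with it demonstrate
the machinery, not patient-level reproduction.

## Simulation

Fixed-step classical RK4, default dt = 0.05 ms, which resolves the ~1 ms
spikes and passes a dt-halving self-convergence check (<1% change in
total spike count).  Initial conditions per run seed: v uniform in
[-65, -55] mV, gating variables at steady state for the initial v,
[Ca] = 0.3, synapse gates 0.  Spikes are upward crossings of -20 mV
separated by >= 2 ms.  The surrogate LFP at site i is the ring-
neighborhood average (site and its two neighbors, uniform weights) of the
magnitude of the pallido-subthalamic synaptic current delivered to each
neighbor; the weighting is isolated behind a parameter.  The first
1000 ms of every run are discarded before analysis.

## Synchrony analysis

Signals are band-passed 10-30 Hz with a 4th-order zero-phase Butterworth
(forward-backward), after mean removal; instantaneous phase is the
analytic-signal argument.  The spike-train phase uses the binary train
directly (mean-removed, filtered, Hilbert).  The first-return map records
the spike phase at every upward crossing of a checkpoint (default 0) by
the LFP phase, with linear interpolation to the crossing instant; the
checkpoint value is statistically irrelevant for locked signals.  The
phase circle is partitioned into four equal pi/2 arcs with the
phase-locked state (circular mean of the recorded phases) at the center
of the synchronization arc; arcs are labeled 1-4 in traversal order.
Per-region transition rates divide the points leaving a region on the
next map step by all points in that region (the final point counts in
the denominator).  The experiment-match flag tests whether every model
rate lies within 0.7 reference SDs of a reference rate set; the shipped
reference values are documented placeholders — the patient-derived rates
are an external input, so the flag's absolute calibration is
configuration, not reproduction.

Whole-network synchrony is the number of principal components capturing
80% of the variance of the STN slow-variable matrix (the gating variable
r by default; [Ca] or s selectable).  PCA is covariance-based on
mean-centered, unstandardized columns.  Fewer components = more
synchronous; counts map to the study's categories (1-3 red, 4-5 green,
6-7 blue, 8-10 black).

## Sweeps and resonance curves

A sweep runs one simulation plus analysis per (A, omega0) cell at a fixed
(g_syn, I_app) pair; the five named presets are (0.5,5), (0.5,7),
(0.5,9), (0.7,5), (0.9,5).  Cell seeds derive deterministically from the
base seed and the cell identity, so sweeps resume exactly and an
early-stopping upward amplitude scan reproduces the full grid's
minimal-amplitude curve at a fraction of the cost.  Replicates (default 1
for figure-style grids, 3 for the reduced protocol) are aggregated by
median component count.  The minimal-amplitude curve gives, per
frequency, the smallest grid amplitude whose aggregated count reaches a
target (3 or 5); the tongue tip is its argmin, with ties broken toward
the deeper radius-1 neighborhood average, then toward the lower
frequency.

**Problem sizes.** The full study grid is 10-30 Hz x A 0-16.  The
package's reduced protocol — used by the acceptance script and the
heavier tests — is 14-24 Hz x A 0-10, 6 s simulated time per cell with
1 s transient, 3 replicate seeds.  Six seconds of network time per cell
is the shortest window for which the component count of a 6-s window
agrees with longer runs to within one unit; the reduced grid still
brackets the printed resonance locations.

## Numerical and degenerate-input conventions

Non-finite states abort integration with the failure time.  A region
never visited has an undefined (NaN) transition rate and fails the match
criterion.  An all-undefined minimal-amplitude curve has no tongue tip
(error); the tip needs at least three defined frequencies.  If the
circular mean of the return-map phases is undefined (resultant length
~ 0) the locked-state center falls back to the densest quarter-circle,
with a warning.  The match-criterion boundary (exactly k SDs) is
inclusive.

## Known limitations

- The exact constants of the precursor network are not printed in any
  available source; the shipped set is a calibrated Terman-type set (see
  the calibration section).  Quantities tied to the paper's precise
  parameter values (figure-level color maps, the experiment-match flag's
  absolute calibration) are reproduced qualitatively, not numerically.
- Heterogeneity stands in for the deterministic chaos that the precursor
  model presumably supplies; patterns of intermittency are therefore
  statistically, not mechanistically, matched.
- The LFP surrogate is a weighted synaptic-input sum, not a
  volume-conductor model.
- No thalamic, cortical or striatal populations; no closed
  cortex-basal-ganglia loop.
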