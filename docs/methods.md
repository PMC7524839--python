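# Methods

## The problem

A single intracellular recording — membrane potential or transmembrane
current from one neuron, sampled at 1 kHz — is usually summarized by a
scalar *deflection* from baseline and decoded through a tuning curve.  The
premise of this package is that the same recording carries stimulus
information in its *dynamics*: the trajectory the signal traces through a
reconstructed state space, and the ordinary differential equation that
locally generates that trajectory.  "Dynamical discrimination" decodes the
stimulus from the coefficients of per-trial sparse polynomial ODE fits.

## Pipeline

1. **Dimensionality expansion** (`dyndisc.embed`).  The chosen response
   epoch of every trial of a cell is concatenated and stacked into a Hankel
   matrix of 101 time-shifted rows (100 delays of 1 ms).  An SVD reduces the
   rows to `d = 3` dimensions (3–7 supported); trajectory coordinates are
   the singular-value-scaled right-singular time courses (principal-
   component scores), sliced back into per-trial trajectories by the trial
   owning each column's first sample, then centered on the grand mean.
   Rows of the Hankel matrix are not Z-scored.  Scores keep the
   singular-value scaling because per-trial amplitude is physiological
   signal: the occupancy decoder and the state-variable analyses rely on
   axial displacements that unit-norm modes would distort.

2. **Sparse ODE fitting** (`dyndisc.sindy`).  The library holds all
   monomials of total degree ≤ 3 of the state (constant first, graded-
   lexicographic).  Derivatives are 5-point fourth-order central
   differences smoothed with a 3-point moving average; two samples are
   trimmed at each end.  Library columns are Z-scored per fitted snippet
   (the constant column is exempt and always live), so every downstream use
   of a coefficient matrix Xi — Euler integration
   `V'(t) = V'(t-1) + Xi^T [E(V'(t-1)) - mu]/sigma`, fixed-point solving,
   Jacobians — carries the same change of coordinates.  One Xi is fitted
   per trial under a shared binary mask; fits are ordinary least squares on
   the mask-selected columns (internally via cached per-trajectory normal
   equations, which agree with a fresh least-squares solve to machine
   precision and make a masked fit a few-by-few linear solve).

3. **Genetic mask search** (`dyndisc.evolve`).  The mask is the genome.
   Seeds come from per-trajectory dense fits thresholded per column at the
   largest magnitude that leaves one survivor; the seed set is expanded to
   the population size (default 300) by crossover and mutation at rate
   0.15.  Each generation breeds children by tournament (parent 1 cycles
   the 45 ranked elites, parent 2 is drawn with probability proportional to
   rank, no self-mating); a child keeps bits present in both parents,
   coin-flips bits present in one, then mutates at the scheduled rate —
   0.05 in generation 1, halved at `N_mut = max(2, ceil(log2(0.05 N_Xi)+1))`
   evenly spaced checkpoints over the first 90% of generations, zero for
   the last 10%.  Elites are re-scored every generation because the
   classification objective is noisy; runs stop early when the elite
   fitness spread falls below 1/1000 of the initial population's range.
   Fitness ties break toward sparser masks, then mask bytes, so runs are
   bit-reproducible from their seed.

4. **Objectives and decoding** (`dyndisc.decode`).  Fitness is
   `0.8 * error + 0.2 * density`.  The classification error term is one
   minus the mean macro-F1 of a 5-tree forest over ten rounds of
   per-stimulus 25% holdout; the regression variant uses `1 - R^2` of a
   5-tree forest predicting the continuous label.  The goodness-of-fit
   error term Euler-integrates each fit four steps from every trajectory
   point and scores `1 - R^2` between the derivatives the model predicts at
   the endpoints and the data derivatives four steps ahead.  (Comparing
   *states* instead is vacuous at 1 kHz — any fit tracks 4 ms of drift, the
   sparsity term then dominates, and the search collapses to near-empty
   masks; the derivative comparison restores the intended gradient.)
   The final decoder trains one 51-tree forest per elite mask; votes
   combine by mode with ties resolved by the top-ranked elite, or by median
   for regression.  Regression forests use a third of the features per
   split (the classic bagged-tree default); classification forests use the
   square root.  Honest numbers come from `outer_holdout`: hold out one
   example of every stimulus, run seeding + evolution + ensemble training
   on the remainder, predict the held-out trials, repeat (default 20).
   Scrambling labels first (surrogate mode) measures the overfitting floor;
   surrogate CCR stays inside the exact binomial chance interval.

5. **Baseline decoders.**  The deflection decoder is a random forest on the
   scalar deflection under the same outer protocol.  The occupancy decoder
   histograms each 3-D trajectory's axial/radial coordinates (cylindrical
   about the first principal axis of the per-stimulus-centered training
   cloud; the angle is discarded) on a 20 x 10 grid spanning the pooled
   training range, Gaussian-smooths with a one-bin kernel, floors densities
   at 1e-12 before logs, and assigns each held-out trajectory to the
   stimulus maximizing the occupancy-weighted log likelihood
   `sum_bins M_t (log M_s + log M_t)`, placing the trajectory in each
   candidate stimulus's frame (centered by that stimulus's central point)
   before histogramming — per-stimulus centering otherwise erases the
   axial displacements the decoder is meant to detect.  The unweighted
   double sum
   factorizes into stimulus-only plus trajectory-only terms and cannot
   classify at all, so the product over *time points* (equivalently, the
   per-bin count weighting) is the reading implemented.  The
   state-variable decoder regresses per-trial reliability and mean
   deflection from Xi features (median-vote ensembles) and classifies the
   stimulus from those two predictions with a third forest.

6. **Stability analysis** (`dyndisc.stability`).  Real fixed points of the
   de-normalized system are found by multi-start root finding (hybr, 200
   starts over a data-scaled box, deduplication at 1e-6 relative, residual
   filter 1e-8).  A numeric multi-start is used for every dimension rather
   than symbolic elimination: generic dense cubic systems routinely defeat
   symbolic solvers in bounded time, and the closed-form Lorenz fixed
   points validate the numeric path exactly.  Jacobians are analytic
   (`sum_m Xi_mk/sigma_m dE_m/dV_l`); classification uses a tolerance of
   1e-6 times the spectral radius; "net convergent" is trace(J) < 0, with
   the strict reading (max real part < 0) also reported, since the term
   admits both.

## The synthetic benchmark (`dyndisc.lorenzbench`)

Latent dynamics are the Lorenz system (sigma = 10, beta = 8/3) with rho
swept over the integers 20–40, through the Hopf bifurcation at
`sigma(sigma+beta+3)/(sigma-beta-1) = 470/19 ≈ 24.7` and into chaos.
Initial conditions are uniform: X, Y in [-16, 16], Z in [-56, 56].  Each
trial is one second at a 10 kHz simulation clock (10,000 samples,
fixed-step RK4 with substeps capped at 5e-3 time units), keeping only X.

**Time base.**  The literature this benchmark emulates is internally
inconsistent about the mapping from Lorenz time to signal time: a literal
1e-4 s step with 10 K steps puts the entire spectrum below ~2 Hz, which
would make the 300 Hz band-limit criterion, the membrane low-pass concern,
and the 1 ms/100 ms embedding-window rationale all vacuous.  The package
therefore exposes `time_scale` (Lorenz units per second), default **20**,
which places the Lorenz oscillation period (~0.7 units) at ~35 ms — inside
the 100 ms delay window and in the band the soma genuinely filters.  This
choice matters: at 1 unit/s each trial is a short arc dominated by its
initial condition; at 100 units/s the 1 ms derivative stencil becomes the
noise floor.  Both regimes degrade rho regression several-fold relative to
the default.

**Band limiting.**  A trial whose fraction of spectral power below 300 Hz
(DC included) falls under 90% is regenerated with fresh initial conditions
at a time scale slowed by `tau = 0.9 * total / below-cut power`,
cumulatively, until the criterion holds (cap 20 iterations).  At the
default time scale the criterion is a safeguard that rarely binds.

**Encoders.**  `current_hh`: `I = alpha1 (X' - zeta1)` clamped to
[-0.15, 0.15] nA injected into a single-compartment Hodgkin–Huxley soma
with classic squid-axon kinetics and a 1000 um^2 membrane (so 0.15 nA is
~15 uA/cm^2, comfortably suprathreshold); integration uses 0.025 ms
substeps with exponential-Euler gates, batched across trials.  Spikes are
0 mV upward crossings; the potential is block-averaged to 1 kHz and
optionally spike-filtered (5 ms median).  `poisson_synapse`: per-0.1 ms
event probability `P = alpha2 (X' - zeta2)` in [0, 1] drives 80–300
excitatory synapses (double-exponential conductance, rise 0.2 ms, decay
1 ms, reversal 0 mV) whose per-synapse peak `g0 * 80 / N_syn` keeps the
total peak conductance independent of the synapse count; this point-neuron
emulation stands in for a morphologically detailed model, so
multi-compartment figures are qualitative expectations only, not targets.
Calibration tunes a gain by bisection toward a target *group-mean* spike
count — deliberately inexact, so spike counts scatter across trials.

**Binning.**  Fifteen logarithmic spike-count bins `[0,1) ... [39,50),
[50,inf)`; the interior edges are the deduplicated integer rounding of a
16-point log spacing from 1 to 50, which lands exactly on the published
anchor edges.  Synapse bins: 19 per low-spike bin (<5 spikes; starts 80–120
by 10, then 125 up by 15) and 16 otherwise (starts 80–305 by 15), giving
the 255 possible two-way bins.  A bin is analyzed iff, after dropping rho
values with fewer than 3 trials, at least 45 trials remain (both thresholds
configurable; reduced scales lower them proportionally).

**Benchmark experiments.**  Regression: embed all 1 kHz trial series
jointly, hold out a stratified 25%, evolve masks under the regression
objective, train the 45-member median-vote ensemble, and report the median
absolute percent error of held-out rho predictions.  Classification:
restrict rho to {22, 25, 28, 31, 34, 37} labeled 1–6 (chance 1/6), reuse
the regression-evolved masks, train voting ensembles per spike bin with
repeated hold-one-per-label splits, and report the median CCR across bins.

## Synthetic fixture (`dyndisc.fixtures`)

Test and demo trial stores are baseline + stimulus-dependent step +
stimulus-dependent damped oscillation + Gaussian noise at 1 kHz, with ramp,
sigmoid, or Gaussian deflection tuning and per-stimulus oscillation
frequencies.  A damped second-order oscillation is the minimal
stimulus-coded dynamics a 3-D embedding with a cubic library can represent,
so the genetic search has a recoverable ground truth; a Gaussian
(non-invertible) tuning with distinct frequencies creates stimuli that
deflection decoding confuses but dynamical discrimination separates.  The
generator emulates the statistical shape of evoked intracellular responses
— it has no spike waveforms, no slow drift, no correlated (1/f) noise, and
its dynamics are linear — so green tests certify the machinery, not
performance on any particular real recording.

## Problem sizes and tolerances

Full-scale defaults follow the published operating point (population 300,
45 elites, 100 generations per 3 mask columns, 10 x 25% inner holdout,
51-tree final forests, 20 outer repetitions).  The acceptance script and
the end-to-end tests run the same code at a reduced scale chosen as the
package's standard desk-scale configuration: 21 rho values with 10 (script)
or 5 (tests) initial conditions each, 45 elites with population 100/80 and
20/12 generations, and proportionally lowered bin-acceptance thresholds in
the tests.  The generation count is deliberately modest: because the mask
search optimizes a cross-validated score on a fixed trial pool, longer
searches select masks that overfit the inner folds and degrade held-out
error at this pool size.  For six-way classification the six rho values
are re-encoded at ten current gains spanning the calibrated range so the
spike-count bins are dense enough to apply the published acceptance rule
(>= 45 trials, >= 3 per rho) verbatim; with thinner pools the rule rejects
everything or leaves only a handful of training examples per label.  Elite
fitness is noisy at this scale; the ensemble median/mode absorbs most of
it.

Numerical choices: derivative trimming (2 samples/end) avoids one-sided
stencil bias; Euler integration flags (not raises) blow-ups past 1e6 x the
data scale; fixed-point deduplication at 1e-6 relative; eigenvalue
classification tolerance 1e-6 x spectral radius; occupancy floor 1e-12;
baseline search ties break to the earliest window; argmin/argmax tuning
ties break to the lower ordinal.

## Known limitations

- The per-trial error of rho regression on 1 s chaotic trials is bounded
  below by initial-condition variability: distinct ICs at the same rho
  yield genuinely different local attractor samples.  At the default time
  base this floor is a few percent — several-fold above the smallest
  published figure, which depends on an effective time base the source
  does not state consistently.  The ordering across encoder tiers (raw <=
  current-injection <= synaptic error) is robust.
- The goodness-of-fit objective's optimum on clean Lorenz data omits one
  collinear term of dX = sigma(Y - X): under the 0.8/0.2 weighting,
  dropping it costs less error than it saves sparsity.  Support recovery
  is therefore 6/7 + constant rows, reproducibly.
- Reliability uses absolute deflection; residual noise measures use the
  leave-self-in cross-trial mean.  Second-order derivatives and d > 3 are
  configuration pass-throughs, untested beyond construction.
- The optional loader for the public experimental deposit is out of scope;
  experimental-data quantities are replaced by the property checks in the
  acceptance suite.
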