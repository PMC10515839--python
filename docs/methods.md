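# Methods

This note documents the models behind each wormcircuit component, the
parameters that matter, and the choices made where the design was open.

## The three-term signal model and its correction pipeline

Each voxel trace in a two-channel recording is modeled as

    S_c(t) = F_c(t) · B_c(t) · A(t) + N_c

where `c` is the channel (calcium-sensitive green, calcium-insensitive
red), `F_c` the fluorophore signal, `B_c(t) = a1·e^(−λ1 t) + a2·e^(−λ2 t)`
a double-exponential photobleaching decay, `A(t)` a multiplicative artifact
shared between channels (focus drift, residual body motion), and `N_c` a
time-independent additive noise term.  Because the red fluorophore is
calcium-insensitive, `F_red` is constant, so a double-exponential fit to
the noise-subtracted red trace estimates `F_red·B_red(t)` and the ratio

    A(t) = (S_red(t) − N_red) / fit_red(t),  renormalized to mean 1,

isolates the artifact.  The green trace is then noise-subtracted, divided
by `A(t)`, bleach-corrected by a second double-exponential fit restricted
to event-free timepoints, and rescaled so its non-event median is 1.

Choices within this pipeline:

- **Raw trace extraction.** Per volume, voxels in an 11×11×5 box around the
  annotated neuron center are sorted by intensity and the 40 brightest are
  averaged.  The descending-sort reading is forced by the geometry: most of
  the 605 voxels in the box are background, so only the top of the sort
  carries neuron signal.  Annotation gaps of up to 3 consecutive volumes
  are filled by linear interpolation; longer gaps stay missing.
- **Noise estimation.** The 0.8 quantile (linear-interpolation convention)
  over all voxels of a channel is taken per volume and aggregated by the
  median across volumes, which is robust to the bleaching trend.  For a
  centered background noise distribution this estimator sits slightly above
  the true additive offset (by ~0.84 SD for Gaussian noise); that small
  bias is inherent to the quantile approach and is part of the error budget
  quoted below.
- **Double-exponential fitting.** Non-negative amplitudes and rates,
  initialized from log-linear fits to the first and last thirds of the
  included points (clamped to sane ranges), refined by bounded
  least-squares; a generic second starting point guards against bad
  initializations, and the better of the two fits is kept.  Components are
  reported fastest-first.  On constant input the fit degenerates gracefully
  (rates → 0) and reproduces the constant to ~1e−7 relative.
- **Event exclusion for the green bleach fit.** "Within an event" means
  [onset − 1 s, onset + duration + 3 s]; the 3 s tail pad covers most of
  the indicator decay (time constant 2.5 s in the generator), but a small
  tail (~e^(−pad/decay)) leaks past it, which limits the identity-pipeline
  rescaling to ~0.1% flatness when transients are present.
- **Normalization.** "Proportionally adjusted" is implemented as a
  rescaling so the non-event median of the corrected trace equals 1; the
  median is robust to residual transients.

### What recovery on synthetic data does and does not show

With the default generator settings (below), across 20 seeded movies the
red-channel bleach rates are recovered with ~4% median relative error and
corrected traces correlate with the true calcium signal at r > 0.99.  Rate
identifiability degrades steeply with artifact amplitude and correlation
time: double-exponential rate estimation is ill-conditioned, and the
low-frequency component of any multiplicative disturbance is absorbed into
the bleach fit, so a recording with (say) an 8% artifact wandering on a
10 s timescale yields rate errors of ~20% even though the *corrected
trace* — the quantity the downstream analyses use — remains accurate
(r > 0.99).  Passing recovery tests therefore validates the pipeline's
correctness, not its robustness to arbitrarily poor recordings.

## Synthetic-data generators

All randomness flows from one seed through named substreams (one per
generator operation), so identical (config, seed) yields bit-identical
outputs and partial pipelines are reproducible.

- **Movies.** Volumetric imaging at 4 Hz with 25 z-planes of 0.4 μm
  lateral / 1.2 μm axial voxels is the geometry the analyses assume; the
  default volume is a 24×24×9 crop around two simulated neurons rather
  than a full camera frame, and the default recording lasts 240 s.
  Neurons are rendered as truncated Gaussians (σ = 1.6 voxels).  Channel
  brightness defaults (red 800, green 600 peak units over a floor of 100)
  put the top-40 trace SNR in the comfortably identifiable regime.
- **Bleaching.** Red (a1=0.35, λ1=0.03/s, a2=0.65, λ2=0.004/s), green
  (0.30, 0.04, 0.70, 0.005): a fast component with ~30 s time constant
  plus a slow one decaying ~40–60% over the recording, both identifiable
  within 240 s.
- **Artifact.** Log-domain AR(1) (Ornstein–Uhlenbeck flavor), exponentiated
  and renormalized to mean 1; defaults 1.5% stationary SD with 1 s
  correlation time emulate a well-immobilized worm on an agar pad.  The
  renormalization makes "mean 1 over the recording" true by construction.
- **Calcium transients.** Event-locked kernel: linear rise (0.6 s) then
  exponential decay (2.5 s), amplitude 1.5 ΔF/F — slow-indicator-like
  kinetics without committing to a specific indicator model.  Reversal
  events: exponential gaps (rate 2/min) plus a hard 5 s refractory period;
  truncated-normal durations (3 ± 1 s, min 0.3 s).
- **Tracks.** Centroid = smooth heading path + sinusoidal lateral
  undulation (period 2 s, amplitude 40 μm, speed 100 μm/s, 20 Hz sampling,
  1 μm localization jitter).  The heading is constant within a movement
  step (five undulation periods) and rotates toward the dorsal side by the
  programmed bias at each step boundary; programmed reversals negate the
  motion along the body axis for their duration.  Dorsal side +1 puts
  dorsal on the left of the heading (counterclockwise turns are dorsal).
- **Mosaic populations.** Each animal starts with the array in the root
  cell; every division edge transmits independently with probability p;
  a terminal cell retains the array iff all edges on its root path
  transmitted.

What the generators deliberately do not emulate: body posture and skeleton
dynamics, indicator saturation and nonlinearity, spatially varying
illumination, neuron tracking errors beyond dropped annotations, and
behavioral state structure beyond programmed reversals and turn bias.
Recovery on these synthetics validates the estimators under the model's
own assumptions; real recordings violate them in ways the tests cannot
probe.

## Event-locked analyses

Event-triggered averages crop a [−3 s, +3 s] window around each reversal
onset (the 6 s window is centered, consistent with the stated [−3, 0]
baseline interval), snap onsets to the nearest sample (at 4 Hz sampling,
sub-sample interpolation is unwarranted), use the baseline mean F0 over
[−3, 0] to form the change ratio (F − F0)/F0, and average across events
with the SEM across events as the uncertainty band.  Windows that would
extend past the recording are dropped and counted.  Spaghetti
normalization uses a [−3 s, +7 s] window and divides each segment by its
own first-3-s mean.  Pairwise Pearson correlations are computed on full
corrected traces (not only event windows), per pair per animal; class
summaries average within animal first, then across animals, and class
comparisons use Welch's t test on the per-animal class means.

## Behavior metrics

A centroid track has no body axis, so forward/backward classification
projects the instantaneous velocity onto a slowly varying axis estimate:
the velocity averaged over one movement step (five undulation periods,
10 s by default).  That window is long enough that reversals lasting up to
roughly half of it leave the axis pointing along the overall direction of
travel — shorter smoothing windows let the axis swing around during a
reversal and produce runaway false detections afterwards.  A
forward-to-backward transition must persist 0.5 s to count; a track whose
smoothed speed exceeds 5 μm/s in fewer than half its samples is classified
as non-moving (zero reversals, with a warning).  On 100 seeded tracks with
programmed reversals of 1–4 s this detector recovers ≥ 99% of events with
< 1% spurious detections and durations accurate to about one frame.

Undulation periods are found as successive same-sign zero crossings of the
lateral deviation from the smoothed (one-period moving average) path;
five periods form one movement step, the trailing partial step is
discarded, and the turning angle between successive step displacement
vectors is reported as the interior angle: 180° straight, < 180° dorsal,
> 180° ventral, using the track's dorsal-side flag to orient the sign.
The dorsal side is an input — it is not inferable from a centroid path.

## Lineage mosaic model

If a fraction f of animals retains an extrachromosomal array after D
divisions, the per-division transmission probability is p = f^(1/D); the
probability of retention through k further divisions is p^k.  With
f = 39/181 and D = 18 (two shared divisions to the divergence node, then
eight per RIM side), p ≈ 0.91826; the headline value is reported at
4-decimal truncation (0.9182) alongside the full-precision and rounded
(0.9183) forms, since the printed convention is not stated.

The shipped fixture tree is a reduced encoding: only division counts
matter, so untracked daughters are elided (unary pass-through divisions)
and all tracked bilateral pairs diverge at the single node two divisions
below the root — which requires a multifurcation there.  A strictly binary
encoding cannot place every pair's divergence at depth 2, and the model's
published predictions require exactly that (root conditioning adds exactly
2 shared divisions for every pair).  Per-pair post-divergence counts are
ASI 16, ADL 18, ASK 20, ADA 16, PHB 16, PVQ 14, RIC 8.

Two printed 4-RIM (root-conditioned) fractions — ADL 0.19 and PVQ 0.25 —
are inconsistent with p^(k+2) for any integer k (the closed form gives
0.18 and 0.26); the package reports the closed-form values.  Report
columns round half-up to 2 decimals; full precision is retained.

Monte Carlo validation simulates per-division loss over the same tree,
conditions on the stated event (array in both RIM sisters for
divergence conditioning) and compares conditional frequencies with the
closed forms under binomial standard errors.

## Numerical conventions and degenerate inputs

Voxel indices 0-based; time in seconds from recording start; positions in
micrometers; angles in degrees.  CSVs are UTF-8 with mandatory headers.
Division-by-near-zero in artifact computation raises a degenerate-fit
error naming the time index; non-positive event baselines raise a
degenerate-baseline error naming the event; zero-variance traces are
excluded from correlation summaries with a log entry; stationary tracks
yield zero reversals with a warning rather than an error.  Monte Carlo
checks use 3 binomial SEs, chosen so that a 7-pair table has roughly a 2%
chance of a false alarm under the null.

## Problem sizes

Default test and validation sizes were chosen so the whole suite runs in
well under a minute: 240 s movies over 24×24×9 voxel crops (20 seeds for
parameter-recovery summaries), 200,000 simulated mosaic animals, 100–200
seeded tracks of 120 s at 20 Hz, and 50-event traces for event-triggered
averaging.  All scale linearly if larger runs are wanted.
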