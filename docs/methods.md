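# Methods

`mousefield` quantifies the spontaneous behavior of a single mouse in a
square open-field arena from pose-keypoint time series (and, optionally,
from raw video via centroid tracking).  This note documents the models
and procedures each stage implements, the parameters that matter, and
the design choices made where the design was genuinely open.

## Recording model

The pipeline assumes bottom-view recordings of one mouse in a
45.7 × 45.7 cm arena sampled at 80 Hz, so a 20-minute trial holds 96,000
frames.  Its canonical input is a `KeypointTimeSeries`: per-frame 2-D
positions of named body markers (snout, chin, inner and outer paw
points, tail base, tail tip) in pixels, with the pixel-to-meter scale
carried as metadata.  When per-marker confidence is available, markers
whose median confidence falls below 0.85 are excluded from the posture
representation; the default posture subset holds 11 markers.

## Centroid tracking and alignment (`tracking`)

Raw grayscale stacks are reduced to a centroid track in three steps:

1. **Background** — per-pixel median over 50 frames sampled uniformly at
   random across the recording (random sampling keeps the moving animal
   out of the median).
2. **Centroid** — each frame is background-subtracted, down-sampled
   (default factor 4), Gaussian-blurred (default σ = 2 px
   post-downsampling), and the centroid is the intensity-weighted center
   of the connected bright region containing the maximum.  The weighted
   regional centroid, rather than the argmax pixel, gives sub-pixel
   stability.  A 400 × 400 px window centered there is recorded per
   frame, clamped at the borders.  Frames with an empty difference image
   are flagged and linearly interpolated.
3. **Egocentric alignment** — each frame is translated so the tail base
   sits at the origin and rotated so the tail-to-snout axis lies along
   +y (anterior).  Alignment is an isometry: all pairwise marker
   distances are preserved exactly.

Centroid kinematics use centered differences of the smoothed (9-frame
moving average) metric centroid for speed, and the smoothed unwrapped
body-axis heading for angular velocity.

## Posture representation (`posture`)

Mouse bodies are not rigid, and any egocentric axis choice biases the
representation toward the markers that define it.  Posture at frame *n*
is therefore the vector of Euclidean distances between all marker pairs
(i < j), which is exactly invariant to rotation and translation of the
camera frame.  With 11 markers this gives 55 distances per frame.

Distances from all trials are reduced by PCA accumulated in streaming
fashion: exact counts, means and co-moments are merged batch by batch
(pairwise-update form), and the final covariance is eigendecomposed
once.  The streaming fit equals direct PCA on the concatenated data to
floating-point accuracy (tested at 1e-8).  Eigenvector signs follow a
fixed convention (largest-magnitude loading positive) and the pair
ordering is persisted with the model, so projections are bit-stable
across sessions.  The top 10 modes are kept; on synthetic trials they
capture ≳90% of distance variance, in line with what is expected for
real recordings.

## Posture dynamics (`dynamics`)

Each of the 10 mode projections is decomposed with a continuous Morlet
wavelet transform over 25 dyadically spaced frequencies from 0.25 to
20 Hz (geometric grid, endpoints exact), yielding a 250-dimensional
feature per frame.  Choices the transform fixes:

- **Mother wavelet** ω₀ = 5 Morlet, computed by frequency-domain
  convolution with reflective padding of twice the maximal wavelet
  support (avoids spurious boundary power in long trials).
- **Normalization** — amplitudes are scaled so a unit-amplitude sinusoid
  at a channel frequency yields peak response ≈ 1; power is the squared
  amplitude, so doubling an oscillation quadruples pre-log power.
- **Log floor** — features are log₁₀ power clamped at −3.  The floor is
  meaningful only at pixel amplitude scale; the pipeline therefore
  computes posture features on pixel coordinates.  (At metric scale
  virtually all power sits below 10⁻³ and classes collapse.)
- No per-frame renormalization of the wavelet vector is applied before
  clustering.

Per-class *fingerprints* recompute the same transform on raw egocentric
body-part coordinates (x and y of each marker as channels) and average
rows within each behavioral class, making the class spectra directly
interpretable (e.g. a 4 Hz peak in a paw channel during locomotion).

## Behavioral vocabulary (`clustering`)

Frame features are heavily unbalanced — steady locomotion would swamp a
direct clustering — so the vocabulary is built from an
importance-sampled training set:

1. Each movie is embedded independently to 2-D (t-SNE, perplexity 32,
   frames subsampled to ≤20,000), the embedding's kernel-density map is
   segmented by a watershed into density modes, and ~100 templates per
   movie are drawn round-robin across modes (rarest first), so every
   mode — and hence every rare behavior — contributes.
2. Pooled templates (~40,000 at full scale) are clustered by k-means,
   k = 100, k-means++ initialization, 10 restarts, best inertia kept.
3. Every frame of every movie is assigned the cluster of its exact
   nearest training template (Euclidean; ties resolve to the lowest
   template index), which is deterministic and cheap for new recordings.

The 100 fine clusters map onto eight coarse classes — Idle, Groom, Slow
Explore, Fast Explore, Rear, Climb, Amble and Turn, Locomotion — via a
user-editable JSON class map.  At full scale this is a manual curation
step; for synthetic data `class_map_from_truth` builds the map by
majority vote of generator ground truth within each cluster.

## Ethogram metrics (`metrics`)

*Usage* is the normalized label histogram of a trial (fine or coarse);
every row sums to one.  *Usage over time* computes the same histogram in
sliding windows (default 180 s window, 30 s step) per mouse, with the
group mean and a 95% percentile-bootstrap CI across mice (1000
resamples, seeded) — the bootstrap is across animals because that is the
variability a group curve should display.

*Spatial occupancy* divides the arena into corner squares of side
arena/4 at each corner and a concentric center square of side arena/2
(both configurable; the geometry is a package default, stated here
because no standard exists).  Corner time is the fraction of frames in
any corner zone; center crossings count sustained entries into the
center zone, with 0.5 s hysteresis to suppress boundary jitter
(unsmoothed membership overcounts crossings severely).

*Grooming modes* subdivide the Groom class into body, face/paw, small
quick movements, foot scratching, and mixture.  An episode is a maximal
run of one mode lasting ≥250 ms (20 frames at 80 Hz); shorter blips are
absorbed into the longer neighboring episode.  Both raw episode counts
and per-mouse normalized fractions are emitted, since "frequency" can
reasonably mean either.

*Habituation summaries* report per-class per-day group medians and
Cohen's d (pooled-SD form) between chosen day pairs.

## Gait analysis (`gait`)

Locomotion bouts are maximal runs of the Locomotion class strictly
longer than 500 ms.  Within a bout, each paw's body-frame
anterior-posterior trace is up-sampled ×100 (cubic), z-scored, and
stride starts are detected with `scipy.signal.find_peaks` under the
standard constraints: ≥80 ms separation and prominence ≥0.2 after
z-scoring.  Peaks are taken on the posterior-ward extreme (the paw's
most retracted point — the start of the swing), which fixes the θ = 0
convention; the sign is configurable since alternative conventions
exist.  Phase interpolates linearly from 0 to 2π between consecutive
stride starts; queries outside a limb's first/last cycle are undefined.

At every front-right (FR) cycle start the other limbs' phases are
sampled together with centroid speed, angular velocity and arena
position, producing one `StrideEvent` per FR cycle.  The
*diagonal-pair lag* of an event is the circular deviation of the FL/HR
pair's mean phase from perfect antiphase with the FR/HL pair; wrap-aware
circular means are used throughout.  Per-pair lags (FL and HR
separately) and the pooled value are all reported.

Strides classify as **trot** when both diagonal pairs are synchronous
within π/4, as **walk** when the four phases match the sequential
quarter-cycle footfall order FR, HL, FL, HR within π/4, and otherwise as
unclassified.  The walk-to-trot transition speed is the 0.5 crossing of
a logistic fit of P(trot | speed) over classified strides (undefined
with fewer than 10 classified strides or a single class).  The
classification rule and logistic estimator are package conventions: the
source gaits are described qualitatively in the literature without an
explicit algorithm, so the π/4 tolerance is exposed as configuration.

## Compositional statistics (`compstats`)

A mouse's time budget over the eight classes is a composition, so group
comparisons run in log-ratio coordinates:

- **Zero replacement** — multiplicative: zeros become δ (default half
  the smallest nonzero fraction observed) and nonzero parts rescale so
  rows still sum to one.
- **ILR** — y = V·clr(x) with V the orthonormal Helmert (sequential
  binary partition) basis; 8 classes give 7 coordinates; the inverse
  reproduces the composition to 1e-10.
- **Group test** — each ILR coordinate is rank-transformed across mice;
  Wilks' Λ = det(W)/det(T) is computed from within/total rank scatter,
  and the p-value is the permutation tail probability
  (1 + #{Λ_perm ≤ Λ_obs}) / (1 + n_perm), default 10,000 permutations,
  seeded.  Note the rank transform makes the statistic only
  approximately invariant to rotations of the coordinates (and class
  relabeling rotates ILR coordinates); test decisions, not exact
  p-values, are stable under relabeling.
- **Per-behavior effects** — the "log-ratio difference" of behavior *b*
  between groups is defined as clr_b of the group geometric-mean
  composition, contrasted between groups (equivalently the group
  difference of mean clr coordinates).  95% CIs come from a percentile
  bootstrap resampling mice within groups, N = 5000, seeded.  Resampling
  is over mice (not trials): the mouse is the experimental unit.

Calibration on logistic-normal synthetic compositions at n = 15
mice/group: type-I error of the permutation test at α = 0.05 falls in
[0.03, 0.07] over 500 null simulations, and CI coverage of the true clr
difference is ~93–95% over 300 replicates (percentile bootstrap
undercovers mildly at this n, as expected).

## Synthetic data (`synthetic`)

The generator emulates the study conditions — 80 Hz, 45.7 cm arena,
20-min-scale trials — with every stage's ground truth recorded.  Body
markers follow a rigid body-frame layout (tail base origin, snout
8 cm anterior) perturbed by state-specific dynamics:

- **idle** — static markers plus white Gaussian pixel noise
  (default 0.5 px SD on every marker).
- **groom** — forelimb/chin oscillations at mode-specific frequencies
  (body 3 Hz, face/paw 5.5 Hz, small-quick 8 Hz, foot-scratch 10 Hz on
  the hind paws), near-stationary centroid.
- **slow/fast explore** — head sweeps at 0.7 / 5 Hz with slow (0.02 /
  0.05 m/s) wandering.
- **rear / climb** — body-length contraction with elevated nose
  dynamics; climb adds 6 Hz limb movement.  These classes only need to
  be dynamically separable, not photorealistic.
- **amble/turn** — slow (0.07 m/s) turning with irregular, phase-jittered
  stepping.
- **locomotion** — per-bout `GaitParams`: speed, stride frequency
  (default 4 Hz), gait type, and diagonal-pair lag.  Limb trajectories
  are sinusoids in the body frame (amplitude 1 cm anterior-posterior)
  projected into the arena frame along a constant-speed steering path
  that avoids the walls; the tail tip oscillates laterally at the stride
  frequency.  Phase θ = 0 is the paw's posterior-most point.  Walk
  places the limbs at successive quarter cycles in footfall order FR,
  HL, FL, HR; trot synchronizes diagonal pairs with the FL/HR pair
  lagging antiphase by the programmed offset.

State sequences are either given explicitly or sampled from a
memoryless dwell model (states drawn independently with target
occupancy probabilities, geometric dwell times, default mean 2 s), the
simplest ethogram null.  Everything is driven by one seeded generator:
identical spec + seed reproduce trials bit-for-bit.

`render_video` adds an anisotropic Gaussian blob (elongated along the
heading) at the true centroid over a static textured background with
additive noise, for testing the tracking stage.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: pose-estimation failure modes (occlusion,
identity swaps, confidence-correlated error), non-sinusoidal limb
kinematics and stance/swing asymmetry, speed-dependent stride frequency,
postural drift within states, fur/lighting artifacts, and any
between-mouse kinematic individuality beyond the programmed parameters.
Parameter-recovery results on synthetic data demonstrate that the
estimators are unbiased under the generative model, not that the model
captures real mice.

## Problem sizes used by the test suite and acceptance script

Desk-scale protocols, chosen as the package's own defaults: gait
parameter recovery uses 20 trials per condition, each with 8 locomotion
bouts of 4 s at 0.2 m/s (≈2,200 stride events per condition; seeds
derived from the CLI seed).  The transition-speed protocol ramps 14
bout speeds over 0.02–0.4 m/s per trial, with per-trial jitter so the
pooled ramp covers the range densely.  The two-genotype end-to-end run
uses 6 mice per genotype, 240-s trials, k = 40 clusters and 100
templates per movie.  Statistical calibration uses 500 null simulations
(499 permutations each) and 300 coverage replicates (5,000 bootstrap
resamples each).

## Known limitations

- The fine-to-coarse class map is data-set-specific; the shipped
  automatic map is only valid for the synthetic vocabulary.
- The walk/trot classifier assumes exactly the two canonical gaits;
  gallop/bound and pathological coordination fall into "unclassified".
- Transition-speed estimates inherit the centroid speed estimator's
  small low bias (~1–2%, from smoothing over curved paths).
- The rank-based multivariate test trades exact rotation invariance for
  robustness; borderline p-values can shift under class relabeling.
- Tracking assumes a single animal brighter than the background.
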