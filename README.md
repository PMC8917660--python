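# mousefield

Deep behavioral phenotyping of open-field mouse recordings: from
pose-keypoint time series (optionally from raw video) to a complete,
quantitative description of what the animal did — a per-frame ethogram
over eight behavioral classes, habituation and spatial-occupancy
metrics, stride-level gait analysis, and compositional statistics of
behavioral time budgets.  A synthetic-data generator with full ground
truth makes every stage testable at desk scale.

It is aimed at behavioral neuroscientists running open-field assays
(e.g. phenotyping neurodevelopmental mouse models) who want more than
distance-traveled and center-time: the pipeline resolves grooming
modes, rearing, exploration styles, and limb-level gait coordination
from a single bottom-view recording.

## The method in brief

1. **Posture.** Each frame's posture is the vector of pairwise
   distances between tracked body markers,
   D_n(i,j) = sqrt((x_i − x_j)² + (y_i − y_j)²), i < j — exactly
   invariant to rotation and translation.  Streaming PCA over all
   recordings reduces the 55 distances (11 markers) to the top 10
   postural modes.
2. **Dynamics.** A Morlet wavelet transform over 25 dyadic frequencies
   (0.25–20 Hz) turns the 10 mode trajectories into a 250-dimensional
   log-power feature per frame (log₁₀, floored at −3).
3. **Vocabulary.** ~100 density-stratified template frames per movie
   are pooled and clustered by k-means (k = 100); every frame is then
   labeled by its nearest training template, and the 100 fine clusters
   map onto eight coarse classes (Idle, Groom, Slow Explore, Fast
   Explore, Rear, Climb, Amble and Turn, Locomotion).
4. **Readouts.** Usage histograms and 180-s sliding-window time series
   with bootstrap CIs; corner time and center crossings; grooming-mode
   decomposition; locomotion bouts (>500 ms) segmented into strides
   (×100 upsampling, peak detection at ≥80 ms separation and ≥0.2
   prominence after z-scoring), limb phases θ ∈ [0, 2π) referenced to
   the front-right paw, walk/trot classification and the walk-to-trot
   transition speed; and isometric-log-ratio compositional tests with
   bootstrapped per-behavior log-ratio differences (N = 5000).

See `docs/methods.md` for the full account of models, parameters and
design choices.

## Worked example

Generate a synthetic trot trial with a known diagonal-pair phase lag of
0.5 rad and re-estimate it with the full gait pipeline:

```python
import numpy as np
from mousefield.gait import analyze_gait, circular_mean, wrap_signed
from mousefield.synthetic import (
    GaitParams, SyntheticTrialSpec, generate_trial, truth_ethogram,
)

segments, f = [], 0
for _ in range(6):                       # six 4-s locomotion bouts
    segments.append(("locomotion", f, f + 320)); f += 320
    segments.append(("idle", f, f + 80)); f += 80

spec = SyntheticTrialSpec(
    duration_s=f / 80.0,
    state_sequence=segments,
    gait_params=GaitParams(speed=0.2, gait="trot",
                           diag_offset_rad=0.5, stride_freq_hz=4.0),
    noise_sd_px=0.5, seed=1,
)
trial = generate_trial(spec)
events, summary = analyze_gait(truth_ethogram(trial),
                               trial.keypoints.to_meters())
print(len(events), "stride events")
print("diagonal-pair lag:", round(summary.pooled_diag_lag, 3), "rad")
print("gaits:", summary.stride_gaits.value_counts().to_dict())
```

Output:

```
84 stride events
diagonal-pair lag: 0.486 rad
gaits: {'trot': 84}
```

84 front-right stride cycles were detected across the six bouts; the
re-estimated lag of the FL/HR diagonal pair behind the FR/HL pair
(0.486 rad) recovers the programmed 0.5 rad, and every stride is
classified as trot — diagonal pairs synchronous, as generated.

The same stages are available from the command line:

```bash
mousefield simulate --seed 1 --duration 60 -o trial.h5
mousefield posture fit trial.h5 -o pca.h5
mousefield posture project --keypoints trial.h5 --model pca.h5 -o proj.h5
mousefield wavelet --projection proj.h5 -o wav.h5
mousefield gait --labels eth.h5 --keypoints trial.h5 -o gait/
mousefield compstats --usage usage.csv --groups WT,KO -o report.json
```

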