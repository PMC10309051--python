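# Methods

## The detection model

Detection is split into *localisation* and *classification*. Localisation
is grayscale thresholding: a pixel is a candidate animal pixel iff its
intensity lies in the configured band `[threshold_low, threshold_high]`.
Candidates are grouped into 8-connected components; components smaller
than `min_blob_area` (default 4 px², a single-pixel-noise filter) are
dropped, and each surviving component contributes one keypoint at its
centroid (pixel-coordinate mean, sub-pixel, more stable than a
bounding-box centre). The band is two-sided so that both dark-on-light
and light-on-dark animals are supported.

The design contract of this stage is **recall bias**: the band should be
set generously so that every animal produces at least one in-band blob,
accepting spurious background blobs. A missed keypoint can never become
a detection, while a spurious keypoint is cheap — it is one extra patch
classification. Thresholding also bounds the per-frame classification
work by the number of blobs rather than the number of sliding-window
positions.

Classification runs a compact CNN on a `box_size × box_size` crop around
each keypoint (crops clamped inward at frame edges; training crops are
clamped identically so both stages see the same distribution). The
architecture is fixed: three convolutional layers of 64 filters (3×3,
stride 1, same padding), each followed by ReLU and 2×2 max-pooling, then
dense layers of 128 and 96 units (ReLU) and a 2-way softmax head. With
the default `box_size = 21` the convolutional stack leaves a 2×2×64 map
(1 280 features). Keeping the network this small is a deliberate trade:
it trains on a few thousand crops in minutes on one CPU and is less
prone to overfitting than deeper nets.

Training uses Adam (lr 1e-3, batch 32, 10 epochs by default) on
cross-entropy with per-class weights inversely proportional to class
frequency, so the recommended practice of collecting more background
("no") than animal ("yes") crops in cluttered habitats does not bias the
head. The network stack is implemented in NumPy inside the package
(`hetrack.nn`); every layer's analytic gradient is checked against
central finite differences in float64 in the test suite, and models
serialize to a single `.npz` with bit-identical predictions after
reload. Weight initialization, shuffling, and splits are all driven by
explicit seeds; single-threaded NumPy arithmetic makes training runs
reproducible bit for bit.

Accepted detections (`p_animal ≥ prob_threshold`, default 0.5) within
one frame are de-duplicated greedily: keep the highest-probability
detection (ties by smaller y, then x), discard all others within
`nms_radius` (default `box_size/2`), repeat. The operation is
idempotent. Suppression is centre-distance-based because detections are
points with a common box size; it runs after classification so that the
classifier, not blob geometry, decides which fragment of a
multiple-blob animal survives.

## Track linking

Each identity is a Kalman filter with state (x, y, vx, vy), transition
`x += vx` per frame (dt = 1), observation of position only, and
white-acceleration process noise `Q = q·[[¼,½],[½,1]] ⊗ I₂` (default
q = 1 px²/frame⁴; measurement noise r = 1 px²; initial position/velocity
variances 10 and 100 px²). Covariance updates use the Joseph form and
the gain uses a pseudo-inverse, so the filter remains correct in the
degenerate exact-measurement limit (r = 0), where the covariance
collapses to zero.

Per frame: predict all live tracks; build the Euclidean cost matrix
between predicted positions and detections; solve the assignment with
`scipy.optimize.linear_sum_assignment`; demote any matched pair with
distance above `max_gate` (default `2·box_size`). Matched tracks are
corrected and reset to zero misses; unmatched tracks coast on their
prediction and die after `max_skipped` (default 10) consecutive misses;
each unmatched detection founds a new track. A vanishing tie-break
perturbation (row-geometric weights on column indices) makes the
assignment deterministic among equal-cost optima without affecting the
optimum itself. Output rows are emitted only for matched frames — every
row in the track table is backed by a detection — and tracks with fewer
than `min_track_length` rows (default 3) are pruned as
single-flicker false positives.

No appearance features enter the cost, so identity switches between
individuals closer than roughly one body length are expected and are
measured rather than prevented (see the one-switch rule below).

## Evaluation

Detections are scored per frame by greedy one-to-one nearest-neighbour
matching within `match_radius` (default `box_size/2`; candidate pairs
ordered by distance, then detection index, so scoring is independent of
input order). TP% is the percentage of true individuals matched,
averaged over scored frames; FP% normalises unmatched detections by the
same per-frame truth count (so it can exceed 100 in pathological
cases); FN% = 100 − TP% identically. Frames are scored at a configurable
stride, defaulting to one frame per second. Greedy matching was chosen
over optimal assignment for scoring transparency; at the densities of
interest the difference is negligible.

Identity persistence follows the one-switch-allowed rule: per true
individual, tracker rows are matched to true positions frame by frame;
the id at the first matched frame is followed until it changes, giving
the first-id duration in seconds; the second id is then followed the
same way; a second change (including a revert to the first id) marks the
individual as lost. The summary reports median and mode of the
durations.

## The synthetic scene generator

The generator emulates the features that make field footage hard while
keeping ground truth exact:

- **Background**: coarse uniform value noise at spacing
  `background_patch_scale` (default 40 px; 80 px in the benchmark scene),
  bilinearly upsampled — spatially correlated clutter with intensities
  provably inside `background_intensity_range`. One heterogeneity knob,
  no overshoot, degenerate to a constant image as the patch scale grows.
- **Animals**: anti-aliased disks of radius `animal_radius` with one
  intensity per individual drawn from `animal_intensity_range`. Disks,
  not silhouettes: patch discrimination is preserved and the true centre
  is unambiguous.
- **Motion**: correlated random walk — constant step `speed` (2
  px/frame), heading perturbed by N(0, `turn_sd`) per frame, reflection
  at borders. A variant confines each animal to its own cell of a frame
  tiling, guaranteeing a minimum pairwise gap for tracking experiments.
- **Camera jitter**: rigid per-frame translation N(0, `jitter_sd`)
  applied to the whole frame *and* to the emitted ground truth, so
  metrics score the pipeline rather than the simulator. No
  rotation/scaling, matching mild wind shake rather than aggressive
  vibration.
- **Noise**: i.i.d. Gaussian pixel noise (default σ = 3 grey levels),
  drawn from a per-frame substream so any frame is independently
  reproducible.

With the `separable` flag (default), animal (30–80) and background
(120–230) intensity ranges are disjoint, so a valid threshold band
exists by construction (`scene.threshold_band()` widens the animal range
by 4 noise standard deviations). This is the premise of the localisation
recall guarantee exercised in the tests.

What the generator does **not** model: animal shape and posture, partial
occlusion beyond incidental disk overlap, illumination drift, rolling
shutter, motion blur, or background motion (wind-blown vegetation).
Passing the synthetic benchmarks therefore demonstrates the pipeline's
mechanics — region proposal recall, classifier convergence, assignment
and filter correctness, identity bookkeeping — not field-footage
accuracy, which depends on how well real crops separate in intensity and
appearance.

## Benchmark experiments and problem sizes

The two standard experiments (`hetrack.benchmarks`) run at sizes chosen
to exercise the full pipeline while completing in minutes on one CPU:

- **Detection benchmark**: 1280×720, 900 frames at 30 fps (30 s), five
  animals of radius 6 px (a ~35 px body at 4K scaled to 1280-wide),
  patch scale 80 px, jitter 1 px, noise 3; the classifier is trained for
  10 epochs on 2000+2000 crops of side 21 px extracted from a 450-frame
  clip with an independent seed; TP%/FP% scored at a 1 s stride with
  match radius 10.5 px. Frames are rendered and consumed as a stream, so
  memory stays flat.
- **Saturation benchmark**: the same 4000-crop dataset, split 80/20
  once; each of three seeds trains on a 20% subsample of the training
  split (640 crops) for 10 epochs and is scored on the common validation
  split — probing the data-scarcity regime where validation accuracy is
  expected to have saturated at the 90% level.

## Numerical and design choices

- `box_size` is normalised up to the next odd integer so every crop has
  an exact centre pixel; detections are reported at keypoint centroids,
  not crop centres.
- Colour frames are collapsed to luminance (0.2125 R + 0.7154 G +
  0.0721 B) before thresholding; crops are grayscale by default.
- Probability ties in duplicate suppression and equal-cost assignment
  optima are broken lexicographically (smaller y, then x; lower row,
  then column) so identical inputs give byte-identical outputs.
- Degenerate inputs are defined behaviour: empty keypoint lists, empty
  detection tables, zero-animal scenes, r = 0 or q = 0 filters, and
  threshold sweeps past 1.0 (precision reported as 1 by convention,
  recall 0) all have tested semantics.
- Config defaults that the problem does not pin down (prob_threshold
  0.5, nms_radius box/2, max_gate 2·box, max_skipped 10,
  min_track_length 3, q = r = 1) are stated in `Config` and surfaced in
  the YAML file; all are overridable.

## Known limitations

- Videos are PNG frame directories; compressed containers (MP4/AVI) are
  not read or written.
- The tracker has no appearance model and no re-identification: after
  `max_skipped` missed frames, or a crossing closer than the gate
  geometry can disambiguate, the individual returns with a new id.
- The CNN is CPU-oriented; there is no GPU path and no transfer
  learning from pre-trained backbones.
- Two-category classification only: one "animal" class against
  background.
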