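# Methods

## Problem setting and model

The package estimates, per tracked occupant of an office scene observed by
a radiometric thermal camera, the clothing insulation rate Icl and the
metabolic rate M — the two personal factors of heat-balance thermal-comfort
models. Both estimates are windowed statistics over a person's track, so
the pipeline is organized as tracking first, then two independent branches.

### Tracking-by-detection

Detections (box + six-way category + confidence) are associated to tracks
with minimum-cost assignment on `1 − IoU` between each track's
Kalman-predicted box and the frame's detections, gated at `iou_threshold`
(default 0.3). The Kalman filter is the standard SORT constant-velocity
model on (center-x, center-y, area, aspect), aspect held constant, with the
usual SORT noise settings; the filter, gate and noise values are
implementation choices — the tracking contract itself only fixes the
lifecycle rules:

* a track is *tentative* until associated in `n_init = 3` consecutive
  frames (a tentative track is dropped on its first miss, since the
  consecutive-association requirement can no longer be met);
* a confirmed track is deleted only after more than `max_age` frames
  without association (default 30 ≈ 1.4 s at 21 fps);
* only tracks that reach confirmation are emitted, but their full
  trajectory (including the pre-confirmation frames) is, so downstream
  windows and MOT evaluation see complete tracks.

An appearance-distance hook `(detection, track) → d ≥ 0` can be blended
into the association cost as a weighted sum; the default configuration
disables it (no deep appearance embedding is computed here). Assignment
ties at equal cost resolve to the lowest (track-id, detection-index) pair.

Per-track category voting returns the modal category over the last
`vote_window_frames` (default 63 ≈ 3 s; "a few seconds" is the requirement,
the exact span is configurable). Ties prefer the previous vote, then any
non-occluded candidate, then lexicographic order — occlusion is a statement
of ignorance, not evidence about the clothes.

CLEAR-MOT counting (`evaluate_tracking`) matches per frame at IoU ≥ 0.5,
keeping still-valid correspondences from previous frames before solving
the remainder with the Hungarian method; MOTA = 1 − (FN+FP+IDSW)/GT.

### Clothing insulation branch

Region rules, conditioned on the voted sleeve status:

| sleeve | skin region Rs | clothes region Rc |
|---|---|---|
| Short | nose + per-side (elbow+wrist)/2 | shoulders |
| Long | nose | shoulders + elbows |
| Occluded | nose | shoulders |

Keypoints below the 0.6 confidence threshold are discarded before the
rules apply. The occluded row is the conservative intersection of the
other two: with unknown sleeve status the forearms and elbows cannot be
assigned to either region safely. The nose contributes to Rs for every
sleeve status.

Each region point is rounded to the nearest pixel, clamped to the frame,
and sampled as a single pixel (a configurable odd patch mean exists but
defaults to 1×1, matching the view of the regions as sets of pixel
coordinates). Samples accumulate over the Icl window — default 5 minutes
(6300 frames at 21 fps), but any window ≥ 1 s is accepted and a trailing
short window is emitted flagged `partial` rather than suppressed, because
minute-scale windows already accumulate thousands of samples. Skeletons
are assigned to tracks by maximal overlap between the skeleton's bounding
hull and the track box in that frame.

T̄s and T̄c are arithmetic means of the accumulated skin and clothes
samples. T̄o is the unweighted mean of per-frame background means, where
background is every pixel outside every confirmed-track box. Then

    Icl = (T̄s − T̄c) / (0.155 · h · (T̄c − T̄o)),   h = 8.6 W/(m²·K),

with 0.155 m²·K/W the definition of one clo. Negative Icl (skin colder
than clothes) is returned as-is and should be read as a localization
diagnostic; clamping would hide the upstream error. When
|T̄c − T̄o| < 0.1 °C the estimate is refused as ill-conditioned instead of
returning an arbitrarily large number.

### Metabolic-rate branch

Windows are non-overlapping spans of `activity_window_frames` (210 = 10 s
at 21 fps). Posture is the modal posture of the window's category history
(mid-window posture changes are resolved by majority). Sitting windows get
the constant 72.5 W/m² — the midpoint of the narrow sitting office range
(58–87 W/m²), within which comfort indices are insensitive to M.

Standing windows are described by three features:

1. **center spread** — eigenvalue product (= determinant) of the 2×2
   sample covariance of the window's box centers, in px². The covariance
   uses the N−1 denominator; at N = 210 the alternative is numerically
   negligible, but fixing it makes results bit-reproducible. The
   eigenvalue product is the raw "ellipse area" statistic, with no π or
   confidence-interval scaling.
2. **scale spread** — the same statistic on the boxes' half-extents
   (w/2, h/2), i.e. the box's upper-right corner after translating it to
   the origin.
3. **flow intensity** — per frame, the mean over box pixels of
   |grayscale − 127| for the horizontal and vertical 8-bit flow images
   (127 encodes zero motion), combined as √(Ix² + Iy²) and averaged over
   the window. Pixel counts normalize out box size. The grayscale ↔
   displacement scale of the flow encoder is irrelevant because the
   classifier consumes the features only relatively.

A classifier maps the three features to probabilities (Pl, Pm, Ph) over
low/moderate/high intensity levels — always emitted in that order — and
M = Pl·75 + Pm·125 + Ph·174 W/m², a convex combination of the standing
range's lower boundary, middle value, and upper boundary. The default
model is a random forest with `max_depth = 2` and a caller-supplied seed;
k-NN (manhattan, distance weights, k = 13) and an RBF SVM (C = 50) are
available alternatives and are z-scored with training-set statistics (the
forest is scale-invariant and is not). Training is deterministic given the
seed and invariant to training-set order (examples are canonically sorted
before fitting); windows labelled `ambiguous` (mixed intensity) are
dropped.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| fps | 21 | frame/s | fixed so that a 10 s window is 210 frames; all window defaults derive from it |
| keypoint_conf_threshold | 0.6 | – | precision over recall: a misplaced keypoint corrupts a temperature sample, a missing one only shrinks it |
| icl_window_frames | 6300 (5 min) | frames | clothes change slowly; long windows filter keypoint noise |
| activity_window_frames | 210 (10 s) | frames | the time scale on which activity intensity is stable |
| vote_window_frames | 63 (3 s) | frames | long enough to ride out transient occlusions |
| h | 8.6 | W/(m²·K) | human surface heat-transfer coefficient |
| m_sitting | 72.5 | W/m² | midpoint of the sitting office range |
| m_levels | 75 / 125 / 174 | W/m² | standing range lower boundary / middle / upper boundary |
| icl_epsilon | 0.1 | °C | refuse Icl when T̄c ≈ T̄o |
| max_age / n_init / iou_threshold | 30 / 3 / 0.3 | frames / frames / – | DeepSort-style lifecycle; values are this package's defaults, all configurable |

## Synthetic scenes

The generator emulates the four input streams of a 384×288 radiometric
sensor at 21 fps with 0.08 °C quantization over a 22 °C office background
(temperatures configurable per scene). Persons are rendered as a torso
ellipse at the clothes temperature, a head disc at the skin temperature,
and forearm discs at skin temperature for short sleeves (clothes
temperature when covered), so the keypoint-derived sample sites carry the
scripted temperatures by construction. Sensor noise is Gaussian with
σ = 0.08 °C — comparable to the quantizer step, which both matches the
NETD class of such sensors and dithers the quantizer so accumulated region
means are unbiased; the residual mean error scales as σ/√n.

Five behaviour scripts (still_sit, still_stand, gesture_stand,
stretch_stand, walk) drive sinusoidal center and scale kinematics with
per-scene randomized amplitudes, frequencies and phases, and analytic flow
fields (center displacement × a fixed gain, plus a limb-motion term, mapped
to the 127-offset encoding inside the box; exact 127 outside). "Still"
scripts keep sub-pixel micro-motion rather than freezing entirely — a low
intensity level means very limited movement, not none. Detections and
keypoints come from ground truth and are corrupted by configurable jitter,
false-negative and false-positive rates; keypoints can be force-occluded
per person. The same seed reproduces a scene bit-identically.

`generate_activity_dataset` runs the feature extractor on single-person
standing scenes (still → low, gesture → moderate, stretch/walk alternating
→ high) and skips thermal rendering, which the features never consume; this
keeps classifier benchmarks at the study's sample sizes (315 training / 68
held-out windows) cheap.

**What passing tests do and do not show.** The generator's blobs have no
clothing texture, no emissivity or reflection physics, no limb
articulation, and its detector/keypoint noise is unstructured. Synthetic
recovery therefore validates the estimator arithmetic, the accumulation
windows, and the pipeline plumbing — not the behaviour of real detectors,
pose networks or flow estimators on thermal imagery, whose error modes
(misplaced noses on lowered heads, boxes on hot coffee mugs) are
structured. Classifier accuracies on the synthetic level distributions say
the features separate the scripted intensities, not that real office
behaviour is equally separable.

## Numerical choices and degenerate inputs

* Eigenvalues of the 2×2 covariance are clipped at 0 before the product;
  collinear center clusters legitimately give zero area.
* Probability vectors must sum to 1 within 1e−9; classifier outputs are
  renormalized after column reordering.
* Empty region sets refuse summarization with an error naming the empty
  region; windows that cannot be computed are recorded as skips with a
  reason, and a pipeline run over a too-short scene succeeds with
  "window not full" notes in its manifest.
* Boxes are half-open, 0-based; file formats carry 1-based frame numbers,
  converted at the boundary. Keypoints stay continuous until temperature
  sampling, where they are rounded once and clamped.

## Known limitations

* No radiometric calibration or emissivity correction — inputs are taken
  as already being surface temperatures in °C.
* The operative temperature proxy (mean background temperature) ignores
  radiant asymmetry and air velocity.
* Masked or bespectacled faces are not special-cased; the nose sample is
  taken regardless, which biases T̄s when the nose is covered.
* The mapping from level probabilities to M inherits the three fixed
  anchors; intensities outside the standing office range (running,
  lifting) are out of scope, as is any physiological M measurement.
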