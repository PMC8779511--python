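# thermocomfort

Contactless estimation of the two *personal* factors of indoor thermal
comfort — the clothing insulation rate **Icl** (clo) and the metabolic rate
**M** (W/m²) — for every person visible to a ceiling-mounted thermal camera.

Comfort indices such as Fanger's PMV need six inputs: four environmental
ones that fixed sensors measure easily (air temperature, mean radiant
temperature, humidity, air velocity) and two personal ones that are dynamic
and hard to obtain without instrumenting people. This package implements a
vision pipeline that derives both personal factors from thermal video
by-products — per-frame person detections with a six-way
clothing-status × posture category, body-keypoint skeletons, radiometric
frames in °C, and optional optical-flow fields — so that no worn sensor is
required and several occupants are handled at once.

## What it computes

**Tracking-by-detection.** Detections are associated frame-to-frame with a
SORT-style constant-velocity Kalman filter and Hungarian assignment on
1 − IoU (an appearance-distance hook can be blended in). Track lifecycle
follows the Tentative-Track / Maximum-Age rules: confirmation after three
consecutive associations, deletion after `max_age` unassociated frames.
Each track's six-way category (LongSit, ShortSit, OclSit, LongStand,
ShortStand, OclStand; CSV class codes 1–6 in this order) is majority-voted
over a sliding window.

**Clothing insulation.** With the voted sleeve status, the skin region Rs
(nose; plus per-side elbow–wrist midpoints for short sleeves) and the
clothing-covered region Rc (shoulders; plus elbows for long sleeves) are
located from keypoints above a 0.6 confidence threshold, accumulated over a
window, and averaged into the mean skin and clothes temperatures T̄s and
T̄c. With the operative temperature T̄o (mean background temperature) the
insulation follows from

```
Icl = (T̄s − T̄c) / (0.155 · h · (T̄c − T̄o))        [clo], h = 8.6 W/(m²·K)
```

**Metabolic rate.** Sitting occupants get the constant 72.5 W/m² (midpoint
of the narrow sitting range). For standing occupants, three
activity-intensity features over a 10 s (210-frame) window — box-center
spread, box-scale spread (each the eigenvalue product of a 2-D cluster
covariance, i.e. a fitted-ellipse area), and mean optical-flow intensity
inside the box — are classified into low/moderate/high levels by a random
forest, and the class probabilities are blended:

```
M = Pl·75 + Pm·125 + Ph·174                        [W/m²]
```

A fully-labelled synthetic scene generator (`thermocomfort.synthetic`)
emulates all four input streams with known ground truth, so the entire
pipeline is testable without a camera.

## Worked example

```
$ thermocomfort simulate --script scene.yaml --seed 7 --out-dir scene
$ thermocomfort track --detections scene/detections.csv --out tracks.csv
$ thermocomfort evaluate --gt scene/gt.csv --hyp tracks.csv
{"gt": 840, "fn": 0, "fp": 0, "idsw": 0, "mota_percent": 100.0}
$ thermocomfort fit-activity --n-per-level 30 --seed 7 --out clf.joblib
$ thermocomfort run --scene-dir scene --classifier clf.joblib --config cfg.yaml --seed 7 --out-dir out
$ cat out/icl.csv
track_id,window_start,window_end,n_skin,n_clothes,ts,tc,to,icl,partial
1,0,419,1260,840,34.4969,33.0022,25.0000,0.1401,0
2,0,419,420,1680,34.7080,33.3980,25.0000,0.1170,0
$ head -5 out/m.csv
track_id,window_start,posture,p_low,p_mod,p_high,m
1,0,Sit,,,,72.5
1,210,Sit,,,,72.5
2,0,Stand,0.0000,1.0000,0.0000,125.0
2,210,Stand,0.0000,1.0000,0.0000,125.0
```

The scene scripted two people: a sitting short-sleeved person with skin
34.5 °C and clothes 33.0 °C, and a standing long-sleeved person gesturing
(34.7 / 33.4 °C), over a 25.0 °C background. Track 1 recovers
T̄s = 34.497, T̄c = 33.002, T̄o = 25.000 — each within the sensor's 0.08 °C
quantization — giving Icl = 0.140 clo against a ground-truth value of
0.1407. The sitting person's M is the 72.5 W/m² constant; the standing
person's gesturing windows classify as moderate intensity, giving
125 W/m². Tracking on the noiseless detections is error-free
(MOTA = 100 %).

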