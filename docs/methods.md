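# Methods

## The interaction rule

The classifier encodes a simple behavioural assumption: personnel
interacting with the operating table stand still at it. Two binary
constraints are evaluated per pose detection and conjoined:

* **Stillness.** Keypoint displacement is the *net* Euclidean distance
  between a keypoint's position at frame `t` and at `t − f_motion`
  within the same tracklet — not a path sum over intermediate frames. A
  cumulative reading of "displacement over a span" is defensible, but the
  net distance is the plainer interpretation, is cheaper, and is what the
  threshold `tau_m` (px per `f_motion` frames) is calibrated against.
* **Position.** Point-in-polygon containment of keypoints in hand-drawn
  regions (one each for wrists, shoulders, head). Separate regions per
  subpose correct for the 2D projection of the 3D scene: a person's head
  and wrists occupy different image areas when they stand at the table.

Missing evidence always defaults toward stillness and away from position:
an undetected or low-confidence keypoint is assumed still (movement rule)
and is counted in no region (position rule). The two defaults pull the
interaction verdict in opposite directions, which is deliberate — heavy
dropout should not fabricate interaction, and brief occlusion should not
break an ongoing still phase. A displacement whose earlier endpoint is
missing (track younger than `f_motion`, or keypoint undetected back then)
is treated like an undetected keypoint: assumed still. The confidence gate
`gamma_m` reads the *current* frame's confidence only.

Thresholds compare strictly in the direction the rule states: displacement
exactly equal to `tau_m` is not "below" it; confidence exactly equal to a
gate counts as reliable. Containment is boundary-inclusive under the
even-odd rule, which stays well defined on accidentally self-intersecting
hand annotations (accepted with a logged warning).

### Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| `f_motion` | displacement span | 5 | frames |
| `M_subpose` | still subposes needed | 1 of {shoulders, head} | — |
| `M_keypoint` | still keypoints per subpose | 1 | — |
| `tau_m` | displacement threshold | 17.5 | px per `f_motion` frames |
| `gamma_m` | movement confidence gate | 0.3 | — |
| `P_subpose` | positioned subposes needed | 2 of {wrists, shoulders, head} | — |
| `P_keypoint` | in-region keypoints | 1 (wrists, shoulders), 2 (head) | — |
| `gamma_p` | position confidence gate | 0.3 (wrists, shoulders), 0.15 (head) | — |

Legs are excluded entirely (they are detected worst in OR footage) and arm
*movement* is ignored (arms legitimately move during table interaction);
wrist *position* still matters. `tau_m` is expressed in px per `f_motion`
frames with no framerate normalisation — under variable-framerate
recording the effective speed threshold varies accordingly, a known
limitation of the rule as specified.

## The metric F

`F = (1/|P|) Σ r(p)` over pose detections. Windows are half-open
`[start, start + length)`, starts at every multiple of `step` below the
recording length; the final windows may extend past the end and simply
hold fewer frames, so late activity stays visible. An empty window's value
is *undefined*, never 0 — `0/0` must not read as "no interaction"; the
same rule makes `fraction()` on an empty record set a raised error. For a
non-overlapping tiling (`step = length`), the pose-count-weighted mean of
window values equals the global F exactly; tests pin this identity.

Windows (and records) are assigned to the workflow phase containing their
*start* frame (frame, for records). Windows can straddle phase
boundaries; assignment by start is the simplest deterministic convention
and keeps stratification a partition.

The annotated patient-interaction fraction is computed on a per-frame,
per-person sampling grid: each annotated person contributes one sample per
frame, samples labelled `absence` are excluded from the denominator, and
the fraction is the share of remaining samples categorised as patient
interaction. The activity-label vocabulary is configuration
(`label → {patient_interaction, other, absence}`), shipped with a
documented example mapping, because real deployments annotate their own
activity lists.

## Tracker

Association is purely geometric (OR clothing defeats appearance
features): object keypoint similarity with the 17 standard COCO
per-keypoint falloff constants, object scale taken as the reference pose's
bounding-box area, averaged over keypoints detected in *both* poses
(empty intersection ⇒ similarity 0). Matching is two-stage greedy in the
BYTE style — detections scoring ≥ 0.6 first, then ≥ 0.1 against leftover
tracks — accepting pairs in descending-OKS order at threshold 0.3; ties
break by lower track id then detection index for determinism. Tracklets
that never span two consecutive frames are discarded, compensating for
single-frame false positives of low-threshold detectors.

Deliberate simplifications: no motion model, and no revival — a track
unmatched on a frame terminates. The metric F is designed to be robust to
exactly the identity fragmentation this can cause, so tracker simplicity
costs accuracy only through the displacement rule's need for `f_motion`
frames of continuity. The thresholds above are package defaults, all
config-overridable.

## Synthetic scenes

The generator emulates the statistical structure of OR recordings: staff
standing still at a table polygon, a circulator pacing, spectators parked
far away, with per-keypoint Gaussian jitter (default σ = 2 px), dropout
(default 0.05 per keypoint per frame), confidence drawn from a clipped
Normal(0.85, 0.1), and optional low-light intervals with elevated dropout
(0.6) and depressed confidence. Defaults model a 1920×1080 view at a
nominal 25 fps with actors of 120 px shoulder width; fixtures span
2000–6000 detections per actor, a desk-scale stand-in for multi-hour
recordings.

Actors are rigid upright stick figures: the classifier reads only
positions and confidences of head, shoulders and wrists, so gait
articulation would add realism the test surface cannot observe. What the
generator does **not** emulate — perspective foreshortening, partial
occlusion correlated between neighbouring keypoints, detector confusion
between crossing persons, variable framerate — bounds what passing tests
show: they validate the rule logic, metric algebra and noise robustness,
not detector-level performance on real video.

Ground truth is *operational*: the rule set run on the noise-free script.
Intent flags (`still_intervals`, `role_tag`) are retained as metadata so
intent-vs-rule divergence can be constructed (a person standing still at
the table while cleaning satisfies the rule without "interacting" in the
human sense). Random draws have fixed shapes per (actor, frame) regardless
of noise parameters, so raising the dropout probability under a fixed seed
removes keypoints monotonically — the property the dropout tests rely on.
The generator's design target, pinned in tests: zero noise recovers the
ground-truth F exactly; jitter ≤ 2 px with dropout ≤ 0.1 keeps the mean
absolute F error over 10 seeds within 0.02.

## Numerical and degenerate-input conventions

* Pixel coordinates, origin top-left, y downward; 0-based half-open frame
  intervals everywhere.
* Undetected keypoints are encoded as confidence 0 with undefined
  coordinates; a `(0, 0, 0)` COCO triplet parses as undetected.
* OKS with no commonly detected keypoints is 0; OKS of a reference pose
  with no detected keypoints at all is an error.
* CSV outputs round-trip exactly (`repr` floats); empty inputs produce
  header-only files.

## Known limitations

The rule measures a proxy — stillness in place — not intent; annotated
patient interaction is the complementary measurement, and the two can
legitimately diverge. Spectators and the patient contribute to F like
everyone else; filtering by role is left to the caller. Region annotations
are per-camera and per-room, and nothing corrects for framerate variation
or 3D perspective.
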