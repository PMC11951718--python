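# Methods

## The index

The Static Sciatic Index compares the resting toe spreads of the operated
hind paw against the contralateral control paw. With TS the Euclidean
distance between the centroids of the 1st and 5th toe pads and ITS the
distance between the 2nd and 4th, the toe-spread factors are

    TSF  = (TSo − TSc) / TSc,     ITSF = (ITSo − ITSc) / ITSc,

and the index is the fixed linear combination

    SSI = 108.44·TSF + 31.85·ITSF − 5.49.

The coefficients are published regression constants relating toe-spread
factors to functional state; `SSICoefficients` exposes them for research
into the model but they are not tuning parameters. Two consequences shape
the implementation: the index is invariant under uniform rescaling of all
pixel distances (so no spatial calibration is required anywhere), and at
equal spreads it equals the intercept −5.49 exactly (the healthy baseline
is not 0). All distances are kept in pixels throughout.

## Measurement pipeline

Each frame passes through five stages, all deterministic:

1. **ROI masking.** A four-vertex polygon (from the crop configuration)
   confines analysis to the box floor. Pixels outside are zeroed; the frame
   is masked, not cropped, so coordinates stay in the original frame system.
2. **Segmentation (classical backend).** Grayscale conversion (channel
   mean); Otsu's global threshold computed from ROI pixels only, which makes
   detection invariant to uniform brightness shifts; morphological opening
   with a radius-1 disk; 8-connected labeling. The largest component is the
   body (frames whose largest component is below a body-size floor are
   rejected `NO_ANIMAL`). Components with area in [30, 2000] px² (limits
   defined at 1920×1080 and scaled by frame area) and solidity ≥ 0.7 become
   digit candidates, at most 10, largest first. A component larger than the
   digit window that contains ≥ 2 intensity peaks (smoothed, σ = 1) is split
   by nearest-peak assignment of its pixels — digit pads merged into one paw
   blob are thereby recovered. Centroids are intensity-weighted and
   sub-pixel. The backend sits behind a contract (frame → `FrameDetection`)
   so a learned segmenter trained on real footage can be plugged in without
   touching the rest of the pipeline.
3. **Body geometry.** The body axis is the major principal axis of the body
   mask's second-order central moments; its length scale is the
   moment-equivalent ellipse major axis (4·√λ₁). Masks with eigenvalue
   ratio < 1.05 are flagged degenerate. The heading along the axis is fixed
   by the rule that hind paws trail the body: the mean digit centroid must
   project caudally of the body centroid. Frames where that projection is
   within 2 px of the centroid are flagged ambiguous and dropped rather than
   guessed — the index is measured on stationary postures, where the rule is
   reliable, and guessing a heading silently swaps operated and control.
4. **Paw assignment and measurement.** Candidates are split left/right by
   the sign of the 2-D cross product of the heading with the centroid-to-
   candidate vector; filming the ventral side from below with y pointing
   down makes the positive sign the animal's left, and a `flip_lr` switch
   covers mirrored optical paths. A side with more than five candidates
   keeps the five largest (small noise blobs lose); fewer than five marks
   the frame `MISSING_DIGITS` (`PAW_NOT_VISIBLE` when empty). Within a paw,
   digits are indexed 1→5 medial→lateral by distance from the body-axis
   line, ties broken by distance to the body centroid so the ordering is
   total. TS = |d₁−d₅|, ITS = |d₂−d₄|. The declared operated side maps the
   two paws onto (o, c) roles.
5. **Frame QC.** A frame is accepted only with a body, a resolved heading,
   five digits per paw, ITS < TS on both paws, and TS within a configurable
   band of [0.05, 0.6] × body-axis length. The band is deliberately loose —
   its job is to catch gross segmentation artifacts (e.g. a reflection
   merged into a paw), not to constrain biology.

### Outlier rejection and aggregation

Per-video SSI values pass two flagging stages: an absolute plausibility
window, default [−150, +50] (the physiological range of roughly −80 to +10
with generous margin on both sides), then Tukey fences at 1.5·IQR computed
from the surviving values with linearly interpolated quartiles — the same
convention under which boxplot crosses mark outliers. Both stages are
configurable; sequences shorter than 4 are never flagged. The video summary
(mean, sample SD with n−1 denominator, median, quartiles) is computed over
a seeded uniform subsample of up to 1,000 retained records, reflecting
reporting from a random sample of measurements while keeping results
bit-reproducible for a given seed. A video passes QC only if more than 50
frames yielded valid measurements; retention (labeled/total) is reported
but not enforced, because how often an animal presents both paws is
behavior, not a tool property.

## Synthetic scenes

The renderer emulates what the camera sees through the box floor: a dark
noisy background (mean 30, Gaussian sd 6 on an 8-bit scale), a bright
elliptical body (intensity 200, semi-axes 260×85 px at 1080p — a rat
occupying about half the frame width), and per paw five Gaussian digit pads
(peak 235, σ = 3 px, i.e. ≈ 9 px pad diameter after thresholding) placed
caudally and laterally of the body centroid. Digit centers realize the
requested TS and ITS exactly: five points equally spaced in angle on a
circular arc with chord(1,5) = TS and chord(2,4) = ITS, degenerating to a
collinear layout when TS ≥ 2·ITS (the chord constraints then admit no
finite circle). Optional artifacts reproduce the common acquisition
problems: a bright reflective patch, and a paw out of view. Per-frame digit
jitter (isotropic Gaussian) emulates the small posture fluctuations of a
resting animal; ground truth records the jittered centers, while the
expected SSI is defined by the requested spreads. All randomness derives
from (scene seed, frame index), so any frame is reproducible in isolation.

What the scenes do **not** emulate: fur texture and limb self-occlusion,
non-uniform illumination, motion blur, walking postures, and digit pads
that genuinely touch (the paper-and-pencil geometry keeps pads separable
down to gaps of ~5 px; the default geometry stays resolvable at frame
heights ≥ 540 px). Passing on synthetic scenes therefore demonstrates the
geometry, indexing, QC and statistics are correct given competent
segmentation — it does not certify the classical backend on real footage,
where a learned backend may be needed.

## Problem sizes and numerical choices

The end-to-end checks run seeded 1,000-frame videos at 1920×1080 (the
acceptance script's three scenarios complete in a few minutes on one CPU);
unit and property tests use 960×540 scenes, the smallest scale at which the
proportionally scaled digit pads remain separable. Quartiles use linear
interpolation everywhere (fence placement depends on this, so it is pinned
and shared between the outlier stage and the summary). Measurement tables
serialize floats at 6 decimal places; CSV mirrors are byte-stable across
reruns with the same seed and configuration. Degenerate inputs are verdicts,
not crashes: empty masks, blank frames, all-on-one-side candidate sets and
too-short videos each map to a named reason code.

## Video containers

Lossless multi-page TIFF is the primary container for both the renderer and
the reader: quantitative tests must not depend on codec loss, and TIFF
round-trips bit-exactly. MP4 reading and near-lossless writing (x264,
crf 0) are implemented behind the same interfaces via imageio's ffmpeg
plugin and activate when `imageio-ffmpeg` is installed; an unreadable file
yields a per-file error and the batch continues.

## Known limitations

- The classical backend assumes a light-coated animal on a darker,
  homogeneous background (or the exact inverse, via `invert`); dark-on-dark
  footage needs a learned backend through the segmentation contract.
- Heading resolution relies on hind paws trailing the body centroid;
  curled-up postures can defeat it and are dropped as ambiguous.
- Digits of one paw must not merge with the body or with the other paw's
  digits in the thresholded image; at very small paw scales (< ~5 px
  between adjacent pads) the peak-splitting stage becomes the only line of
  defense and its accuracy degrades.
- The operated side is a per-experiment declaration; the tool cannot detect
  which paw was operated.
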