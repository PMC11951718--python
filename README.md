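# ssipaw

Automated **Static Sciatic Index (SSI)** measurement from under-box videos of
rats, for peripheral-nerve-regeneration studies.

In the rat sciatic-nerve crush model, functional recovery is tracked by how
far the animal can spread the toes of the injured hind paw. The SSI captures
this from the resting animal, filmed from below through a transparent box
floor: for the operated (o) and contralateral control (c) paws one measures
the toe spread **TS** (distance between the 1st and 5th toe) and the
intermediate toe spread **ITS** (2nd to 4th toe), forms the factors

```
TSF = (TSo − TSc) / TSc          ITSF = (ITSo − ITSc) / ITSc
```

and combines them linearly:

```
SSI = 108.44·TSF + 31.85·ITSF − 5.49
```

SSI ≈ 0 is a healthy animal; values near −80 indicate complete loss of toe
spreading after a crush injury. Because both factors are ratios of pixel
distances, no physical calibration is needed and the index is independent of
camera and mounting distance.

Measuring TS and ITS by hand on a handful of frames per video is slow and
noisy. `ssipaw` automates it over every frame of a video: it segments the
bright body and digit pads, reconstructs the animal's body axis and heading,
splits the digits into left and right paws, orders them medial→lateral,
measures both spreads, computes a per-frame SSI, rejects outliers
(physiological plausibility window, then Tukey's 1.5·IQR fences), and exports
one spreadsheet per video. Every stage is also exercised against a synthetic
scene renderer with exact ground truth, so the whole chain is testable
without animal footage.

## Quick start

From Python (see `examples/` for narrated scripts of each capability):

```python
from ssipaw import PipelineConfig, RoiPolygon, SceneSpec, process_frames
from ssipaw.scenes import iter_frames

spec = SceneSpec(ts_o=60, ts_c=80, its_o=30, its_c=40, jitter_sd=1.0, seed=42)
frames = ((i, img) for i, img, _ in iter_frames(spec, 200))
result = process_frames(frames, RoiPolygon.full_frame(1920, 1080), PipelineConfig())
print(result.summary.mean_ssi, result.summary.sd_ssi)
```

From the shell, the batch workflow mirrors acquisition practice — declare the
crop, then process a folder:

```
ssipaw simulate --out clips/rat1_day7.tif --n-frames 100 --seed 42
ssipaw crop --video rat1_day7.tif --points 0,0,1919,0,1919,1079,0,1079 \
        --operated-side left --crop-config crop.ini
ssipaw process --input clips --crop-config crop.ini
```

`process` writes, per video, `Output/<name>.xlsx` (sheets `measurements` with
frame-wise TSo, ITSo, TSc, ITSc, TSF, ITSF, SSI and outlier flags, and
`summary`) plus a CSV mirror and a `run_manifest.json` with the configuration
hash and seed.

### Worked example

`python examples/03_full_pipeline.py` renders two 60-frame synthetic videos —
a healthy baseline (operated spreads equal control) and an injured animal
(operated spreads at 75 % of control) — and processes them as a batch. It
prints:

```
rat1_day0.tif:
  labeled 60/60 frames, QC pass
  mean SSI    -5.57   (ground truth    -5.49)
rat1_day7.tif:
  labeled 59/60 frames, QC pass
  mean SSI   -39.95   (ground truth   -40.56)
```

The baseline recovers the intercept −5.49 (both factors zero) to within a
tenth of an SSI unit; the injured video recovers the ground-truth index
−40.56 implied by its spreads (TSF = ITSF = −0.25) to within a unit, from
sub-pixel digit centroids. A video only passes QC when more than 50 frames
yield valid measurements.

## Scope and limitations

The segmentation backend shipped here is the fully specified classical one
(Otsu threshold within the ROI, morphological opening, connected components,
area/solidity filters, intensity-peak splitting of merged paws); it assumes a
light-coated animal brighter than a homogeneous dark background (an `invert`
flag handles the reverse). The backend contract (`frame → FrameDetection`)
is the integration point for learned segmenters trained on real footage.
Walking-track indices (SFI) are out of scope. See `docs/methods.md` for the
model, parameter and design details.
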