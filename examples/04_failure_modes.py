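"""Acquisition problems and how QC responds to them.

Renders three problematic scenes — a reflective patch in the background, a
paw out of view, and a too-short recording — and shows the reason codes the
pipeline reports instead of silently producing bad measurements.
"""

from ssipaw import PipelineConfig, RoiPolygon, SceneSpec, process_frames
from ssipaw.scenes import iter_frames

SIZE = (960, 540)
config = PipelineConfig()


def run(spec, n_frames, roi=None):
    roi = roi or RoiPolygon.full_frame(*SIZE)
    frames = ((i, img) for i, img, _ in iter_frames(spec, n_frames))
    return process_frames(frames, roi, config)


# 1. Reflective patch inside the analyzed area: the bright artifact swamps
#    the detector unless it is cropped away with the ROI polygon.
shiny = SceneSpec.default(frame_size=SIZE, jitter_sd=0.5, seed=5,
                          reflective_patch=(30, 30, 50, 50, 245.0))
with_patch = run(shiny, 10)
roi = RoiPolygon(((120.0, 0.0), (959.0, 0.0), (959.0, 539.0), (120.0, 539.0)))
cropped = run(shiny, 10, roi)
print("reflective patch, full frame: ", with_patch.reason_counts)
print("reflective patch, ROI-cropped:", cropped.reason_counts)

# 2. One paw out of view for the whole video.
occluded = SceneSpec.default(frame_size=SIZE, jitter_sd=0.5, seed=5,
                             occlude_paw="left")
print("left paw occluded:            ", run(occluded, 10).reason_counts)

# 3. A clean but too-short recording: every frame labels, yet the video
#    fails QC because fewer than the required >50 frames were measured.
short = run(SceneSpec.default(frame_size=SIZE, jitter_sd=0.5, seed=5), 30)
print(f"short video: {short.summary.n_frames_labeled} labeled frames, "
      f"qc_pass={short.summary.qc_pass}, reasons={short.summary.qc_reasons}")
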