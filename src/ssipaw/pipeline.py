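"""End-to-end orchestration: frames -> detections -> paws -> SSI -> tables.

``process_frames`` is the core driver over any iterable of frames (decoded
video, in-memory synthetic stream, ...); ``process_video`` adds file
decoding and ``process_folder`` reproduces the batch workflow: crop every
video per the crop configuration, label it in the background, and write one
spreadsheet per video into an ``Output`` folder together with a run
manifest.  Per-video failures are isolated so one corrupt file does not
abort the batch.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import geometry, qc, ssi, video_io
from .geometry import assign_roles, body_axis, measure_paw, resolve_heading, split_paws
from .qc import FrameVerdict, QCParams, validate_frame, validate_video
from .segmentation import RoiPolygon, SegmentationParams, segment_frame
from .ssi import (DEFAULT_SSI_RANGE, SpreadPair, SSICoefficients, SSIRecord,
                  VideoSummary, flag_outliers, record_from_spreads, summarize_video)
from .video_io import CropConfig, VideoReadError, read_frames, write_results

__all__ = ["PipelineConfig", "PipelineResult", "process_frames", "process_video",
           "process_folder"]

logger = logging.getLogger(__name__)

VIDEO_SUFFIXES = (".mp4", ".tif", ".tiff")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs beyond the frames themselves."""

    operated_side: str = "left"
    flip_lr: bool = False
    stride: int = 1
    heading_tolerance: float = 2.0  # px; below this the heading is ambiguous
    segmentation: SegmentationParams = SegmentationParams()
    qc: QCParams = QCParams()
    coefficients: SSICoefficients = SSICoefficients()
    ssi_range: tuple[float, float] = DEFAULT_SSI_RANGE
    iqr_factor: float = 1.5
    sample_size: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Per-video output: flagged records, per-frame verdicts and summary."""

    records: list[SSIRecord]
    verdicts: list[FrameVerdict]
    summary: VideoSummary

    @property
    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.verdicts:
            counts[v.reason] = counts.get(v.reason, 0) + 1
        return counts


def _measure_frame(frame_index: int, frame: np.ndarray, roi: RoiPolygon,
                   config: PipelineConfig) -> tuple[FrameVerdict, SpreadPair | None]:
    """Run one frame through segmentation, geometry and frame QC."""
    detection = segment_frame(frame, roi, config.segmentation, frame_index)
    if detection.reject_reason is not None:
        return validate_frame(detection), None

    axis = body_axis(detection.body_mask)
    centroids = detection.centroids
    if len(centroids) == 0:
        verdict = FrameVerdict(frame_index=frame_index, accepted=False,
                               reason=qc.PAW_NOT_VISIBLE)
        return verdict, None
    axis = resolve_heading(axis, centroids, tolerance=config.heading_tolerance)
    if axis.heading_sign is None:
        return validate_frame(detection, axis), None

    split = split_paws(detection.digit_candidates, axis, flip_lr=config.flip_lr)
    left = measure_paw(split.left, axis, "left") if split.left_status == geometry.OK else None
    right = measure_paw(split.right, axis, "right") if split.right_status == geometry.OK else None
    verdict = validate_frame(detection, axis, left, right,
                             paw_status=(split.left_status, split.right_status),
                             params=config.qc)
    if not verdict.accepted:
        return verdict, None

    operated, control = assign_roles(left, right, config.operated_side)
    spreads = SpreadPair(ts_o=operated.ts, ts_c=control.ts,
                         its_o=operated.its, its_c=control.its)
    return verdict, spreads


def process_frames(frames, roi: RoiPolygon,
                   config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Measure an iterable of ``(frame_index, frame)`` pairs.

    Produces one SSI record per accepted frame, flags outliers over the whole
    video (absolute plausibility window, then Tukey fences), and aggregates a
    seeded-subsample summary with the video-level QC verdict.
    """
    verdicts: list[FrameVerdict] = []
    records: list[SSIRecord] = []
    n_seen = 0
    for frame_index, frame in frames:
        n_seen += 1
        verdict, spreads = _measure_frame(frame_index, frame, roi, config)
        verdicts.append(verdict)
        if spreads is not None:
            records.append(record_from_spreads(frame_index, spreads, config.coefficients))

    if records:
        flags = flag_outliers([r.ssi for r in records],
                              absolute_range=config.ssi_range,
                              iqr_factor=config.iqr_factor)
        records = [r.with_outlier(f) for r, f in zip(records, flags)]
    summary = summarize_video(records, sample_size=config.sample_size,
                              seed=config.seed, n_frames_total=n_seen)
    summary = validate_video(summary)
    return PipelineResult(records=records, verdicts=verdicts, summary=summary)


def process_video(path: str | Path, roi: RoiPolygon,
                  config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Decode one video file and measure it."""
    return process_frames(read_frames(path, stride=config.stride), roi, config)


def _first_frame_shape(path: Path) -> tuple[int, int]:
    for _, frame in read_frames(path, stride=1):
        return frame.shape[:2]
    raise VideoReadError(f"{path} contains no frames")


def _manifest(config: PipelineConfig, statuses: dict) -> dict:
    import scipy
    import skimage

    from . import __version__

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    return {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "ssipaw": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
        },
        "videos": statuses,
    }


def process_folder(input_dir: str | Path, crop_config: CropConfig,
                   output_dir: str | Path | None = None,
                   config: PipelineConfig = PipelineConfig()) -> dict:
    """Batch-process every video in a folder.

    Finds ``.mp4``/``.tif`` files in ``input_dir`` (sorted by name), applies
    each video's ROI and operated-side declaration from the crop config, and
    writes per-video XLSX/CSV results into ``output_dir`` (default: an
    ``Output`` folder inside ``input_dir``) plus a ``run_manifest.json``
    recording the configuration hash, seed and library versions.

    Returns the manifest dict; ``manifest["videos"]`` maps each file to its
    status (``ok`` with retention statistics, or ``error`` with the message).
    Failures are isolated per video.
    """
    input_dir = Path(input_dir)
    out_dir = Path(output_dir) if output_dir is not None else input_dir / "Output"
    videos = sorted(p for p in input_dir.iterdir()
                    if p.suffix.lower() in VIDEO_SUFFIXES and p.is_file())
    if not videos:
        raise FileNotFoundError(f"no video files ({'/'.join(VIDEO_SUFFIXES)}) in {input_dir}")

    statuses: dict[str, dict] = {}
    for path in videos:
        t0 = time.perf_counter()
        try:
            shape = _first_frame_shape(path)
            roi = crop_config.roi_for(path.name, shape)
            side = crop_config.operated_side_for(path.name, fallback=config.operated_side)
            video_config = dataclasses.replace(config, operated_side=side)
            result = process_video(path, roi, video_config)
            files = write_results(result.records, result.summary, out_dir, path.name)
            statuses[path.name] = {
                "status": "ok",
                "operated_side": side,
                "n_frames_total": result.summary.n_frames_total,
                "n_frames_labeled": result.summary.n_frames_labeled,
                "n_frames_retained": result.summary.n_frames_retained,
                "retention_fraction": round(result.summary.retention_fraction, 4),
                "qc_pass": result.summary.qc_pass,
                "mean_ssi": result.summary.mean_ssi,
                "outputs": [str(files["xlsx"]), str(files["csv"])],
                "seconds": round(time.perf_counter() - t0, 2),
            }
            logger.info("%s: %d/%d frames labeled (%.0f%%), mean SSI %.2f",
                        path.name, result.summary.n_frames_labeled,
                        result.summary.n_frames_total,
                        100 * result.summary.retention_fraction,
                        result.summary.mean_ssi)
        except (VideoReadError, KeyError, ValueError, OSError) as exc:
            statuses[path.name] = {"status": "error", "message": str(exc)}
            logger.error("%s: %s", path.name, exc)

    manifest = _manifest(config, statuses)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
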