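"""Frame- and video-level quality control.

A frame yields a valid measurement only when the animal is present, its
heading could be resolved, both paws contribute exactly five digits, and the
measured geometry is plausible.  Verdicts are pure functions of their inputs
(no randomness, no state), so re-running QC on the same detections gives
identical results.

At the video level the only hard rule is the acceptability floor: a video
must yield more than 50 labeled frames, otherwise its summary statistics are
not considered reliable.  Retention (labeled / total frames) is reported but
not enforced — how often an animal presents both paws cleanly is behavior,
not a tool property.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import geometry
from .geometry import BodyAxis, PawMeasurement
from .segmentation import NO_ANIMAL, FrameDetection
from .ssi import MIN_LABELED_FRAMES, NO_FRAMES, TOO_FEW_FRAMES, VideoSummary

__all__ = ["FrameVerdict", "QCParams", "validate_frame", "validate_video", "REASONS"]

OK = "OK"
MISSING_DIGITS = geometry.MISSING_DIGITS
PAW_NOT_VISIBLE = geometry.PAW_NOT_VISIBLE
AMBIGUOUS_HEADING = "AMBIGUOUS_HEADING"
IMPLAUSIBLE_GEOMETRY = "IMPLAUSIBLE_GEOMETRY"

REASONS = (OK, NO_ANIMAL, MISSING_DIGITS, PAW_NOT_VISIBLE,
           AMBIGUOUS_HEADING, IMPLAUSIBLE_GEOMETRY)


@dataclass(frozen=True)
class FrameVerdict:
    """Accept/reject decision for one frame with a single reason code."""

    frame_index: int
    accepted: bool
    reason: str

    def __post_init__(self) -> None:
        if self.accepted != (self.reason == OK):
            raise ValueError("accepted must hold exactly when reason is OK")


@dataclass(frozen=True)
class QCParams:
    """Plausibility limits for frame geometry.

    ``ts_body_ratio_range`` bounds the toe spread relative to the body
    major-axis length; it catches segmentation artifacts such as reflections
    merged into a paw.  The default band is deliberately loose: a rat's toe
    spread is a modest fraction of its body length.
    """

    ts_body_ratio_range: tuple[float, float] = (0.05, 0.6)


def validate_frame(detection: FrameDetection,
                   axis: BodyAxis | None = None,
                   left: PawMeasurement | None = None,
                   right: PawMeasurement | None = None,
                   paw_status: tuple[str, str] = (geometry.OK, geometry.OK),
                   params: QCParams = QCParams()) -> FrameVerdict:
    """Judge one frame's detection and paw measurements.

    Reason precedence: NO_ANIMAL, AMBIGUOUS_HEADING, PAW_NOT_VISIBLE,
    MISSING_DIGITS, IMPLAUSIBLE_GEOMETRY, OK.  Geometry is implausible when
    either paw has ITS >= TS (intermediate digits cannot spread wider than
    the outer ones; coincident digits fail here too) or a TS outside the
    configured band relative to body length.
    """
    idx = detection.frame_index

    def reject(reason: str) -> FrameVerdict:
        return FrameVerdict(frame_index=idx, accepted=False, reason=reason)

    if detection.reject_reason is not None:
        return reject(detection.reject_reason)
    if axis is None or axis.ambiguous or axis.heading_sign is None:
        return reject(AMBIGUOUS_HEADING)
    statuses = set(paw_status)
    if PAW_NOT_VISIBLE in statuses:
        return reject(PAW_NOT_VISIBLE)
    if MISSING_DIGITS in statuses:
        return reject(MISSING_DIGITS)
    if left is None or right is None:
        return reject(PAW_NOT_VISIBLE)
    lo, hi = params.ts_body_ratio_range
    for paw in (left, right):
        if paw.its >= paw.ts:
            return reject(IMPLAUSIBLE_GEOMETRY)
        if not (lo * axis.axis_length <= paw.ts <= hi * axis.axis_length):
            return reject(IMPLAUSIBLE_GEOMETRY)
    return FrameVerdict(frame_index=idx, accepted=True, reason=OK)


def validate_video(summary: VideoSummary) -> VideoSummary:
    """Re-derive the video-level QC verdict from the summary's frame counts.

    ``qc_pass`` requires strictly more than 50 labeled frames and at least
    one retained record; reasons TOO_FEW_FRAMES / NO_FRAMES are set
    accordingly.  Idempotent.
    """
    reasons = []
    if summary.n_frames_labeled <= MIN_LABELED_FRAMES:
        reasons.append(TOO_FEW_FRAMES)
    if summary.n_frames_retained == 0:
        reasons.append(NO_FRAMES)
    summary.qc_reasons = reasons
    summary.qc_pass = not reasons
    return summary
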