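"""Synthetic under-box scenes with exact ground truth.

Renders parameterized frames emulating the view a camera sees from below a
transparent box holding a light-coated rat: a bright elliptical body blob,
two hind paws of five bright digit blobs each, over a dark noisy background.
Optional artifacts reproduce common acquisition problems — a reflective patch
in the background and a paw out of view.

Digit placement is driven directly by the requested toe spread (TS, the
digit-1 to digit-5 distance) and intermediate toe spread (ITS, digit 2 to
digit 4): the five digit centers sit on a circular arc whose chords realize
both distances exactly, with digits equally spaced in arc angle.  When
TS >= 2*ITS the arc degenerates to a straight line and the digits are placed
collinearly (endpoints TS apart, digits 2/4 ITS apart).  The ground truth
returned with every frame records the digit centers actually drawn (after
per-frame jitter), the requested spreads and the SSI they imply, so every
downstream stage can be scored against exact answers.

All randomness (background noise, centroid jitter) is drawn from a generator
seeded by ``(spec.seed, frame_index)``: rendering a frame is a pure function
of the spec and the frame index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .ssi import SpreadPair, record_from_spreads

__all__ = ["SceneSpec", "GroundTruth", "digit_arc_offsets", "render_frame",
           "iter_frames", "render_video"]

_REFERENCE_HEIGHT = 1080.0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene; immutable and hashable.

    Geometry defaults are sized for 1920x1080 frames with the camera close to
    the box floor, roughly matching a 4K camera downscaled to full HD: the
    body spans about half the frame width and a healthy toe spread of 80 px
    is about 4% of the frame width.  Use :meth:`default` to get the same
    proportions at other frame sizes.

    Intensities are 8-bit luminance levels: dark background (~30) under a
    bright white-coated body (~200) with digit pads pressed to the floor
    appearing brighter still (~235).  ``noise_sd`` is Gaussian sensor noise.
    """

    frame_size: tuple[int, int] = (1920, 1080)  # (width, height)
    body_center: tuple[float, float] | None = None  # defaults to frame center
    body_semi_axes: tuple[float, float] = (260.0, 85.0)
    heading_deg: float = 0.0  # angle of the head direction, x-axis = 0, y down
    ts_o: float = 60.0
    ts_c: float = 80.0
    its_o: float = 30.0
    its_c: float = 40.0
    operated_side: str = "left"
    paw_offset_caudal: float = 150.0
    paw_offset_lateral: float = 160.0
    digit_sigma: float = 3.0
    digit_peak: float = 235.0
    body_intensity: float = 200.0
    background: float = 30.0
    noise_sd: float = 6.0
    reflective_patch: tuple[int, int, int, int, float] | None = None  # x, y, w, h, level
    occlude_paw: str | None = None
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.its_o < self.ts_o and self.its_c < self.ts_c):
            raise ValueError("intermediate toe spread must be smaller than toe spread")
        if self.operated_side not in ("left", "right"):
            raise ValueError(f"operated_side must be 'left' or 'right', got {self.operated_side!r}")
        if self.occlude_paw not in (None, "left", "right"):
            raise ValueError(f"occlude_paw must be None, 'left' or 'right', got {self.occlude_paw!r}")

    @classmethod
    def default(cls, frame_size: tuple[int, int] = (1920, 1080), **overrides) -> "SceneSpec":
        """A spec with geometry scaled to ``frame_size`` (same proportions)."""
        s = frame_size[1] / _REFERENCE_HEIGHT
        scaled = dict(
            frame_size=frame_size,
            body_semi_axes=(260.0 * s, 85.0 * s),
            ts_o=60.0 * s, ts_c=80.0 * s, its_o=30.0 * s, its_c=40.0 * s,
            paw_offset_caudal=150.0 * s,
            paw_offset_lateral=160.0 * s,
            digit_sigma=max(1.5, 3.0 * s),
        )
        scaled.update(overrides)
        return cls(**scaled)

    @property
    def center(self) -> tuple[float, float]:
        if self.body_center is not None:
            return self.body_center
        w, h = self.frame_size
        return (w / 2.0, h / 2.0)

    @property
    def heading(self) -> np.ndarray:
        a = math.radians(self.heading_deg)
        return np.array([math.cos(a), math.sin(a)])

    @property
    def spreads(self) -> SpreadPair:
        return SpreadPair(self.ts_o, self.ts_c, self.its_o, self.its_c)

    def side_spreads(self, side: str) -> tuple[float, float]:
        """(ts, its) requested for the given paw side."""
        if side == self.operated_side:
            return self.ts_o, self.its_o
        return self.ts_c, self.its_c

    def digit_centers(self) -> list[tuple[str, int, float, float]]:
        """Unjittered digit centers as (side, digit_index 1-5, x, y).

        Digit 1 is the innermost (medial) toe, digit 5 the outermost.  The
        animal's left is the side with positive cross product heading x
        (position - body center) in image coordinates (ventral view from
        below, y pointing down).
        """
        h = self.heading
        left_lateral = np.array([-h[1], h[0]])  # cross(h, left_lateral) = +1
        cx, cy = self.center
        centers: list[tuple[str, int, float, float]] = []
        for side in ("left", "right"):
            if side == self.occlude_paw:
                continue
            lateral = left_lateral if side == "left" else -left_lateral
            paw = (np.array([cx, cy]) - self.paw_offset_caudal * h
                   + self.paw_offset_lateral * lateral)
            ts, its = self.side_spreads(side)
            for i, (u, v) in enumerate(digit_arc_offsets(ts, its), start=1):
                p = paw + u * lateral + v * (-h)
                centers.append((side, i, float(p[0]), float(p[1])))
        return centers


def digit_arc_offsets(ts: float, its: float) -> np.ndarray:
    """Local (lateral, caudal) offsets of digits 1-5 realizing the spreads.

    Digits are equally spaced in angle on a circular arc with
    chord(1,5) = ts and chord(2,4) = its, which requires ts < 2*its; at
    ts >= 2*its the arc flattens to a straight line and the digits are placed
    collinearly.  Offsets are centered on the paw: digit 3 at the origin,
    digit 1 at the most medial (negative lateral) end.
    """
    if not its < ts:
        raise ValueError(f"need its < ts, got ts={ts}, its={its}")
    ratio = ts / (2.0 * its)
    if ratio >= 1.0 - 1e-9:  # flat: chords cannot both lie on a finite circle
        u = np.array([-ts / 2, -its / 2, 0.0, its / 2, ts / 2])
        v = np.zeros(5)
        return np.column_stack([u, v])
    delta = math.acos(ratio)
    radius = its / (2.0 * math.sin(delta))
    angles = np.array([-2, -1, 0, 1, 2]) * delta
    u = radius * np.sin(angles)
    v = radius * (1.0 - np.cos(angles))  # toes curl away from the body
    return np.column_stack([u, v])


@dataclass
class GroundTruth:
    """Exact per-frame answers the pipeline is scored against."""

    frame_index: int
    digits: list[tuple[str, int, float, float]]  # (side, index, x, y) after jitter
    spreads: SpreadPair  # requested, not jittered
    expected_ssi: float
    body_mask: np.ndarray | None = None

    def side_centroids(self, side: str) -> np.ndarray:
        """(5, 2) array of this side's digit centers, ordered digit 1 -> 5."""
        pts = [(i, x, y) for s, i, x, y in self.digits if s == side]
        pts.sort()
        return np.array([[x, y] for _, x, y in pts])


@lru_cache(maxsize=8)
def _static_base(spec: SceneSpec) -> np.ndarray:
    """Background + body ellipse (+ reflective patch), float32, read-only."""
    w, h = spec.frame_size
    base = np.full((h, w), spec.background, dtype=np.float32)
    cx, cy = spec.center
    a, b = spec.body_semi_axes
    hd = spec.heading
    ys, xs = np.mgrid[0:h, 0:w]
    dx = xs - cx
    dy = ys - cy
    along = dx * hd[0] + dy * hd[1]
    across = -dx * hd[1] + dy * hd[0]
    inside = (along / a) ** 2 + (across / b) ** 2 <= 1.0
    base[inside] = spec.body_intensity
    if spec.reflective_patch is not None:
        px, py, pw, ph, level = spec.reflective_patch
        base[int(py):int(py + ph), int(px):int(px + pw)] = level
    base.setflags(write=False)
    return base


@lru_cache(maxsize=8)
def body_mask(spec: SceneSpec) -> np.ndarray:
    """Boolean mask of the body ellipse (static across frames)."""
    mask = _static_base(spec) == np.float32(spec.body_intensity)
    if spec.reflective_patch is not None and spec.reflective_patch[4] == spec.body_intensity:
        # patch shares the body level; recompute from geometry instead
        w, h = spec.frame_size
        cx, cy = spec.center
        a, b = spec.body_semi_axes
        hd = spec.heading
        ys, xs = np.mgrid[0:h, 0:w]
        dx, dy = xs - cx, ys - cy
        along = dx * hd[0] + dy * hd[1]
        across = -dx * hd[1] + dy * hd[0]
        mask = (along / a) ** 2 + (across / b) ** 2 <= 1.0
    mask.setflags(write=False)
    return mask


def _frame_rng(spec: SceneSpec, frame_index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, frame_index])


def render_frame(spec: SceneSpec, frame_index: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Render one frame and its ground truth.

    Deterministic: identical (spec, frame_index) give identical pixels and
    ground truth.  Digit centers are jittered per frame by isotropic Gaussian
    noise of sd ``spec.jitter_sd``; ground truth records the jittered centers.
    Raises if any digit blob falls outside the frame.
    """
    w, h = spec.frame_size
    rng = _frame_rng(spec, frame_index)

    img = np.array(_static_base(spec), dtype=np.float32, copy=True)
    if spec.noise_sd > 0:
        img += rng.standard_normal(img.shape, dtype=np.float32) * spec.noise_sd

    centers = spec.digit_centers()
    if spec.jitter_sd > 0:
        jit = rng.normal(0.0, spec.jitter_sd, size=(len(centers), 2))
    else:
        jit = np.zeros((len(centers), 2))
    jittered: list[tuple[str, int, float, float]] = []
    half = int(math.ceil(4 * spec.digit_sigma))
    for (side, idx, x, y), (dx, dy) in zip(centers, jit):
        x, y = x + dx, y + dy
        if not (half <= x < w - half and half <= y < h - half):
            raise ValueError(
                f"digit {side}:{idx} at ({x:.1f}, {y:.1f}) falls outside the "
                f"{w}x{h} frame; shrink the geometry or enlarge the frame"
            )
        jittered.append((side, idx, x, y))
        x0, y0 = int(x) - half, int(y) - half
        gy, gx = np.mgrid[y0:y0 + 2 * half + 1, x0:x0 + 2 * half + 1]
        blob = spec.digit_peak * np.exp(
            -((gx - x) ** 2 + (gy - y) ** 2) / (2.0 * spec.digit_sigma ** 2)
        )
        img[y0:y0 + 2 * half + 1, x0:x0 + 2 * half + 1] += blob.astype(np.float32)

    np.clip(img, 0, 255, out=img)
    expected = record_from_spreads(frame_index, spec.spreads).ssi
    gt = GroundTruth(
        frame_index=frame_index,
        digits=jittered,
        spreads=spec.spreads,
        expected_ssi=expected,
        body_mask=body_mask(spec),
    )
    return img.astype(np.uint8), gt


def iter_frames(spec: SceneSpec, n_frames: int, start: int = 0):
    """Yield (frame_index, image, ground_truth) for a run of frames."""
    for i in range(start, start + n_frames):
        img, gt = render_frame(spec, i)
        yield i, img, gt


def ground_truth_table(truths: list[GroundTruth]) -> pd.DataFrame:
    """Tabulate ground truths: one row per frame, digit coords in columns."""
    rows = []
    for gt in truths:
        row = {
            "frame_index": gt.frame_index,
            "ts_o": gt.spreads.ts_o, "ts_c": gt.spreads.ts_c,
            "its_o": gt.spreads.its_o, "its_c": gt.spreads.its_c,
            "expected_ssi": gt.expected_ssi,
        }
        for side, idx, x, y in gt.digits:
            tag = f"{side[0].upper()}{idx}"
            row[f"{tag}_x"] = x
            row[f"{tag}_y"] = y
        rows.append(row)
    return pd.DataFrame(rows)


def render_video(spec: SceneSpec, n_frames: int, out: str | Path) -> tuple[Path, Path]:
    """Render a video file plus a ground-truth CSV next to it.

    ``.tif``/``.tiff`` targets are written losslessly via tifffile (the
    recommended container for quantitative work).  ``.mp4`` targets use
    imageio's ffmpeg plugin with near-lossless x264 settings and require
    ``imageio-ffmpeg`` to be installed.  Returns (video_path, csv_path).
    """
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    suffix = out.suffix.lower()
    truths: list[GroundTruth] = []

    def frames():
        for _, img, gt in iter_frames(spec, n_frames):
            gt.body_mask = None  # keep memory flat for long videos
            truths.append(gt)
            yield img

    if suffix in (".tif", ".tiff"):
        import tifffile

        w, h = spec.frame_size
        big = n_frames * w * h > 3_500_000_000
        tifffile.imwrite(out, frames(), shape=(n_frames, h, w), dtype=np.uint8,
                         bigtiff=big, photometric="minisblack")
    elif suffix == ".mp4":
        import imageio

        try:
            writer = imageio.get_writer(
                out, fps=30, codec="libx264",
                output_params=["-crf", "0", "-preset", "veryfast"],
                pixelformat="yuv444p",
            )
        except Exception as exc:  # pragma: no cover - depends on ffmpeg plugin
            raise RuntimeError(
                "MP4 encoding needs imageio's ffmpeg plugin "
                "(pip install imageio-ffmpeg); alternatively render to .tif"
            ) from exc
        with writer:
            for img in frames():
                writer.append_data(img)
    else:
        raise ValueError(f"unsupported video container {suffix!r}; use .tif or .mp4")

    csv_path = out.with_name(out.stem + "_ground_truth.csv")
    ground_truth_table(truths).to_csv(csv_path, index=False, float_format="%.6f")
    return out, csv_path
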