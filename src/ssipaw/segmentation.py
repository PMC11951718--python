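"""Frame segmentation: body mask and digit-candidate detection.

Turns a cropped video frame into a :class:`FrameDetection` — the bright body
blob plus a small set of compact bright components hypothesized to be toe
contact points.  The detection stage is a pluggable backend behind a single
contract (frame -> FrameDetection); the shipped ``classical`` backend is a
deterministic intensity pipeline:

1. grayscale conversion (channel mean) with an optional intensity inversion
   for dark-coated animals on bright floors;
2. Otsu's adaptive global threshold computed from pixels inside the ROI, so a
   uniform brightness shift does not change the detection;
3. morphological opening (disk radius 1) to cut sensor-noise speckle;
4. 8-connected component labeling: the largest component is the body, the
   remaining components are digit candidates if their area lies in a
   configured window and their solidity (area / convex hull area) is at
   least ``min_solidity``;
5. paw-sized components (area above the digit window) holding two or more
   intensity peaks are split by nearest-peak assignment, recovering digits
   whose pads merged into one blob.

Area limits are expressed at a 1920x1080 reference and scaled by the actual
frame area, so the same configuration works across resolutions.  Centroids
are intensity-weighted and sub-pixel, in (x, y) image coordinates with the
origin at the top-left corner and y pointing down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "RoiPolygon",
    "DigitCandidate",
    "FrameDetection",
    "SegmentationParams",
    "apply_roi",
    "segment_frame",
]

NO_ANIMAL = "NO_ANIMAL"

_OPEN_STRUCTURE = ndimage.generate_binary_structure(2, 1)  # disk of radius 1
_LABEL_STRUCTURE = ndimage.generate_binary_structure(2, 2)  # 8-connectivity


@dataclass(frozen=True)
class RoiPolygon:
    """Four-vertex region of interest in click order, in (x, y) pixels.

    Must be a simple (non-self-intersecting) quadrilateral of positive area;
    analysis is confined to its interior so that reflective surroundings of
    the box do not produce spurious detections.
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) != 4:
            raise ValueError(f"ROI polygon needs exactly 4 vertices, got {len(self.vertices)}")
        from shapely.geometry import Polygon

        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"ROI polygon is degenerate or self-intersecting: {self.vertices}")

    @classmethod
    def full_frame(cls, width: int, height: int) -> "RoiPolygon":
        return cls(((0.0, 0.0), (width - 1.0, 0.0), (width - 1.0, height - 1.0), (0.0, height - 1.0)))

    def check_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for x, y in self.vertices:
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                raise ValueError(f"ROI vertex ({x}, {y}) outside {w}x{h} frame")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the polygon interior for a (height, width) frame."""
        return _polygon_mask(self.vertices, shape)

    def contains(self, x: float, y: float) -> bool:
        from shapely.geometry import Point, Polygon

        return Polygon(self.vertices).buffer(1e-9).contains(Point(x, y))


@lru_cache(maxsize=32)
def _polygon_mask(vertices: tuple, shape: tuple[int, int]) -> np.ndarray:
    from shapely.geometry import Polygon
    from skimage.draw import polygon2mask

    # Vertices address pixel centers; dilate by half a pixel so that a
    # polygon whose corners are the frame corners covers every pixel.
    poly = Polygon(vertices).buffer(0.5, join_style="mitre")
    xy = np.asarray(poly.exterior.coords)
    mask = polygon2mask(shape, xy[:, ::-1])  # (row, col) order
    mask.setflags(write=False)
    return mask


@dataclass(frozen=True)
class DigitCandidate:
    """A compact bright component hypothesized to be a toe contact point."""

    centroid: tuple[float, float]  # (x, y), intensity-weighted, sub-pixel
    area: int  # pixel count
    mean_intensity: float

    @property
    def xy(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)


@dataclass
class FrameDetection:
    """Per-frame segmentation output: body mask plus digit candidates."""

    frame_index: int
    body_mask: np.ndarray | None = None
    digit_candidates: list[DigitCandidate] = field(default_factory=list)
    reject_reason: str | None = None

    @property
    def centroids(self) -> np.ndarray:
        if not self.digit_candidates:
            return np.empty((0, 2))
        return np.array([c.centroid for c in self.digit_candidates])


@dataclass(frozen=True)
class SegmentationParams:
    """Classical backend configuration.

    Area limits are in px^2 at the 1920x1080 reference resolution and are
    scaled by (frame area / reference area) before use.  ``invert`` flips
    intensities for foreground-darker-than-background footage.
    """

    backend: str = "classical"
    invert: bool = False
    digit_area_min: float = 30.0
    digit_area_max: float = 2000.0
    min_body_area: float = 5000.0
    min_solidity: float = 0.7
    max_candidates: int = 10
    reference_area: float = 1920.0 * 1080.0
    peak_min_distance: int = 5

    def area_scale(self, shape: tuple[int, int]) -> float:
        return (shape[0] * shape[1]) / self.reference_area


def apply_roi(frame: np.ndarray, roi: RoiPolygon) -> np.ndarray:
    """Zero all pixels outside the ROI polygon; frame dimensions preserved.

    Masking rather than cropping keeps all downstream coordinates in the
    original frame system.
    """
    roi.check_bounds(frame.shape[:2])
    mask = roi.to_mask(frame.shape[:2])
    out = frame.copy()
    out[~mask] = 0
    return out


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return frame.astype(np.float32, copy=False)
    if frame.ndim == 3:
        return frame.mean(axis=-1, dtype=np.float32)
    raise ValueError(f"expected a 2-D or 3-D frame, got shape {frame.shape}")


def _otsu(values: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(values))


def _solidity(region: np.ndarray) -> float:
    from skimage.morphology import convex_hull_image

    area = int(region.sum())
    if area <= 2:
        return 1.0
    hull = int(convex_hull_image(region).sum())
    return area / hull if hull else 1.0


def _weighted_centroid(gray_crop: np.ndarray, region: np.ndarray,
                       offset: tuple[int, int]) -> tuple[float, float]:
    """Intensity-weighted centroid of ``region`` in full-frame (x, y) coords."""
    w = np.where(region, gray_crop, 0.0)
    total = w.sum()
    if total <= 0:  # fall back to the geometric centroid
        ys, xs = np.nonzero(region)
        return (float(xs.mean()) + offset[1], float(ys.mean()) + offset[0])
    ys, xs = np.nonzero(region)
    wv = w[ys, xs]
    return (float((xs * wv).sum() / total) + offset[1],
            float((ys * wv).sum() / total) + offset[0])


def _split_by_peaks(gray_crop: np.ndarray, region: np.ndarray,
                    offset: tuple[int, int], params: SegmentationParams,
                    area_lo: float, area_hi: float) -> list[DigitCandidate]:
    """Split a merged paw-sized component at its intensity peaks.

    Each pixel of the component is assigned to the nearest intensity peak;
    the resulting sub-components within the digit area window become
    candidates.  Returns [] when fewer than two peaks are found.
    """
    from skimage.feature import peak_local_max
    from skimage.filters import gaussian

    smoothed = gaussian(np.where(region, gray_crop, 0.0), sigma=1.0, preserve_range=True)
    peaks = peak_local_max(smoothed, min_distance=params.peak_min_distance,
                           labels=region.astype(np.uint8), num_peaks=params.max_candidates)
    if len(peaks) < 2:
        return []
    tree = cKDTree(peaks)
    ys, xs = np.nonzero(region)
    _, nearest = tree.query(np.column_stack([ys, xs]))
    candidates = []
    for k in range(len(peaks)):
        sel = nearest == k
        if not (area_lo <= sel.sum() <= area_hi):
            continue
        sub = np.zeros_like(region)
        sub[ys[sel], xs[sel]] = True
        cx, cy = _weighted_centroid(gray_crop, sub, offset)
        candidates.append(DigitCandidate(
            centroid=(cx, cy), area=int(sel.sum()),
            mean_intensity=float(gray_crop[sub].mean()),
        ))
    return candidates


def segment_frame(frame: np.ndarray, roi: RoiPolygon,
                  params: SegmentationParams = SegmentationParams(),
                  frame_index: int = 0) -> FrameDetection:
    """Detect the body and digit candidates in one (croppable) frame.

    Fully deterministic: identical frames yield identical detections.  Frames
    with no body-sized bright component are returned with
    ``reject_reason=NO_ANIMAL`` instead of raising.
    """
    if params.backend != "classical":
        raise ValueError(f"unknown segmentation backend {params.backend!r}")
    gray = _to_gray(frame)
    if params.invert:
        gray = gray.max() - gray
    roi_mask = roi.to_mask(gray.shape)
    vals = gray[roi_mask]
    detection = FrameDetection(frame_index=frame_index)
    if vals.size == 0 or vals.max() == vals.min():
        detection.reject_reason = NO_ANIMAL
        return detection

    threshold = _otsu(vals)
    binary = (gray > threshold) & roi_mask
    opened = ndimage.binary_opening(binary, structure=_OPEN_STRUCTURE)
    labels, n_labels = ndimage.label(opened, structure=_LABEL_STRUCTURE)
    if n_labels == 0:
        detection.reject_reason = NO_ANIMAL
        return detection

    scale = params.area_scale(gray.shape)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    body_label = int(np.argmax(areas))
    if areas[body_label] < params.min_body_area * scale:
        detection.reject_reason = NO_ANIMAL
        return detection
    detection.body_mask = labels == body_label

    area_lo = params.digit_area_min * scale
    area_hi = params.digit_area_max * scale
    slices = ndimage.find_objects(labels)
    candidates: list[DigitCandidate] = []
    for lab, slc in enumerate(slices, start=1):
        if lab == body_label or slc is None:
            continue
        area = int(areas[lab])
        if area < area_lo:
            continue
        offset = (slc[0].start, slc[1].start)
        region = labels[slc] == lab
        gray_crop = gray[slc]
        if area > area_hi:
            candidates.extend(
                _split_by_peaks(gray_crop, region, offset, params, area_lo, area_hi))
            continue
        if _solidity(region) < params.min_solidity:
            continue
        cx, cy = _weighted_centroid(gray_crop, region, offset)
        candidates.append(DigitCandidate(
            centroid=(cx, cy), area=area,
            mean_intensity=float(gray_crop[region].mean()),
        ))

    candidates.sort(key=lambda c: (-c.area, c.centroid))
    detection.digit_candidates = candidates[: params.max_candidates]
    return detection
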