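"""Body axis, heading, left/right paw assignment and toe-spread measurement.

Given the digit candidates of one frame, this module reconstructs the
animal's geometry far enough to measure both hind paws:

* the body axis is the major principal axis of the body mask's second-order
  central moments;
* the heading along that axis is fixed by the rule that hind paws trail the
  body — the mean digit position must lie on the caudal side of the body
  centroid.  The rule needs no snout detection and is robust for the
  stationary postures the static index is measured in; frames where the
  digit cloud straddles the centroid are flagged ambiguous and dropped
  rather than guessed;
* candidates are split into left/right paws by the sign of the 2-D cross
  product of the heading with the centroid-to-candidate vector.  The camera
  films the ventral side from below, so in image coordinates (y down) a
  positive cross product is the animal's left; rigs with a mirror in the
  optical path can set ``flip_lr``;
* within a paw, digits are indexed 1 (innermost toe, closest to the body
  axis) to 5 (outermost) by their distance from the body axis line, and the
  spreads are TS = |digit1 - digit5|, ITS = |digit2 - digit4| (Euclidean,
  pixels).

All distances are Euclidean, so the whole chain is equivariant under rigid
rotations and translations of the scene.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .segmentation import DigitCandidate

__all__ = [
    "BodyAxis",
    "PawMeasurement",
    "PawSplit",
    "body_axis",
    "resolve_heading",
    "split_paws",
    "order_digits",
    "toe_spreads",
    "measure_paw",
    "assign_roles",
]

OK = "OK"
MISSING_DIGITS = "MISSING_DIGITS"
PAW_NOT_VISIBLE = "PAW_NOT_VISIBLE"

#: Eigenvalue ratio below which the body mask is treated as isotropic.
_DEGENERATE_RATIO = 1.05


@dataclass(frozen=True)
class BodyAxis:
    """Principal axis of the body mask, optionally with a resolved heading.

    ``direction`` is a unit vector along the major axis with an arbitrary but
    deterministic sign; ``heading_sign`` (+1/-1) orients it toward the head
    once resolved.  ``axis_length`` is the full major-axis length of the
    moment-equivalent ellipse, used by QC as a body-size scale.
    """

    centroid: tuple[float, float]
    direction: tuple[float, float]
    axis_length: float
    heading_sign: int | None = None
    degenerate: bool = False
    ambiguous: bool = False

    @property
    def heading(self) -> np.ndarray:
        if self.heading_sign is None:
            raise ValueError("heading not resolved; call resolve_heading first")
        return self.heading_sign * np.asarray(self.direction)

    @property
    def centroid_xy(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)


@dataclass(frozen=True, eq=False)
class PawMeasurement:
    """One paw's ordered digits and toe spreads (pixels)."""

    side: str  # "left" | "right"
    digits: np.ndarray  # (5, 2), ordered digit 1 -> 5 (medial -> lateral)
    ts: float
    its: float
    role: str | None = None  # "operated" | "control"


@dataclass
class PawSplit:
    """Left/right partition of digit candidates with per-side status."""

    left: list[DigitCandidate]
    right: list[DigitCandidate]
    left_status: str = OK
    right_status: str = OK

    def side(self, name: str) -> list[DigitCandidate]:
        return self.left if name == "left" else self.right

    def status(self, name: str) -> str:
        return self.left_status if name == "left" else self.right_status


def body_axis(body_mask: np.ndarray) -> BodyAxis:
    """Centroid and major principal axis of a binary body mask.

    The direction is the leading eigenvector of the second-order central
    moment (inertia) tensor, with its sign fixed deterministically (positive
    x, ties toward positive y).  Nearly isotropic masks (eigenvalue ratio
    below 1.05, e.g. a circle) are flagged ``degenerate``; the returned
    direction is then arbitrary but still deterministic.
    """
    ys, xs = np.nonzero(body_mask)
    if ys.size == 0:
        raise ValueError("cannot compute a body axis from an empty mask")
    cx, cy = float(xs.mean()), float(ys.mean())
    dx, dy = xs - cx, ys - cy
    mxx = float((dx * dx).mean())
    myy = float((dy * dy).mean())
    mxy = float((dx * dy).mean())
    tensor = np.array([[mxx, mxy], [mxy, myy]])
    eigvals, eigvecs = np.linalg.eigh(tensor)  # ascending eigenvalues
    major = eigvecs[:, 1]
    if major[0] < 0 or (major[0] == 0 and major[1] < 0):
        major = -major
    lam_minor, lam_major = float(eigvals[0]), float(eigvals[1])
    degenerate = lam_minor > 0 and lam_major / lam_minor < _DEGENERATE_RATIO
    # For a solid ellipse the major second moment is (a/2)^2, so the full
    # major-axis length is 4 * sqrt(lambda_major).
    return BodyAxis(
        centroid=(cx, cy),
        direction=(float(major[0]), float(major[1])),
        axis_length=4.0 * np.sqrt(max(lam_major, 0.0)),
        degenerate=degenerate,
    )


def resolve_heading(axis: BodyAxis, digit_centroids: np.ndarray,
                    tolerance: float = 2.0) -> BodyAxis:
    """Orient the body axis using the rule that hind paws trail the body.

    The heading sign is chosen so the mean digit centroid lies on the caudal
    (negative-heading) side of the body centroid.  If the mean's projection
    onto the axis is within ``tolerance`` pixels of the centroid the frame is
    flagged ``ambiguous`` (heading left unresolved) instead of guessing.
    """
    pts = np.atleast_2d(np.asarray(digit_centroids, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("need at least one digit centroid to resolve heading")
    t = float((pts.mean(axis=0) - axis.centroid_xy) @ np.asarray(axis.direction))
    if abs(t) < tolerance:
        return replace(axis, ambiguous=True, heading_sign=None)
    return replace(axis, heading_sign=-1 if t > 0 else 1, ambiguous=False)


def split_paws(candidates: list[DigitCandidate], axis: BodyAxis,
               flip_lr: bool = False) -> PawSplit:
    """Partition candidates into the animal's left and right paws.

    A candidate is on the animal's left when the cross product of the heading
    with (candidate - body centroid) is positive (ventral view, y down);
    ``flip_lr`` inverts the rule for mirrored rigs.  A side with more than 5
    candidates keeps the 5 largest by area; fewer than 5 marks the side
    ``MISSING_DIGITS`` (``PAW_NOT_VISIBLE`` when empty).
    """
    h = axis.heading
    c = axis.centroid_xy
    left: list[DigitCandidate] = []
    right: list[DigitCandidate] = []
    for cand in candidates:
        v = cand.xy - c
        cross = h[0] * v[1] - h[1] * v[0]
        if flip_lr:
            cross = -cross
        (left if cross > 0 else right).append(cand)

    def trim(side: list[DigitCandidate]) -> tuple[list[DigitCandidate], str]:
        if not side:
            return side, PAW_NOT_VISIBLE
        if len(side) < 5:
            return side, MISSING_DIGITS
        side = sorted(side, key=lambda cand: (-cand.area, cand.centroid))[:5]
        return side, OK

    left, left_status = trim(left)
    right, right_status = trim(right)
    return PawSplit(left=left, right=right, left_status=left_status, right_status=right_status)


def order_digits(digit_centroids: np.ndarray, axis: BodyAxis) -> np.ndarray:
    """Order a paw's 5 digit centroids from medial (digit 1) to lateral (5).

    Sorts by the absolute signed projection onto the axis perpendicular to
    the heading — the distance from the body axis line — with ties broken by
    distance to the body centroid, which keeps the order total and
    deterministic.
    """
    pts = np.asarray(digit_centroids, dtype=float)
    if pts.shape != (5, 2):
        raise ValueError(f"expected exactly 5 digit centroids, got shape {pts.shape}")
    h = axis.heading
    perp = np.array([-h[1], h[0]])
    rel = pts - axis.centroid_xy
    lateral = np.abs(rel @ perp)
    radial = np.linalg.norm(rel, axis=1)
    order = np.lexsort((radial, lateral))
    return pts[order]


def toe_spreads(ordered_digits: np.ndarray) -> tuple[float, float]:
    """(TS, ITS) of an ordered paw: |digit1 - digit5| and |digit2 - digit4|."""
    d = np.asarray(ordered_digits, dtype=float)
    if d.shape != (5, 2):
        raise ValueError(f"expected 5 ordered digits, got shape {d.shape}")
    ts = float(np.linalg.norm(d[0] - d[4]))
    its = float(np.linalg.norm(d[1] - d[3]))
    return ts, its


def measure_paw(candidates: list[DigitCandidate], axis: BodyAxis, side: str) -> PawMeasurement:
    """Order a side's 5 candidates and measure its toe spreads."""
    if len(candidates) != 5:
        raise ValueError(f"{side} paw needs exactly 5 candidates, got {len(candidates)}")
    ordered = order_digits(np.array([c.centroid for c in candidates]), axis)
    ts, its = toe_spreads(ordered)
    return PawMeasurement(side=side, digits=ordered, ts=ts, its=its)


def assign_roles(left: PawMeasurement | None, right: PawMeasurement | None,
                 operated_side: str) -> tuple[PawMeasurement, PawMeasurement]:
    """Attach operated/control roles; returns (operated, control).

    A missing paw raises — callers reject such frames with reason
    ``PAW_NOT_VISIBLE`` before any SSI is computed.
    """
    if operated_side not in ("left", "right"):
        raise ValueError(f"operated_side must be 'left' or 'right', got {operated_side!r}")
    if left is None or right is None:
        missing = "left" if left is None else "right"
        raise ValueError(f"{missing} paw not measured ({PAW_NOT_VISIBLE})")
    paws = {"left": left, "right": right}
    control_side = "right" if operated_side == "left" else "left"
    operated = replace(paws[operated_side], role="operated")
    control = replace(paws[control_side], role="control")
    return operated, control
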