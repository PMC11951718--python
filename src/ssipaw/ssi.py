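"""Static Sciatic Index arithmetic, outlier flagging and per-video aggregation.

The Static Sciatic Index (SSI) quantifies hind-limb function of a rat at rest
from two toe-spread measurements per hind paw: the toe spread TS (distance
between the first and fifth toe centroids) and the intermediate toe spread ITS
(distance between the second and fourth toe centroids).  The operated paw (o)
is compared against the contralateral control paw (c) through the toe spread
factor and intermediate toe spread factor

    TSF  = (TSo - TSc) / TSc,        ITSF = (ITSo - ITSc) / ITSc,

and combined linearly into

    SSI  = 108.44 * TSF + 31.85 * ITSF - 5.49.

An SSI near zero indicates normal function; values around -80 indicate a
complete loss of toe spreading, as seen immediately after a sciatic crush
injury.  Because both factors are ratios of pixel distances, the index is
independent of camera resolution and physical calibration.

Everything in this module is pure computation on numbers; image analysis
lives in :mod:`ssipaw.segmentation` and :mod:`ssipaw.geometry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpreadPair",
    "SSICoefficients",
    "SSIRecord",
    "VideoSummary",
    "DEFAULT_COEFFICIENTS",
    "toe_spread_factor",
    "static_sciatic_index",
    "record_from_spreads",
    "flag_outliers",
    "summarize_video",
]

#: QC / rejection reason codes shared across modules.
NO_FRAMES = "NO_FRAMES"
TOO_FEW_FRAMES = "TOO_FEW_FRAMES"

#: Minimum number of labeled frames a video must exceed to pass QC.
MIN_LABELED_FRAMES = 50

#: Default absolute plausibility window for per-frame SSI values.  The
#: physiological range runs from roughly -80 (complete loss) to +10
#: (healthy baseline); the window adds generous margin on both sides.
DEFAULT_SSI_RANGE = (-150.0, 50.0)


@dataclass(frozen=True)
class SpreadPair:
    """Toe spreads of one frame: operated (o) and control (c) paws, in pixels.

    All four distances must be strictly positive (a zero control spread makes
    the toe-spread factors undefined) and each intermediate spread must be
    smaller than its toe spread, because digits 2 and 4 lie between digits 1
    and 5.
    """

    ts_o: float
    ts_c: float
    its_o: float
    its_c: float

    def __post_init__(self) -> None:
        vals = (self.ts_o, self.ts_c, self.its_o, self.its_c)
        if not all(math.isfinite(v) and v > 0 for v in vals):
            raise ValueError(
                f"all spreads must be finite and strictly positive, got {vals}"
            )
        if not (self.its_o < self.ts_o and self.its_c < self.ts_c):
            raise ValueError(
                "intermediate toe spread must be smaller than toe spread "
                f"(ITSo={self.its_o}, TSo={self.ts_o}; "
                f"ITSc={self.its_c}, TSc={self.ts_c})"
            )

    def scaled(self, k: float) -> "SpreadPair":
        """Return a copy with all four distances multiplied by ``k`` > 0."""
        return SpreadPair(self.ts_o * k, self.ts_c * k, self.its_o * k, self.its_c * k)


@dataclass(frozen=True)
class SSICoefficients:
    """Weights of the SSI linear model.

    The defaults are the published regression coefficients relating toe-spread
    factors to functional recovery; override only for research into the model
    itself, never for routine measurement.
    """

    w_tsf: float = 108.44
    w_itsf: float = 31.85
    intercept: float = -5.49


DEFAULT_COEFFICIENTS = SSICoefficients()


@dataclass(frozen=True)
class SSIRecord:
    """One frame's spreads, toe-spread factors, SSI value and outlier flag."""

    frame_index: int
    spreads: SpreadPair
    tsf: float
    itsf: float
    ssi: float
    outlier: bool = False

    def with_outlier(self, flag: bool) -> "SSIRecord":
        return replace(self, outlier=bool(flag))


@dataclass
class VideoSummary:
    """Per-video aggregate of the retained SSI measurements plus QC verdict."""

    n_frames_total: int
    n_frames_labeled: int
    n_frames_retained: int
    mean_ssi: float = math.nan
    sd_ssi: float = math.nan
    median_ssi: float = math.nan
    q25_ssi: float = math.nan
    q75_ssi: float = math.nan
    qc_pass: bool = False
    qc_reasons: list[str] = field(default_factory=list)

    @property
    def retention_fraction(self) -> float:
        if self.n_frames_total == 0:
            return 0.0
        return self.n_frames_retained / self.n_frames_total


def toe_spread_factor(operated: float, control: float, *, frame: int | None = None) -> float:
    """Relative deviation of the operated spread from the control spread.

    Computes ``(operated - control) / control``; serves both TSF (from the toe
    spreads) and ITSF (from the intermediate toe spreads).  Scale invariant:
    multiplying both inputs by any k > 0 leaves the result unchanged.

    Raises
    ------
    ValueError
        If ``control`` is not strictly positive or ``operated`` is negative;
        the message names the offending frame when ``frame`` is given.
    """
    where = "" if frame is None else f" (frame {frame})"
    if not (math.isfinite(control) and control > 0):
        raise ValueError(f"control spread must be strictly positive, got {control}{where}")
    if not (math.isfinite(operated) and operated >= 0):
        raise ValueError(f"operated spread must be non-negative, got {operated}{where}")
    return (operated - control) / control


def static_sciatic_index(
    tsf: float, itsf: float, coeffs: SSICoefficients = DEFAULT_COEFFICIENTS
) -> float:
    """Evaluate the SSI linear model at the given toe-spread factors."""
    if not (math.isfinite(tsf) and math.isfinite(itsf)):
        raise ValueError(f"toe-spread factors must be finite, got tsf={tsf}, itsf={itsf}")
    return coeffs.w_tsf * tsf + coeffs.w_itsf * itsf + coeffs.intercept


def record_from_spreads(
    frame_index: int,
    spreads: SpreadPair,
    coeffs: SSICoefficients = DEFAULT_COEFFICIENTS,
) -> SSIRecord:
    """Build a consistent :class:`SSIRecord` from one frame's spreads."""
    tsf = toe_spread_factor(spreads.ts_o, spreads.ts_c, frame=frame_index)
    itsf = toe_spread_factor(spreads.its_o, spreads.its_c, frame=frame_index)
    return SSIRecord(
        frame_index=frame_index,
        spreads=spreads,
        tsf=tsf,
        itsf=itsf,
        ssi=static_sciatic_index(tsf, itsf, coeffs),
    )


def flag_outliers(
    ssi_values,
    *,
    absolute_range: tuple[float, float] = DEFAULT_SSI_RANGE,
    iqr_factor: float = 1.5,
) -> np.ndarray:
    """Flag implausible per-frame SSI values, preserving input order.

    Two stages:

    1. *Plausibility*: values outside ``absolute_range`` are flagged outright.
       The default window brackets the physiological SSI range with margin.
    2. *Tukey fences*: of the surviving values, those outside
       ``[q25 - iqr_factor*IQR, q75 + iqr_factor*IQR]`` are flagged, the same
       convention under which boxplot crosses mark outliers.  Quartiles use
       linear interpolation.

    Fewer than 4 values raise no flags (quartiles are meaningless); an empty
    input is an error.
    """
    values = np.asarray(ssi_values, dtype=float)
    if values.ndim != 1:
        raise ValueError("ssi_values must be one-dimensional")
    if values.size == 0:
        raise ValueError("cannot flag outliers in an empty sequence")
    flags = np.zeros(values.size, dtype=bool)
    if values.size < 4:
        return flags

    lo, hi = absolute_range
    flags |= (values < lo) | (values > hi) | ~np.isfinite(values)

    surviving = values[~flags]
    if surviving.size == 0:
        return flags
    q25, q75 = np.percentile(surviving, [25.0, 75.0])
    iqr = q75 - q25
    lo_fence = q25 - iqr_factor * iqr
    hi_fence = q75 + iqr_factor * iqr
    flags |= ~flags & ((values < lo_fence) | (values > hi_fence))
    return flags


def summarize_video(
    records,
    sample_size: int = 1000,
    seed: int = 0,
    *,
    n_frames_total: int | None = None,
) -> VideoSummary:
    """Aggregate per-frame SSI records into a :class:`VideoSummary`.

    Draws a seeded uniform subsample (without replacement) of up to
    ``sample_size`` non-outlier records — mirroring reporting the index from a
    random sample of measurements — and computes mean, sample SD (n-1
    denominator), median and quartiles over that subsample.  With fewer
    retained records than ``sample_size`` the whole retained set is used.

    QC: ``qc_pass`` is False with reason ``TOO_FEW_FRAMES`` whenever the video
    has 50 or fewer labeled frames, and with reason ``NO_FRAMES`` when no
    record survives outlier removal.  Identical seeds give bit-identical
    summaries.
    """
    records = list(records)
    n_labeled = len(records)
    n_total = n_frames_total if n_frames_total is not None else n_labeled
    retained = [r.ssi for r in records if not r.outlier]

    summary = VideoSummary(
        n_frames_total=n_total,
        n_frames_labeled=n_labeled,
        n_frames_retained=len(retained),
    )
    if n_labeled <= MIN_LABELED_FRAMES:
        summary.qc_reasons.append(TOO_FEW_FRAMES)
    if not retained:
        summary.qc_reasons.append(NO_FRAMES)
        return summary
    summary.qc_pass = not summary.qc_reasons

    values = np.asarray(retained, dtype=float)
    if values.size > sample_size:
        rng = np.random.default_rng(seed)
        values = values[rng.choice(values.size, size=sample_size, replace=False)]

    summary.mean_ssi = float(np.mean(values))
    summary.sd_ssi = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    q25, med, q75 = np.percentile(values, [25.0, 50.0, 75.0])
    summary.median_ssi = float(med)
    summary.q25_ssi = float(q25)
    summary.q75_ssi = float(q75)
    return summary
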