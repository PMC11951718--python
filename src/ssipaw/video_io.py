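"""Video decoding, crop configuration and measurement export.

Frame sources
-------------
``read_frames`` yields ``(frame_index, frame)`` pairs with a configurable
stride.  Two containers are supported:

* multi-page TIFF (``.tif``/``.tiff``), read via tifffile — lossless, the
  recommended container for quantitative work and the one the synthetic
  renderer writes by default;
* MP4 (``.mp4``), read via imageio's ffmpeg plugin when it is installed
  (``pip install imageio-ffmpeg``).

Crop configuration
------------------
The interactive four-click cropper of the original acquisition GUI is
replaced by a plain-text INI file: one section per video filename with the
four ROI vertices as eight numbers, plus an optional per-video
``operated_side`` override.  See :func:`load_crop_config`.

Export
------
``write_results`` writes ``<video>.xlsx`` with a ``measurements`` sheet
(frame_index, TSo, ITSo, TSc, ITSc, TSF, ITSF, SSI, outlier) and a
``summary`` sheet, plus a CSV mirror of the measurements sheet with numbers
serialized at 6 decimal places.  Distances are in pixels throughout — the
toe-spread factors are ratios, so no physical calibration is needed.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import RoiPolygon
from .ssi import SSIRecord, VideoSummary

__all__ = [
    "VideoReadError",
    "read_frames",
    "probe_video",
    "CropEntry",
    "CropConfig",
    "load_crop_config",
    "save_crop_entry",
    "write_results",
    "read_measurements_csv",
]

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "frame_index", "TSo", "ITSo", "TSc", "ITSc", "TSF", "ITSF", "SSI", "outlier",
]

_TIFF_SUFFIXES = (".tif", ".tiff")


class VideoReadError(RuntimeError):
    """A video file could not be decoded."""


def read_frames(path: str | Path, stride: int = 1):
    """Yield ``(frame_index, frame)`` from a video file, every ``stride``-th frame.

    Frame indices refer to the original file (0, stride, 2*stride, ...).
    Raises :class:`VideoReadError` for missing or undecodable files so batch
    drivers can record the failure and continue with the next video.
    """
    path = Path(path)
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if not path.exists():
        raise VideoReadError(f"video file not found: {path}")
    suffix = path.suffix.lower()
    n = 0
    try:
        if suffix in _TIFF_SUFFIXES:
            import tifffile

            with tifffile.TiffFile(path) as tif:
                for i in range(0, len(tif.pages), stride):
                    yield i, tif.pages[i].asarray()
                    n += 1
        elif suffix == ".mp4":
            yield from _read_mp4(path, stride)
            return
        else:
            raise VideoReadError(f"unsupported container {suffix!r} for {path}; "
                                 "use .mp4 or .tif")
    except VideoReadError:
        raise
    except Exception as exc:
        raise VideoReadError(f"failed to decode {path}: {exc}") from exc
    logger.info("read %d frames (stride %d) from %s", n, stride, path)


def _read_mp4(path: Path, stride: int):
    try:
        import imageio.v2 as imageio

        reader = imageio.get_reader(path, format="ffmpeg")
    except Exception as exc:
        raise VideoReadError(
            f"cannot open MP4 {path}: {exc} — MP4 decoding requires imageio's "
            "ffmpeg plugin (pip install imageio-ffmpeg)"
        ) from exc
    n = 0
    try:
        meta = reader.get_meta_data()
        logger.info("opened %s (fps %s)", path, meta.get("fps"))
        for i, frame in enumerate(reader):
            if i % stride == 0:
                yield i, np.asarray(frame)
                n += 1
    except Exception as exc:
        raise VideoReadError(f"failed while decoding {path}: {exc}") from exc
    finally:
        reader.close()
    logger.info("read %d frames (stride %d) from %s", n, stride, path)


def probe_video(path: str | Path) -> int:
    """Number of frames in a video file (TIFF only; cheap metadata read)."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        with tifffile.TiffFile(path) as tif:
            return len(tif.pages)
    raise VideoReadError(f"cannot probe frame count of {path} without decoding")


@dataclass(frozen=True)
class CropEntry:
    roi: RoiPolygon | None = None  # None = full frame
    operated_side: str | None = None


@dataclass
class CropConfig:
    """Per-video ROI polygons and operated-side declarations.

    ``allow_full_frame`` controls whether a video missing from the config
    falls back to a full-frame ROI (the explicit default the file format
    supports) or is treated as a configuration error.
    """

    entries: dict[str, CropEntry] = field(default_factory=dict)
    default_operated_side: str | None = None
    allow_full_frame: bool = True

    def roi_for(self, video_name: str, frame_shape: tuple[int, int]) -> RoiPolygon:
        entry = self.entries.get(video_name)
        if entry is not None and entry.roi is not None:
            return entry.roi
        if entry is None and not self.allow_full_frame:
            raise KeyError(f"no crop entry for {video_name!r} and full-frame "
                           "fallback is disabled")
        h, w = frame_shape
        return RoiPolygon.full_frame(w, h)

    def operated_side_for(self, video_name: str, fallback: str = "left") -> str:
        entry = self.entries.get(video_name)
        if entry is not None and entry.operated_side is not None:
            return entry.operated_side
        return self.default_operated_side or fallback


def _parse_points(text: str) -> RoiPolygon:
    nums = [float(t) for t in text.replace(",", " ").split()]
    if len(nums) != 8:
        raise ValueError(f"expected 8 numbers (4 vertices), got {len(nums)}: {text!r}")
    return RoiPolygon(tuple((nums[i], nums[i + 1]) for i in range(0, 8, 2)))


def load_crop_config(path: str | Path) -> CropConfig:
    """Read an INI crop configuration.

    Format::

        [DEFAULT]
        operated_side = left

        [rat3_day7.mp4]
        points = 120,40 1800,40 1800,1040 120,1040
        operated_side = right

    A section without ``points`` declares a full-frame ROI explicitly.
    """
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(f"crop config not found: {path}")
    entries: dict[str, CropEntry] = {}
    for section in parser.sections():
        roi = None
        if parser.has_option(section, "points"):
            roi = _parse_points(parser.get(section, "points"))
        side = parser.get(section, "operated_side", fallback=None)
        if side is not None and side not in ("left", "right"):
            raise ValueError(f"[{section}] operated_side must be left or right, got {side!r}")
        entries[section] = CropEntry(roi=roi, operated_side=side)
    default_side = parser.defaults().get("operated_side")
    return CropConfig(entries=entries, default_operated_side=default_side)


def save_crop_entry(path: str | Path, video_name: str,
                    points: tuple[tuple[float, float], ...] | None,
                    operated_side: str | None = None) -> None:
    """Add or replace one video's entry in a crop config file."""
    parser = configparser.ConfigParser()
    parser.read(path)
    if not parser.has_section(video_name):
        parser.add_section(video_name)
    if points is not None:
        RoiPolygon(tuple(points))  # validate before writing
        parser.set(video_name, "points",
                   " ".join(f"{x:g},{y:g}" for x, y in points))
    if operated_side is not None:
        parser.set(video_name, "operated_side", operated_side)
    with open(path, "w") as fh:
        parser.write(fh)


def records_frame(records: list[SSIRecord]) -> pd.DataFrame:
    """Measurement records as a DataFrame in the pinned column layout."""
    rows = [
        {
            "frame_index": r.frame_index,
            "TSo": r.spreads.ts_o, "ITSo": r.spreads.its_o,
            "TSc": r.spreads.ts_c, "ITSc": r.spreads.its_c,
            "TSF": r.tsf, "ITSF": r.itsf, "SSI": r.ssi,
            "outlier": bool(r.outlier),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def summary_frame(summary: VideoSummary) -> pd.DataFrame:
    rows = [
        ("n_frames_total", summary.n_frames_total),
        ("n_frames_labeled", summary.n_frames_labeled),
        ("n_frames_retained", summary.n_frames_retained),
        ("retention_fraction", round(summary.retention_fraction, 6)),
        ("mean_ssi", summary.mean_ssi),
        ("sd_ssi", summary.sd_ssi),
        ("median_ssi", summary.median_ssi),
        ("q25_ssi", summary.q25_ssi),
        ("q75_ssi", summary.q75_ssi),
        ("qc_pass", summary.qc_pass),
        ("qc_reasons", ";".join(summary.qc_reasons)),
    ]
    return pd.DataFrame(rows, columns=["field", "value"])


def write_results(records: list[SSIRecord], summary: VideoSummary,
                  out_dir: str | Path, video_name: str) -> dict[str, Path]:
    """Write a video's XLSX workbook and CSV mirror into ``out_dir``.

    The workbook carries a ``measurements`` sheet (one row per labeled frame)
    and a ``summary`` sheet (including QC reason codes).  The CSV mirrors the
    measurements sheet with floats at 6 decimals; reading it back with
    :func:`read_measurements_csv` reproduces the table exactly at that
    precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = Path(video_name).stem
    xlsx = out_dir / f"{stem}.xlsx"
    csv = out_dir / f"{stem}.csv"

    measurements = records_frame(records)
    with pd.ExcelWriter(xlsx, engine="openpyxl") as writer:
        measurements.to_excel(writer, sheet_name="measurements", index=False)
        summary_frame(summary).to_excel(writer, sheet_name="summary", index=False)
    measurements.to_csv(csv, index=False, float_format="%.6f")
    logger.info("wrote %s and %s (%d rows)", xlsx.name, csv.name, len(measurements))
    return {"xlsx": xlsx, "csv": csv}


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    """Read back a measurements CSV written by :func:`write_results`."""
    return pd.read_csv(path, dtype={"frame_index": int, "outlier": bool})
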