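"""Image/table I/O, run configuration and logging.

This module owns the three plumbing concerns of the measurement tool:

* reading micrographs into :class:`RgbMicrograph` containers with an 8-bit
  working range, regardless of the on-disk bit depth;
* the :class:`MeasurementConfig` record that captures every free parameter
  of the Fourier pipeline, together with a stable ``config_digest`` so each
  measurement row is traceable to the exact parameters that produced it;
* a lossless CSV round trip for :class:`MeasurementRecord` tables, the
  single interchange format between the measurement and statistics halves.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import (
    EmptyRecordSet,
    ImageTooSmall,
    InvalidConfig,
    UnreadableImage,
)

logger = logging.getLogger("cborient")

MIN_IMAGE_DIM = 64

#: Staining / microscopy techniques the tool distinguishes.
TECHNIQUES = ("masson", "masson_optimized", "picrosirius", "he_confocal", "synthetic")

CSV_COLUMNS = [
    "sample_id",
    "technique",
    "replicate_id",
    "index",
    "major_px",
    "minor_px",
    "major_angle_deg",
    "config_digest",
]


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger with a terse, parseable format."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RgbMicrograph:
    """A stained-tissue image field, the raw unit of measurement.

    ``pixels`` is always H×W×3 uint8: greyscale sources are replicated to
    three identical channels and 16-bit sources rescaled, so downstream
    code sees one working range.
    """

    pixels: np.ndarray
    technique: str
    sample_id: str
    replicate_id: int
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise UnreadableImage(f"expected H×W×3 pixels, got shape {px.shape}")
        if px.shape[0] < MIN_IMAGE_DIM or px.shape[1] < MIN_IMAGE_DIM:
            raise ImageTooSmall(
                f"image is {px.shape[0]}×{px.shape[1]}; both dimensions must be ≥ {MIN_IMAGE_DIM}"
            )
        if self.technique not in TECHNIQUES:
            raise InvalidConfig(f"unknown technique {self.technique!r}")
        if self.replicate_id < 1:
            raise InvalidConfig("replicate_id must be ≥ 1")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


# Field metadata drives both validation and the YAML/JSON config loader.
_CONFIG_ENUMS = {
    "threshold_mode": ("auto", "manual"),
    "window": ("none", "hann"),
    "grey_levels": ("16bit", "8bit"),
}


@dataclass(frozen=True)
class MeasurementConfig:
    """Free parameters of the Fourier measurement protocol.

    The defaults reproduce the fully automatic variant of the protocol:
    automatic (Otsu) spectrum segmentation, a gain of 100 (the paper-style
    manual adjustment range being 1–400), morphological cleanup with a
    2 px disk, convex hull on, 3 px spike removal, no window.
    """

    spectrum_gain: float = 100.0
    threshold_mode: str = "auto"
    manual_threshold: int | None = None
    min_area_fraction: float = 0.0005
    smoothing_radius_px: int = 2
    apply_convex_hull: bool = True
    spike_removal_radius_px: int = 3
    window: str = "none"
    grey_levels: str = "16bit"
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.spectrum_gain <= 400):
            raise InvalidConfig(f"spectrum_gain {self.spectrum_gain} outside [1, 400]")
        for key, allowed in _CONFIG_ENUMS.items():
            if getattr(self, key) not in allowed:
                raise InvalidConfig(f"{key} must be one of {allowed}")
        if self.threshold_mode == "manual":
            if self.manual_threshold is None:
                raise InvalidConfig("manual_threshold required when threshold_mode is 'manual'")
            if not (0 <= self.manual_threshold <= 255):
                raise InvalidConfig("manual_threshold must be in [0, 255]")
        if not (0.0 < self.min_area_fraction < 1.0):
            raise InvalidConfig("min_area_fraction must lie in (0, 1)")
        if self.smoothing_radius_px < 0 or self.spike_removal_radius_px < 0:
            raise InvalidConfig("morphology radii must be ≥ 0")

    def digest(self) -> str:
        """Short stable hash of the canonicalized configuration.

        Changes iff any field changes; recorded with every measurement so
        results are auditable.
        """
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class MeasurementRecord:
    """One row of the measurement table: the index for one micrograph."""

    sample_id: str
    technique: str
    replicate_id: int
    index: float
    major_px: float
    minor_px: float
    major_angle_deg: float
    config_digest: str

    def __post_init__(self) -> None:
        if not (0.0 < self.index <= 1.0):
            raise InvalidConfig(f"index {self.index} outside (0, 1]")
        if self.minor_px > self.major_px:
            raise InvalidConfig("minor_px must not exceed major_px")
        if abs(self.index - self.minor_px / self.major_px) > 1e-9:
            raise InvalidConfig("index must equal minor_px / major_px")
        if not (0.0 <= self.major_angle_deg < 180.0):
            raise InvalidConfig("major_angle_deg must lie in [0, 180)")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def load_micrograph(
    path: str | Path,
    technique: str,
    sample_id: str,
    replicate_id: int,
) -> RgbMicrograph:
    """Read a TIFF/PNG micrograph and normalize it to 8-bit RGB.

    Greyscale files are replicated to three identical channels; 16-bit
    inputs are linearly rescaled to the 0–255 working range (the
    acquisition convention for these images is the full 8-bit dynamic
    range). RGBA alpha channels are dropped.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of types
        raise UnreadableImage(f"cannot decode {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[:, :, :3]
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise UnreadableImage(f"{path}: unsupported raster shape {raw.shape}")
    if raw.dtype == np.uint16:
        raw = np.round(raw.astype(np.float64) / 65535.0 * 255.0).astype(np.uint8)
    elif raw.dtype != np.uint8:
        arr = raw.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        raw = np.zeros(arr.shape, np.uint8) if hi == lo else np.round(
            (arr - lo) / (hi - lo) * 255.0
        ).astype(np.uint8)
    return RgbMicrograph(
        pixels=raw,
        technique=technique,
        sample_id=sample_id,
        replicate_id=replicate_id,
        source_path=str(path),
    )


def write_measurements(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    """Write measurement records as CSV (UTF-8, '.' decimal, 9 sig. digits)."""
    if not records:
        raise EmptyRecordSet("refusing to write an empty measurement table")
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=CSV_COLUMNS)
    # 12 significant digits: comfortably lossless at the 9-digit contract
    # while keeping index == minor/major within its 1e-9 invariant on re-read
    df.to_csv(path, index=False, float_format="%.12g")


def read_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Inverse of :func:`write_measurements` (lossless at 9 sig. digits)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "technique": str, "config_digest": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidConfig(f"measurement CSV missing columns: {missing}")
    return [
        MeasurementRecord(
            sample_id=str(row["sample_id"]),
            technique=str(row["technique"]),
            replicate_id=int(row["replicate_id"]),
            index=float(row["index"]),
            major_px=float(row["major_px"]),
            minor_px=float(row["minor_px"]),
            major_angle_deg=float(row["major_angle_deg"]),
            config_digest=str(row["config_digest"]),
        )
        for row in df.to_dict("records")
    ]


def load_config(path: str | Path | None = None) -> MeasurementConfig:
    """Load a YAML/JSON config document; missing keys take defaults.

    Unknown keys are rejected rather than ignored so a typo in a config
    file cannot silently change a measurement campaign.
    """
    if path is None or path == "":
        return MeasurementConfig()
    try:
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except Exception as exc:
        raise InvalidConfig(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        return MeasurementConfig()
    if not isinstance(data, dict):
        raise InvalidConfig("config document must be a key-value mapping")
    known = {f.name for f in dataclasses.fields(MeasurementConfig)}
    unknown = set(data) - known
    if unknown:
        raise InvalidConfig(f"unknown config keys: {sorted(unknown)}")
    try:
        return MeasurementConfig(**data)
    except TypeError as exc:
        raise InvalidConfig(str(exc)) from exc
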