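"""The Fourier orientation pipeline: grey image → CBO index.

The collagen bundle orientation (CBO) index of a micrograph is the
minor/major axis ratio of the thresholded central blob of its 2D Fourier
power plot. Parallel collagen bundles concentrate spectral power along a
single line through the origin (perpendicular, in frequency space, to
the bundle direction), so the thresholded blob is elongated and the
index is small; randomly oriented bundles spread power isotropically and
the index approaches 1.

The pipeline mirrors an eight-step interactive protocol (contrast →
greyscale → FFT power plot with gain → threshold → area filter/cleanup →
spike removal → caliper axis measurement), with the two manual steps
(threshold choice and spike exclusion) automated by Otsu's method and a
morphological opening so the default run is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image, disk

from .errors import DegenerateImage, EmptyMask, MaskTooSmall, MixedSample
from .io_config import (
    MeasurementConfig,
    MeasurementRecord,
    RgbMicrograph,
    logger,
)
from .preprocess import GreyImage, best_fit_contrast, to_grey

EXPECTED_REPLICATES = 5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PowerSpectrum:
    """Centered log-magnitude 2D FFT plot, scaled to the 0–255 range."""

    values: np.ndarray  # N×N float64 in [0, 255]
    gain: float
    window: str = "none"

    @property
    def dc_position(self) -> tuple[int, int]:
        n = self.values.shape[0]
        return n // 2, n // 2


@dataclass
class SpectrumMask:
    """Binary blob of central frequencies whose axes encode anisotropy."""

    mask: np.ndarray  # N×N bool
    threshold_used: int
    area_px: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area_px = int(self.mask.sum())


@dataclass(frozen=True)
class AxisMeasurement:
    """Caliper (Feret) axes of the segmented spectrum blob, in pixels."""

    major_px: float  # maximum Feret diameter
    minor_px: float  # extent perpendicular to the major direction
    major_angle_deg: float  # [0, 180), CCW from the +x (column) axis


@dataclass(frozen=True)
class OrientationResult:
    """CBO index for one micrograph plus the parameters that produced it."""

    index: float
    axes: AxisMeasurement
    spectrum_gain: float
    threshold_used: int
    config: MeasurementConfig

    def to_record(self, img: RgbMicrograph) -> MeasurementRecord:
        return MeasurementRecord(
            sample_id=img.sample_id,
            technique=img.technique,
            replicate_id=img.replicate_id,
            index=self.index,
            major_px=self.axes.major_px,
            minor_px=self.axes.minor_px,
            major_angle_deg=self.axes.major_angle_deg,
            config_digest=self.config.digest(),
        )


@dataclass(frozen=True)
class SampleResult:
    """Per-sample mean of replicate indices (the unit of the statistics)."""

    sample_id: str
    technique: str
    replicate_indices: tuple[float, ...]
    mean_index: float


# ---------------------------------------------------------------------------
# Step 3–4: power spectrum
# ---------------------------------------------------------------------------

def _center_crop_square(px: np.ndarray) -> np.ndarray:
    h, w = px.shape
    n = min(h, w)
    r0 = (h - n) // 2
    c0 = (w - n) // 2
    return px[r0 : r0 + n, c0 : c0 + n]


def compute_power_spectrum(
    grey: GreyImage, gain: float = 100.0, window: str = "none"
) -> PowerSpectrum:
    """Centered log-magnitude FFT plot on the 0–255 display scale.

    The image is center-cropped to a square (unequal frequency sampling
    would bias the axis ratio), mean-subtracted, optionally Hann-windowed,
    transformed, and displayed as ``clip(gain * log1p(|F|) / max, 0, 255)``.
    The DC bin — exactly zero after mean subtraction — is set to the
    global maximum, matching the display convention in which the
    zero-frequency point is the brightest spot of the power plot, so the
    plot's central seed point is never an artificial pit.
    """
    px = _center_crop_square(np.asarray(grey.pixels, dtype=np.float64))
    if px.shape[0] < 64:
        raise DegenerateImage("image too small for spectral analysis (min 64 px)")
    if np.ptp(px) == 0:
        raise DegenerateImage("constant image has no spectrum")
    px = px - px.mean()
    if window == "hann":
        hann = np.hanning(px.shape[0])
        px = px * np.outer(hann, hann)
    f = np.fft.fftshift(np.fft.fft2(px))
    s = np.log1p(np.abs(f))
    n = s.shape[0]
    c = n // 2
    s[c, c] = s.max()
    smax = s.max()
    if smax <= 0:
        raise DegenerateImage("spectrum is identically zero")
    values = np.clip(gain * s / smax, 0.0, 255.0)
    return PowerSpectrum(values=values, gain=float(gain), window=window)


# ---------------------------------------------------------------------------
# Step 4–5: segmentation of the central frequencies
# ---------------------------------------------------------------------------

#: Upper bound on the fraction of the power plot an automatic threshold
#: may select; above it Otsu is re-applied within the selection
#: (hierarchical Otsu). The central-frequency blob of a real texture
#: occupies far less than a quarter of the plot.
MAX_SELECTED_FRACTION = 0.25

def _component_containing(mask: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """8-connected component of ``mask`` containing ``seed`` (empty if none)."""
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    lab = labels[seed]
    if lab == 0:
        return np.zeros_like(mask)
    return labels == lab


def segment_spectrum(
    ps: PowerSpectrum,
    mode: str = "auto",
    manual_threshold: int | None = None,
) -> SpectrumMask:
    """Threshold the power plot to select the central frequencies.

    ``auto`` applies Otsu's method to the non-zero values of the
    0–255-quantized display scale (the automated stand-in for the
    protocol's manual segmentation on that scale); ``manual`` uses the
    given threshold directly. Because the display histogram of a noisy
    micrograph is dominated by the spectral noise floor, a single Otsu
    split can land inside that floor and select most of the plot — a
    selection no operator would accept as "the central frequencies" — so
    Otsu is re-applied within the selection until it covers at most
    :data:`MAX_SELECTED_FRACTION` of the plot. Every above-threshold
    pixel enters the mask: for a strongly oriented texture the central
    frequencies appear as a streak plus symmetric harmonic clusters, and
    dropping satellite clusters is the area filter's job
    (:func:`clean_mask`), not the threshold's.
    """
    values = ps.values
    if mode == "manual":
        if manual_threshold is None:
            raise EmptyMask("manual mode requires a threshold")
        thr = float(manual_threshold)
    else:
        display = np.round(values)
        nz = display[display > 0]
        if nz.size < 2 or np.ptp(nz) == 0:
            raise EmptyMask("spectrum has no contrast to threshold")
        thr = float(threshold_otsu(nz, nbins=256))
        while (values >= thr).mean() > MAX_SELECTED_FRACTION:
            nz = nz[nz >= thr]
            if nz.size < 2 or np.ptp(nz) == 0:
                break
            new_thr = float(threshold_otsu(nz, nbins=256))
            if new_thr <= thr:
                break
            thr = new_thr
    binary = values >= thr
    if not binary.any():
        raise EmptyMask(f"threshold {thr:.0f} excludes every spectrum pixel")
    return SpectrumMask(mask=binary, threshold_used=int(round(thr)))


#: Satellite components survive the area filter only if their brightest
#: pixel reaches this fraction of the plot maximum — i.e. they are
#: harmonic peaks of the dominant periodicity, not noise-floor clumps.
HARMONIC_BRIGHTNESS_FRACTION = 0.8


def clean_mask(
    smask: SpectrumMask,
    min_area_fraction: float = 0.0005,
    smoothing_radius_px: int = 2,
    apply_convex_hull: bool = True,
    dc_position: tuple[int, int] | None = None,
    values: np.ndarray | None = None,
) -> SpectrumMask:
    """Area-filter, fill holes, smooth, and optionally take the convex hull.

    In order: (1) the area filter removes satellite components — the
    component containing the DC position always survives; other
    components survive only if they are both larger than
    ``min_area_fraction`` of the field and (when ``values`` is given)
    about as bright as the plot maximum, which keeps the symmetric
    harmonic peaks of a near-periodic texture while dropping noise-floor
    clumps; (2) holes are filled; (3) morphological closing then opening
    with a disk smooths the outline; (4) if ``apply_convex_hull``, the
    surviving structure is replaced by its convex hull — the step that
    turns the central streak plus its harmonic peaks into one homogeneous
    plot.
    """
    mask = smask.mask
    if dc_position is None:
        dc_position = (mask.shape[0] // 2, mask.shape[1] // 2)
    labels, nlab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if nlab == 0:
        raise EmptyMask("cannot clean an empty mask")
    idx = range(1, nlab + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=idx)
    keep = np.zeros(nlab + 1, dtype=bool)
    if values is not None:
        peaks = ndimage.maximum(values, labels, index=idx)
        bright = peaks >= HARMONIC_BRIGHTNESS_FRACTION * values.max()
        keep[1:] = bright & (
            (areas >= min_area_fraction * mask.size) | (areas >= 9)
        )
    else:
        keep[1:] = areas >= min_area_fraction * mask.size
    dc_lab = labels[dc_position]
    if dc_lab > 0:
        keep[dc_lab] = True  # the central component always survives
    filtered = keep[labels]
    if not filtered.any():
        filtered = mask  # area filter removed everything: fall back
    mask = ndimage.binary_fill_holes(filtered)
    if smoothing_radius_px > 0:
        selem = disk(smoothing_radius_px)
        smoothed = ndimage.binary_opening(
            ndimage.binary_closing(mask, structure=selem), structure=selem
        )
        if smoothed.any():
            mask = ndimage.binary_fill_holes(smoothed)
    if apply_convex_hull:
        mask = convex_hull_image(mask)
    if not mask.any():
        raise EmptyMask("cleanup removed every spectrum pixel")
    return SpectrumMask(mask=mask, threshold_used=smask.threshold_used)


def split_spikes(
    smask: SpectrumMask,
    spike_removal_radius_px: int = 3,
    dc_position: tuple[int, int] | None = None,
) -> SpectrumMask:
    """Remove thin radial spikes from the blob by morphological opening.

    Automated surrogate for the protocol's manual "split objects" step:
    spikes in FFT plots (e.g. the axis-aligned cross from image edges)
    are thin structures that an opening with a small disk removes. If
    opening empties the mask (blob thinner than the disk everywhere), the
    input is returned unchanged with a logged warning. Radius 0 is a
    no-op.
    """
    if spike_removal_radius_px <= 0:
        return smask
    mask = smask.mask
    if dc_position is None:
        dc_position = (mask.shape[0] // 2, mask.shape[1] // 2)
    opened = ndimage.binary_opening(mask, structure=disk(spike_removal_radius_px))
    if not opened.any():
        logger.warning(
            "spike removal (radius %d) would empty the mask; keeping input",
            spike_removal_radius_px,
        )
        return smask
    component = _component_containing(opened, dc_position)
    if not component.any():
        # blob survived but drifted off the DC pixel: keep largest piece
        labels, nlab = ndimage.label(opened, structure=np.ones((3, 3), dtype=int))
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, nlab + 1))
        component = labels == (1 + int(np.argmax(sizes)))
    return SpectrumMask(mask=component, threshold_used=smask.threshold_used)


# ---------------------------------------------------------------------------
# Step 8: caliper axis measurement
# ---------------------------------------------------------------------------

ANGLE_STEP_DEG = 0.5


def _mask_points(mask: np.ndarray) -> np.ndarray:
    """Pixel-centre coordinates (x=col, y=-row so angles are CCW) of a mask."""
    rows, cols = np.nonzero(mask)
    return np.column_stack([cols.astype(np.float64), -rows.astype(np.float64)])


def measure_axes(smask: SpectrumMask, angle_step_deg: float = ANGLE_STEP_DEG) -> AxisMeasurement:
    """Maximum Feret diameter and perpendicular width of the blob.

    The major axis is the maximum over directions (searched at
    ``angle_step_deg`` granularity over [0°, 180°)) of the caliper extent
    of the pixel-centre point set, plus 1 px for the pixel footprint; the
    minor axis is the extent perpendicular to the major direction, plus
    1 px. Ties are broken towards the smallest angle.
    """
    if smask.area_px < 3:
        raise MaskTooSmall(f"mask has {smask.area_px} px; need ≥ 3")
    pts = _mask_points(smask.mask)
    # Caliper extents depend only on the convex hull; reduce the point set
    # when the blob is large enough for Qhull to be worthwhile.
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) sets: keep all points
    angles = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])  # A×2
    proj = pts @ dirs.T  # P×A
    extents = proj.max(axis=0) - proj.min(axis=0)
    best = int(np.argmax(extents))  # argmax returns the first (smallest) angle
    major = float(extents[best] + 1.0)
    perp = dirs[best] @ np.array([[0.0, -1.0], [1.0, 0.0]])
    proj_perp = pts @ perp
    minor = float(proj_perp.max() - proj_perp.min() + 1.0)
    angle = float(np.rad2deg(angles[best])) % 180.0
    if minor > major:  # can only happen by the +1 on near-square blobs
        major, minor = max(major, minor), min(major, minor)
    return AxisMeasurement(major_px=major, minor_px=minor, major_angle_deg=angle)


def orientation_index(axes: AxisMeasurement) -> float:
    """CBO index: minor/major axis ratio, in (0, 1].

    0 indicates perfectly parallel collagen bundles, 1 fully random
    orientation.
    """
    return axes.minor_px / axes.major_px


# ---------------------------------------------------------------------------
# Full protocol
# ---------------------------------------------------------------------------

def measure_micrograph(
    img: RgbMicrograph, config: MeasurementConfig | None = None
) -> OrientationResult:
    """Run the complete eight-step protocol on one micrograph.

    Composes greyscale conversion → best-fit contrast → power spectrum →
    segmentation → cleanup → spike removal → axis measurement → index.
    Deterministic for fixed input and configuration.
    """
    if config is None:
        config = MeasurementConfig()
    grey = to_grey(img, depth=config.grey_levels)
    return measure_grey_image(grey, config)


def measure_grey_image(
    grey: GreyImage, config: MeasurementConfig | None = None
) -> OrientationResult:
    """Protocol steps 1 and 3–8 on an already-greyscale image."""
    if config is None:
        config = MeasurementConfig()
    grey = best_fit_contrast(grey)
    ps = compute_power_spectrum(grey, gain=config.spectrum_gain, window=config.window)
    smask = segment_spectrum(ps, mode=config.threshold_mode, manual_threshold=config.manual_threshold)
    smask = clean_mask(
        smask,
        min_area_fraction=config.min_area_fraction,
        smoothing_radius_px=config.smoothing_radius_px,
        apply_convex_hull=config.apply_convex_hull,
        dc_position=ps.dc_position,
        values=ps.values,
    )
    smask = split_spikes(smask, config.spike_removal_radius_px, dc_position=ps.dc_position)
    axes = measure_axes(smask)
    return OrientationResult(
        index=orientation_index(axes),
        axes=axes,
        spectrum_gain=ps.gain,
        threshold_used=smask.threshold_used,
        config=config,
    )


def average_sample(records: list[MeasurementRecord]) -> SampleResult:
    """Arithmetic mean of the replicate indices of one sample+technique.

    The study design takes five fields per sample; a count other than
    five is legal but logged as a warning.
    """
    if not records:
        raise MixedSample("no records to average")
    ids = {(r.sample_id, r.technique) for r in records}
    if len(ids) > 1:
        raise MixedSample(f"records mix samples/techniques: {sorted(ids)}")
    if len(records) != EXPECTED_REPLICATES:
        logger.warning(
            "sample %s has %d replicates (expected %d)",
            records[0].sample_id,
            len(records),
            EXPECTED_REPLICATES,
        )
    indices = tuple(r.index for r in records)
    return SampleResult(
        sample_id=records[0].sample_id,
        technique=records[0].technique,
        replicate_indices=indices,
        mean_index=float(np.mean(indices)),
    )
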