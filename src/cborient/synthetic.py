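"""Synthetic fiber textures, Masson-like scenes, and brute-force oracles.

No real micrographs ship with this package, so everything downstream is
exercised on generated images with exact ground truth:

* :func:`generate_fiber_image` draws straight anti-aliased fiber
  segments whose orientations follow an axial von Mises distribution —
  κ = 0 is fully random orientation, large κ is near-parallel bundles —
  emulating the parallel vs. random collagen patterns of infarct scars.
* :func:`generate_masson_image` colours such a fiber field like a
  Masson's trichrome slide (blue collagen on a pale background) and
  superimposes purple "cellular" blobs with a known mask, so the purple
  removal step can be validated pixel-for-pixel.
* :func:`oracle_spectral_anisotropy` and :func:`oracle_feret` are
  deliberately simple, independent re-derivations (spectral second
  moments; exhaustive-rotation caliper) used to cross-check the pipeline.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateImage, InvalidParams, MaskTooSmall
from .fourier import AxisMeasurement, SpectrumMask, _center_crop_square
from .io_config import RgbMicrograph
from .preprocess import GreyImage


def _check_range(name: str, rng: tuple[float, float], positive: bool = True) -> None:
    lo, hi = rng
    if lo > hi or (positive and lo <= 0):
        raise InvalidParams(f"{name} range {rng} invalid (need 0 < low ≤ high)")


@dataclass(frozen=True)
class FiberFieldParams:
    """Parameters of a synthetic fiber texture.

    Defaults describe a scaled-down (256 px) field of a collagen-rich
    scar at roughly the study's magnification: several hundred bundles a
    few pixels wide and tens to hundreds of pixels long, moderate
    brightness variation between bundles, and mild acquisition noise.
    """

    size_px: int = 256
    n_fibers: int = 300
    kappa: float = 0.0
    mean_angle_deg: float = 30.0
    fiber_length_px: tuple[float, float] = (60.0, 180.0)
    fiber_width_px: tuple[float, float] = (2.0, 6.0)
    fiber_intensity: tuple[float, float] = (60.0, 140.0)
    background_noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_px < 256:
            raise InvalidParams("size_px must be ≥ 256")
        if self.n_fibers < 1:
            raise InvalidParams("n_fibers must be ≥ 1")
        if self.kappa < 0:
            raise InvalidParams("kappa must be ≥ 0")
        if not (0.0 <= self.mean_angle_deg < 180.0):
            raise InvalidParams("mean_angle_deg must lie in [0, 180)")
        if self.background_noise_sd < 0:
            raise InvalidParams("background_noise_sd must be ≥ 0")
        _check_range("fiber_length_px", self.fiber_length_px)
        _check_range("fiber_width_px", self.fiber_width_px)
        _check_range("fiber_intensity", self.fiber_intensity)


@dataclass(frozen=True)
class MassonSceneParams:
    """Parameters of a Masson-like RGB scene: blue collagen, purple cells.

    Default colours approximate aniline-blue collagen (hue ≈ 220°) and
    purple-stained cellular structures (hue ≈ 300°) on the pale slide
    background; the two hues sit well apart so segmentation ground truth
    is unambiguous.
    """

    fiber: FiberFieldParams = field(default_factory=FiberFieldParams)
    collagen_color: tuple[int, int, int] = (40, 85, 170)
    background_color: tuple[int, int, int] = (235, 232, 240)
    n_cell_blobs: int = 40
    blob_radius_px: tuple[float, float] = (6.0, 18.0)
    blob_color: tuple[int, int, int] = (150, 40, 150)
    blob_coverage_target: float = 0.15

    def __post_init__(self) -> None:
        if self.n_cell_blobs < 0:
            raise InvalidParams("n_cell_blobs must be ≥ 0")
        if not (0.0 <= self.blob_coverage_target < 0.5):
            raise InvalidParams("blob_coverage_target must lie in [0, 0.5)")
        _check_range("blob_radius_px", self.blob_radius_px)
        if _hue_deg(self.collagen_color) is not None and _hue_deg(self.blob_color) is not None:
            sep = abs(_hue_deg(self.collagen_color) - _hue_deg(self.blob_color))
            sep = min(sep, 360.0 - sep)
            if sep < 30.0:
                raise InvalidParams(
                    f"collagen and blob hues only {sep:.0f}° apart (need ≥ 30°)"
                )


def _hue_deg(rgb: tuple[int, int, int]) -> float | None:
    """Hue of an RGB triple in degrees (None for achromatic colours)."""
    r, g, b = (c / 255.0 for c in rgb)
    mx, mn = max(r, g, b), min(r, g, b)
    if mx == mn:
        return None
    d = mx - mn
    if mx == r:
        h = ((g - b) / d) % 6.0
    elif mx == g:
        h = (b - r) / d + 2.0
    else:
        h = (r - g) / d + 4.0
    return h * 60.0


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def sample_axial_von_mises(
    rng: np.random.Generator, mean_angle_deg: float, kappa: float, n: int
) -> np.ndarray:
    """Draw ``n`` undirected fiber angles in [0°, 180°).

    Axial data convention: angles are doubled onto the full circle,
    drawn from von Mises(2·mean, κ), then halved. κ = 0 reduces to the
    axial uniform distribution.
    """
    doubled = rng.vonmises(np.deg2rad(2.0 * mean_angle_deg), kappa, size=n)
    return (np.rad2deg(doubled) / 2.0) % 180.0


def _render_fibers(p: FiberFieldParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Additively compose anti-aliased fiber segments; returns (field, angles)."""
    n = p.size_px
    field_img = np.zeros((n, n), dtype=np.float64)
    angles = sample_axial_von_mises(rng, p.mean_angle_deg, p.kappa, p.n_fibers)
    cx = rng.uniform(0, n, p.n_fibers)
    cy = rng.uniform(0, n, p.n_fibers)
    lengths = rng.uniform(*p.fiber_length_px, p.n_fibers)
    widths = rng.uniform(*p.fiber_width_px, p.n_fibers)
    intens = rng.uniform(*p.fiber_intensity, p.n_fibers)
    for i in range(p.n_fibers):
        theta = np.deg2rad(angles[i])
        ux, uy = np.cos(theta), -np.sin(theta)  # image rows grow downwards
        half = lengths[i] / 2.0
        margin = widths[i] / 2.0 + 1.5
        ex, ey = half * abs(ux), half * abs(uy)
        x0 = max(int(np.floor(cx[i] - ex - margin)), 0)
        x1 = min(int(np.ceil(cx[i] + ex + margin)) + 1, n)
        y0 = max(int(np.floor(cy[i] - ey - margin)), 0)
        y1 = min(int(np.ceil(cy[i] + ey + margin)) + 1, n)
        if x0 >= x1 or y0 >= y1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        dx = xs - cx[i]
        dy = ys - cy[i]
        t = np.clip(dx * ux + dy * uy, -half, half)
        dist = np.hypot(dx - t * ux, dy - t * uy)
        profile = np.clip(widths[i] / 2.0 + 0.5 - dist, 0.0, 1.0)  # 1-px AA edge
        field_img[y0:y1, x0:x1] += intens[i] * profile
    return field_img, angles


def generate_fiber_image(p: FiberFieldParams) -> tuple[GreyImage, np.ndarray]:
    """Render a fiber texture; returns the image and the true angle list."""
    rng = np.random.default_rng(p.seed)
    field_img, angles = _render_fibers(p, rng)
    if p.background_noise_sd > 0:
        field_img = field_img + rng.normal(0.0, p.background_noise_sd, field_img.shape)
    field_img = np.clip(field_img, 0.0, 255.0)
    return GreyImage(pixels=field_img, depth="8bit"), angles


def generate_masson_image(
    p: MassonSceneParams,
    sample_id: str = "synthetic",
    replicate_id: int = 1,
) -> tuple[RgbMicrograph, np.ndarray, np.ndarray]:
    """Render a Masson-like scene; returns (image, blob mask, fiber angles).

    Fibers are alpha-blended in ``collagen_color`` over the background,
    then irregular elliptical blobs in ``blob_color`` are superimposed at
    random positions/orientations until ``blob_coverage_target`` is
    reached (never exceeded by more than one blob). The exact blob mask
    is returned as ground truth.
    """
    rng = np.random.default_rng(p.fiber.seed)
    field_img, angles = _render_fibers(p.fiber, rng)
    alpha = np.clip(field_img / 180.0, 0.0, 1.0)[:, :, None]
    bg = np.asarray(p.background_color, dtype=np.float64)
    fg = np.asarray(p.collagen_color, dtype=np.float64)
    rgb = bg + alpha * (fg - bg)

    n = p.fiber.size_px
    blob_mask = np.zeros((n, n), dtype=bool)
    target_px = p.blob_coverage_target * n * n
    ys, xs = np.mgrid[0:n, 0:n]
    for _ in range(p.n_cell_blobs):
        if blob_mask.sum() >= target_px:
            break
        cx, cy = rng.uniform(0, n, 2)
        a = rng.uniform(*p.blob_radius_px)
        b = a * rng.uniform(0.4, 1.0)  # squashed ellipse
        phi = rng.uniform(0, np.pi)
        dx, dy = xs - cx, ys - cy
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        # mild radial irregularity so blobs are not perfect ellipses
        wobble = 1.0 + 0.15 * np.sin(3.0 * np.arctan2(v, u) + rng.uniform(0, 2 * np.pi))
        blob_mask |= (u / (a * wobble)) ** 2 + (v / (b * wobble)) ** 2 <= 1.0
    rgb[blob_mask] = np.asarray(p.blob_color, dtype=np.float64)

    if p.fiber.background_noise_sd > 0:
        rgb = rgb + rng.normal(0.0, p.fiber.background_noise_sd, rgb.shape)
    img = RgbMicrograph(
        pixels=np.clip(np.round(rgb), 0, 255).astype(np.uint8),
        technique="masson" if p.n_cell_blobs else "synthetic",
        sample_id=sample_id,
        replicate_id=replicate_id,
    )
    return img, blob_mask, angles


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def oracle_spectral_anisotropy(grey: GreyImage) -> float:
    """Independent anisotropy score from spectral second moments.

    Forms the second-moment matrix of raw FFT power over frequency
    coordinates (DC excluded, no gain, no thresholding) and returns
    sqrt(λ_min / λ_max) of its eigenvalues — 1 for isotropic power, → 0
    for power concentrated on a line. Used only for ordering/correlation
    cross-checks against the pipeline's index, never for equality.
    """
    px = _center_crop_square(np.asarray(grey.pixels, dtype=np.float64))
    if np.ptp(px) == 0:
        raise DegenerateImage("constant image has no spectrum")
    px = px - px.mean()
    power = np.abs(np.fft.fftshift(np.fft.fft2(px))) ** 2
    n = power.shape[0]
    c = n // 2
    power[c, c] = 0.0
    freq = np.arange(n, dtype=np.float64) - c
    fy, fx = np.meshgrid(freq, freq, indexing="ij")
    total = power.sum()
    mxx = (power * fx * fx).sum() / total
    myy = (power * fy * fy).sum() / total
    mxy = (power * fx * fy).sum() / total
    eigs = np.linalg.eigvalsh(np.array([[mxx, mxy], [mxy, myy]]))
    lam_min, lam_max = max(eigs[0], 0.0), eigs[1]
    if lam_max <= 0:
        raise DegenerateImage("spectral power has no spread")
    return float(np.sqrt(lam_min / lam_max))


def oracle_feret(mask: SpectrumMask, angle_step_deg: float = 1.0) -> AxisMeasurement:
    """Brute-force caliper twin of ``measure_axes``: no optimizations.

    Rotates the full pixel-centre point set over [0°, 180°) in explicit
    steps, recording extents; major = max extent + 1, minor = the
    perpendicular extent at the argmax angle + 1.
    """
    if int(mask.mask.sum()) < 3:
        raise MaskTooSmall("mask area must be ≥ 3 px")
    rows, cols = np.nonzero(mask.mask)
    x = cols.astype(np.float64)
    y = -rows.astype(np.float64)
    best_extent = -1.0
    best_angle = 0.0
    for ang in np.arange(0.0, 180.0, angle_step_deg):
        t = np.deg2rad(ang)
        proj = x * np.cos(t) + y * np.sin(t)
        extent = proj.max() - proj.min()
        if extent > best_extent + 1e-12:
            best_extent = extent
            best_angle = ang
    t = np.deg2rad(best_angle + 90.0)
    proj = x * np.cos(t) + y * np.sin(t)
    minor = proj.max() - proj.min() + 1.0
    return AxisMeasurement(
        major_px=best_extent + 1.0,
        minor_px=min(minor, best_extent + 1.0),
        major_angle_deg=best_angle % 180.0,
    )


def make_reliability_fixture(
    n_samples: int,
    k_raters: int,
    icc_target: float,
    seed: int = 0,
    grand_mean: float = 0.6,
    error_sd: float = 0.1,
    rater_sd: float = 0.02,
) -> np.ndarray:
    """Simulate an n×k rater matrix with a known population ICC.

    Values follow the two-way random-effects model
    ``value = mean + subject + rater + noise``; the subject variance is
    chosen so the population consistency/average-measures ICC,
    k·σ_s² / (k·σ_s² + σ_e²), equals ``icc_target``.
    """
    if n_samples < 2 or k_raters < 2:
        raise InvalidParams("need n ≥ 2 samples and k ≥ 2 raters")
    if not (0.0 <= icc_target < 1.0):
        raise InvalidParams("icc_target must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    var_e = error_sd**2
    var_s = icc_target * var_e / (k_raters * (1.0 - icc_target))
    subj = rng.normal(0.0, np.sqrt(var_s), size=(n_samples, 1))
    rater = rng.normal(0.0, rater_sd, size=(1, k_raters))
    noise = rng.normal(0.0, error_sd, size=(n_samples, k_raters))
    return grand_mean + subj + rater + noise
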