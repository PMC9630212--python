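# Methods

## The measurement model

A micrograph of fibrous tissue is treated as a 2D texture whose
orientation content is read off its Fourier power spectrum. A single
straight fiber at angle θ contributes spectral power along the line
through the origin at θ + 90°; a population of fibers produces a
central structure whose anisotropy mirrors the angular dispersion of
the population. The CBO index is the minor/major caliper (Feret) axis
ratio of that structure after thresholding and cleanup, in (0, 1]:
small for parallel bundles, near 1 for random orientation.

The pipeline (`measure_micrograph`) runs:

1. **Greyscale conversion** — ITU-R 601 luminance
   (0.299 R + 0.587 G + 0.114 B), working depth 16-bit by default.
   The spectrum is invariant to a global linear rescale, so the depth
   choice is benign; it exists because the original interactive protocol
   had an explicit grey-conversion step.
2. **Best-fit contrast** — a percentile-clipped linear stretch to the
   full dynamic range (default clip 0.5% per tail). Idempotent at
   clip 0; rejects constant images.
3. **Power plot** — center-crop to the largest square (unequal
   frequency sampling would bias the axis ratio), subtract the mean,
   optionally apply a 2D Hann window, FFT, shift DC to the center,
   display as `clip(gain · log(1+|F|)/max, 0, 255)`. The DC bin, zeroed
   by mean subtraction, is set to the display maximum — the bright
   zero-frequency point of a conventional power-plot display — so the
   central structure always contains its seed.
4. **Segmentation** — `auto` (default) applies Otsu's method to the
   non-zero values of the 0–255-quantized display; if the selected
   fraction of the plot exceeds 25% (`MAX_SELECTED_FRACTION`), Otsu is
   re-applied within the selection (hierarchical Otsu). The display
   histogram of a noisy micrograph is dominated by the spectral noise
   floor, and a single split can land inside it, selecting most of the
   plot — a selection no operator doing manual segmentation would
   accept. `manual` mode reproduces the operator's fixed threshold.
5. **Cleanup** — connected components smaller than `min_area_fraction`
   of the field (default 5·10⁻⁴) are dropped; the component containing
   DC always survives, and other components survive only if their peak
   display value reaches 80% of the plot maximum
   (`HARMONIC_BRIGHTNESS_FRACTION`) — these are the symmetric harmonic
   peaks of a near-periodic texture, as produced by a grating, whereas
   dim noise-floor clumps are removed regardless of size. Holes are
   filled; a morphological closing-then-opening with a 2 px disk smooths
   the outline; the convex hull of the surviving structure (default on)
   produces the homogeneous central plot that is measured. The hull is
   what bridges a grating's harmonic peaks into one elongated object.
6. **Spike removal** — a morphological opening with a 3 px disk
   (default) removes thin radial spikes such as the axis-aligned cross
   caused by image-edge discontinuities; it replaces the interactive
   "split objects" correction. Radius 0 disables it; if opening would
   empty the mask the input is kept and a warning logged.
7. **Axis measurement** — the major axis is the maximum Feret diameter
   of the pixel-center point set (searched at 0.5° steps over [0°,180°),
   +1 px for the pixel footprint, ties broken to the smallest angle);
   the minor axis is the extent perpendicular to the major direction,
   +1 px. Angles are degrees counterclockwise from the +x (column) axis
   with y pointing up, so the spectral major axis lies perpendicular to
   the dominant fiber direction. An exhaustive-rotation oracle
   (`oracle_feret`) cross-checks this within 1.5%.
8. **Index and averaging** — index = minor/major; per-sample results are
   the arithmetic mean over replicate fields (the study design used five
   per sample; other counts warn but proceed).

## Optimized Masson's trichrome

Masson's trichrome stains collagen blue but cellular structures purple;
in the luminance channel both read as dark texture, and the isotropic
cellular content biases the index towards random. `segment_cellular`
thresholds in HSV space (defaults: hue 260°–340°, saturation ≥ 0.15,
value ≥ 0.10 — calibrated on the synthetic scene generator, since no
reference images ship with the package) and `remove_non_collagen`
replaces masked pixels with the mean colour of the unmasked pixels
(or white), leaving unmasked pixels bit-identical and relabelling the
image `masson_optimized`. Stain-vector deconvolution would be the
natural extension point for real slides but is out of scope.

## Reliability statistics

* **ICC** — two-way random-effects, consistency, average measures:
  ICC = (MS_R − MS_E)/MS_R from the two-way ANOVA without replication;
  F = MS_R/MS_E on (n−1, (n−1)(k−1)) df; one-sided p for H0: ICC = 0;
  95% CI = [1 − 1/F_L, 1 − 1/F_U] with F_L = F/F_{α/2;df1,df2},
  F_U = F·F_{α/2;df2,df1}. Columns identical up to an additive constant
  give ICC = 1 exactly (a negligible residual mean square, below 10⁻¹²
  of MS_R, is treated as zero to absorb floating-point cancellation).
  Fewer than five subjects warns rather than fails so small fixtures run.
* **Bland–Altman** — bias = mean difference; limits = bias ± 2·SD
  (sample SD, n−1). The ±2 convention (not 1.96) is deliberate and
  matched by the calibration test (95.45% of Gaussian differences fall
  inside).
* **CV** — CV% = 100·SEmeas/mean with SEmeas = s_pooled·√(1 − ICC),
  s_pooled the SD of all n·k values. This is the standard error of
  measurement consistent with an ICC-based reliability analysis; the
  source protocol names SEmeas without printing its formula, so this is
  the one reconstructed formula in the package.
* **Report** — all column pairs are compared pairwise (no omnibus
  model), matching the published two-rater and six-technique-pair
  tables. The ICC p-value is one-sided (the alternative reading,
  two-sided, is not offered).

## Synthetic data

`generate_fiber_image` renders straight anti-aliased fiber segments on
a 256 px field: angles from an axial von Mises distribution
(angle-doubling convention; κ = 0 axially uniform, large κ near-
parallel), centers uniform, lengths 60–180 px, widths 2–6 px,
intensities 60–140 on the 8-bit scale, additive composition clipped at
255, Gaussian noise SD 6. The defaults describe a scaled-down field of
a collagen-rich scar: several hundred bundles a few pixels wide with
heavy overlap; 256 px (rather than the 1024 px acquisition format)
keeps the full test suite inside minutes while leaving the geometry of
the measurement unchanged — the index is a ratio and scale-free.

`generate_masson_image` colours the same fiber field aniline-blue
(hue ≈ 220°) over a pale slide background and superimposes irregular
purple (hue ≈ 300°) elliptical blobs until a target coverage (default
15%) is reached, returning the exact blob mask as ground truth.

What the generator does **not** emulate: fiber curvature and waviness,
stain-intensity gradients, polarized-light birefringence, confocal
point-spread blur, uneven illumination. A green synthetic test
establishes the measurement's response to orientation structure and
stain colours, not its behaviour on any particular real slide.

`oracle_spectral_anisotropy` is the independent cross-check for the
index's ordering behaviour: √(λ_min/λ_max) of the second-moment matrix
of raw spectral power (DC excluded). It shares no thresholding or
morphology with the pipeline, so it is used for rank/ordering
comparisons only — the index has no closed form, and equality against
any independent formula would be a false standard.

## Numerical and design choices

* Pure sinusoidal gratings are the degenerate limit of a parallel
  texture: their spectra are isolated peak clusters. They are measurable
  only with the Hann window (without a window, a grating commensurate
  with the grid produces 1–2 px peaks that carry no leakage and cannot
  survive any cleanup); grating checks therefore run with `window=hann`,
  which is also the recommended setting whenever rotation robustness
  matters. The default remains `none`, faithful to the original
  protocol.
* The major-axis *angle* of a wide angular fan (e.g. κ = 8) is
  intrinsically jittery: the convex hull of a bowtie-shaped fan is
  nearly rectangular and the maximum Feret direction snaps to a
  diagonal. Rotation-equivariance checks therefore use strongly
  concentrated textures (κ = 50) and compare seed averages; per-image
  index jitter under resampling is of the same order (±0.05–0.10) as the
  human interrater variability the protocol itself reports.
* Measurement CSVs are written at 12 significant digits: lossless at the
  documented 9-digit contract while keeping the stored index equal to
  minor/major within 10⁻⁹ on re-read.
* The reliability fixture draws subject effects with variance
  σ_s² = t·σ_e²/(k(1−t)) so the population consistency/average-measures
  ICC, kσ_s²/(kσ_s² + σ_e²), equals the target t; a 10⁴-replicate Monte
  Carlo at n = 200 confirms estimator bias < 0.02.

## Known limitations

* No local/ROI-wise orientation maps, fiber tracing, curvature or
  density metrics — the output is one global index per field.
* HSV purple segmentation is calibrated on synthetic colours; real
  Masson slides with atypical stain balance may need the hue/saturation
  thresholds adjusted (they are exposed on the CLI).
* Whole-slide formats and vendor metadata are unsupported; inputs are
  plain TIFF/PNG fields.
* The automatic threshold emulates, but cannot reproduce, any specific
  human operator; the manual mode exists for exact replication of an
  operator's choice.
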