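# cborient

Measurement of **collagen bundle orientation (CBO)** in histology
micrographs by 2D Fourier analysis, with digital "optimization" of
Masson's trichrome images and the method-agreement statistics used to
validate such measurements.

## The problem

Collagen bundle orientation in myocardial infarct scars (and other
collagen-rich tissues such as dermis) determines much of the scar's
mechanical behaviour. A standard way to quantify it from a micrograph is
Fourier analysis: parallel bundles concentrate power of the image's 2D
FFT along a line through the origin, while randomly oriented bundles
spread it isotropically. The **CBO index** is

```
index = minor axis / major axis of the thresholded central blob
        of the log-scaled 2D power spectrum
```

where the axes are caliper (Feret) measurements — the maximum extent
over all directions and the extent perpendicular to it. The index runs
from near 0 (perfectly parallel bundles) to 1 (fully random
orientation).

Masson's trichrome is cheap and ubiquitous but non-specific: cellular
structures (stained purple) enter the power spectrum and push the index
towards "random". The package therefore also implements **optimized
Masson's trichrome**: purple pixels are segmented in HSV space and
replaced by the background colour before measurement, leaving only
collagenous structure.

Because rater choices (spectrum gain, threshold) are part of the
protocol, the package ships the reliability statistics used to compare
raters and staining/microscopy techniques: the two-way random-effects
ICC (consistency, average measures) with F-based 95% CI, Bland–Altman
bias with ±2 SD limits of agreement, and the coefficient of variation
CV% = 100·SEmeas/mean with SEmeas = s·√(1 − ICC).

## Who it is for

Labs quantifying fibrosis/scar architecture from stained sections
(Masson's trichrome, Picrosirius red under polarized light, H&E under
confocal) who want a reproducible, scriptable CBO measurement instead of
an interactive image-analysis session, plus the agreement statistics to
compare observers or staining techniques.

## Worked example

```python
from cborient import (FiberFieldParams, MeasurementConfig,
                      generate_fiber_image, measure_grey_image)

cfg = MeasurementConfig(window="hann")
for label, kappa in [("parallel", 8.0), ("random", 0.0)]:
    grey, angles = generate_fiber_image(FiberFieldParams(kappa=kappa, seed=42))
    r = measure_grey_image(grey, cfg)
    print(f"{label:9s} kappa={kappa}: index={r.index:.3f}  "
          f"major={r.axes.major_px:.1f}px minor={r.axes.minor_px:.1f}px "
          f"angle={r.axes.major_angle_deg:.1f}deg threshold={r.threshold_used}")
```

prints

```
parallel  kappa=8.0: index=0.294  major=179.1px minor=52.6px angle=122.5deg threshold=70
random    kappa=0.0: index=0.959  major=105.9px minor=101.6px angle=172.5deg threshold=68
```

The parallel field (von Mises concentration κ = 8 around 30°) yields an
elongated spectral blob — index 0.29, major axis at 122.5° i.e.
perpendicular to the fiber direction in the spectrum's y-up convention —
while the randomly oriented field (κ = 0) yields a nearly round blob and
an index close to 1. `threshold` is the automatically chosen (Otsu)
segmentation level on the 0–255 display scale; it is recorded, together
with a configuration digest, in every output row so measurements stay
auditable.

## Command line

```
cborient simulate --kind fiber --kappa 8 --n-images 5 --seed 0 --out imgs/
cborient measure --in imgs/ --technique synthetic --window hann --out measurements.csv
cborient optimize-masson --in masson/ --out masson_optimized/
cborient reliability --in measurements.csv --mode interrater --out report.csv
```

`measure` expects filenames like `<sample>_<replicate>.png` (or `.tif`)
and averages the replicate indices per sample; `reliability` emits one
row per column pair with ICC (95% CI, p), Bland–Altman bias/limits and
CV% — the layout used to report interrater and intertechnique agreement.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computation from scratch: it simulates a
two-rater study (ten samples, five replicate fields each, orientation
concentrations spanning random to parallel), measures every field with
the Fourier protocol twice — once with the automatic threshold and once
with the threshold shifted by 10 grey levels, emulating a second
observer — and prints the resulting interrater ICC, Bland–Altman limits
and CV. The JSON file records the script's (empty) target table.
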