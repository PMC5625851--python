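# Methods

## Scope and model

`grainspec` implements a single-kernel wheat protein workflow for push-broom
NIR hyperspectral images: radiometric calibration, spike repair, kernel
segmentation and indexing, spectral pretreatment, NIPALS PLS1 calibration
against Dumas reference protein (N x 5.7, "as-is"), and per-pixel /
per-kernel / per-batch prediction. Because no single-kernel wheat dataset is
publicly deposited, the package ships a first-class scene simulator whose
defaults encode the study conditions the analysis assumes; all quantitative
guarantees are therefore statements about the pipeline's behaviour on data
with that structure, not about any particular instrument.

## The synthetic scene

**Population.** Protein is truncated-normal(mean 10.59 %, SD 2.07 %, bounds
6.15–19.77 %), sampled by rejection; kernels are i.i.d. (no batch-level
protein clustering). Note the bounds are asymmetric around the mean
(−2.1 SD / +4.4 SD), so the truncated mean is ~10.67 %: at the Monte-Carlo
scale used in tests (400 kernels) this bias is inside the 3-SE tolerance,
but exact convergence to 10.59 at very large n is impossible under these
bounds. Projected area is truncated-normal(33.79, 5.54 mm²); kernel weight
follows the allometric coupling `weight = 0.248 · area^{3/2} · exp(ε)` with
ε ~ N(0, 0.13) clipped at ±2.5 SD, which lands the area–weight Pearson r
near the reported 0.88 with weight mean ≈ 49.6 mg, while protein and weight
stay uncorrelated (they are sampled independently). Moisture is
truncated-normal(0.12, 0.01). Each batch carries a hard/soft label
(60 % hard) purely as subset metadata; by default it does not shift the
protein distribution, so the global population statistics stay at their
configured values.

**Optics.** Kernels are axis-aligned ellipses (aspect ~2.0) in two tray
rows. Per-pixel absorbance is a diagonal Beer–Lambert model:
`A(λ) = path · h · o · Σ cᵢ kᵢ(λ)`, with a parabolic pathlength dome
(`0.7 + 0.3(1 − r²)`, normalised to mean 1 over the ellipse), per-kernel
optical thickness `h ∝ √area · exp(ε)` (shared with the weight residual, so
spectra carry thickness — hence partial weight — information that SNV
deliberately removes), and a small per-orientation factor `o ~ N(1, 0.01)`
(orientation was reported not to matter; the default effect is small).
Component absorptivities are baselines plus Gaussian bands: protein at
1500 (weak), 1918, 2008, 2062, 2272 nm; water at 1450 and 1936 nm; starch
at 1200, 1580, 2100, 2320 nm; the tray has a broad resonance at 1186 nm on
a high baseline, giving tray absorbance ≥ 0.9 at the segmentation band and
≈ kernel-level absorbance elsewhere. The kernel/tray boundary is blended
over ~2.5 px (a penumbra), with the tray level chosen so the 0.9 threshold
crossing sits at the geometric ellipse boundary — recovered areas then
match planted areas to a few percent.

**Noise and artifacts.** Raw counts are `black + (white − black)·10^(−A)`
plus Gaussian count noise (sd 80 at a white level of 40000; reference
frames average 100 acquisitions). Multiplicative (±5 %) and additive
(±0.02 AU) scatter are smooth random fields (5 px correlation) common to
all bands — physical scatter varies at kernel scale, not pixel scale.
Spikes corrupt single (line, sample, band) cells by ±0.6–1.5 AU at a rate
of 2·10⁻⁶ per cell and are registered with their clean values and the local
absorbance-equivalent noise sd (floored at the scene's median-radiance
figure) so repair accuracy is measurable. A smooth per-spectrum "structure
noise" (sd 0.004 AU, 60 nm correlation) represents kernel-to-kernel
biochemical variation outside the three-component mixture; it is what makes
the restricted 1000–1700 nm study measurably worse than the full range, as
observed on real instruments where protein information below 1700 nm is
weak. Reference protein values carry N(0, 0.4 %) Dumas repeatability —
this, not spectral noise, is the floor on achievable RMSEP
(`grainspec.noise_floor`).

**Fast path.** `simulate_spectra_table` produces kernel-mean spectra
without rendering images: since the rendered patch depends on position only
through the normalised radius, the kernel mean over the segmentable support
equals a 1-D radial integral (including the partial tray contribution of
edge pixels). Residual kernel-mean scatter and count noise are added with
variances attenuated by the effective number of independent scatter patches
and the pixel count. With artifacts off the fast path matches rendered +
extracted means to ~0.01 AU (pixelisation of the dome and support set is
the remaining difference); calibration-scale studies use it, image-level
tests use full renders.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: germ/endosperm substructure (only an optional
linear protein ramp), touching kernels, temporal drift between scans,
wavelength-dependent detector noise, batch-level protein clustering, and
any non-Beer–Lambert radiative transfer. Real-data RMSEP/R² will be worse
than the synthetic figures; the published-table identity checks are
consistency checks, not reproductions.

## Pipeline choices

- **References per detector column.** Black/white frames are applied per
  (sample, band), matching push-broom geometry where each frame column is a
  fixed detector element.
- **Reflectance floor.** `A = log10(1/max(R, 1e-4))`; floored pixels are
  counted and reported. No clipping at the reflectance stage.
- **Spike detection** follows the neighbour-median rule: per band, flag
  `|x − median₃ₓ₃(x)| > k · max(1.4826·MAD_band, 0.025)` with k = 6. The
  absolute floor (0.025 AU) keeps the threshold meaningful when a band's
  pooled MAD underestimates local noise (kernel pixels are far quieter than
  dark-tray pixels) and on noise-free data. **Repair** interpolates across
  the pixel's unflagged bands rather than substituting the spatial median:
  scenes are smooth in wavelength everywhere, whereas the spatial median is
  biased by construction at kernel/tray boundaries, where mixed-class
  windows would make accurate repair impossible. Repair is a fixed point
  under re-application, and only reported cells are ever modified.
- **Segmentation** is the strict single-band rule A(1186 nm) < 0.9 at the
  nearest grid band (no interpolation). Components are 8-connected; objects
  under 20 px are dropped as debris (a kernel at 0.109 mm/px spans
  thousands of pixels). Rows are found by splitting sorted centroid line
  coordinates at the largest gaps; indexing is reading order. Touching
  kernels are not split — a documented limitation consistent with spaced
  tray layouts.
- **Pretreatments.** "Normalisation" and "baseline" have selectable modes
  (defaults unit-area and offset-min) since the original software's exact
  definitions are not recoverable; de-trend defaults to order 2;
  Savitzky–Golay uses polyorder 2 for the 5-point window, derivative in
  per-band-index units (the grid is ~uniform; constant factors are absorbed
  by the regression), and one-sided polynomial edge handling to preserve
  band count for per-pixel mapping. The MSC training mean is frozen into
  the serialised spec at fit time.
- **PLS protocol.** Grain-level 80/20 split; 10 random grain-blocked CV
  folds choose the component count (A ≤ 20) by minimum RMSECV, ties within
  1e-9 resolved to the smallest A. Degenerate deflation raises (or
  truncates, inside CV). Outlier screening uses the standard leverage
  `h = 1/N + Σₐ tₐ²/(tₐᵀtₐ)` against `3·(A+1)/N` plus |standardised
  residual| > 3; flags are reported, never silently applied, one removal
  round at most. The slope is predictions regressed on references. R² is
  1 − SSE/SS_tot; with that convention R² = 1 − (RMSE/SD_n)² holds exactly
  (population SD), and RPD uses the sample SD — the hair between the two is
  far below printed precision at study sizes.
- **Prediction mapping.** Default aggregation is spectrum-mean (how the
  calibration was trained); pixel-mean is provided for map-style figures,
  and the two provably coincide for linear pretreatments only.
  Out-of-range pixel predictions are kept and counted, clipped only in
  rendering.
- **ENVI I/O** is implemented in-package (plain-text header + flat binary;
  BIL/BIP/BSQ, little/big endian, uint8/16/32, int16/32, float32/64); raw
  counts are written uint16, calibrated stages float32.

## Numerical notes

- Cubes are float32 in memory (absorbance resolution ~3e-8, far below every
  tolerance used); kernel means and all regression algebra are float64.
- The despiking median is an exact window median via partition, replicated
  edges.
- Truncated-normal sampling is by rejection, exact to the bounds.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical config + seed reproduces cubes and
  tables bit for bit.

## Problem sizes

Unit tests run on reduced scenes (64–128 bands, 4–12 kernels) that keep the
full physics; acceptance-grade checks use the default instrument geometry
(256 bands, 11 kernels/scene, 20 scenes for segmentation/spike statistics)
and a calibration study of 40 batches × 10 kernels × 2 orientations
(800 spectra), with batch-mean recovery on 4 × 100 kernels. These sizes
give stable statistics (≥600 planted spikes, ~3-decimal stability on rates)
while a full run stays in the minutes range on one CPU.
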