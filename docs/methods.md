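# Methods

This note documents the models, algorithms and numerical choices behind
`marginspec`, and what the synthetic-data experiments do and do not show.

## The analysis problem

Hyperspectral FT-IR and Raman maps of excised salivary-gland tissue yield
thousands of pixel spectra per section, labeled only at the tissue level
(tumor vs healthy margin). The discrimination pipeline pools all pixel
spectra per modality, reduces them with PCA, and classifies on the first
principal-component score. The scientific subtlety is that the margin is
not chemically uniform: adipose lipid domains scattered through it produce
a long right tail in lipid content. Pooled PCA then "sees" lipid variance
first, which is a within-margin effect, not a tumor/margin effect. The
package's central operation is therefore a *lipid filter*: score every
spectrum by its ester-carbonyl band integral and drop the lipid-rich tail
before the second PCA pass.

## Preprocessing

Stage order is fixed: SNR rejection → despiking (Raman) → Savitzky–Golay →
rubberband → area normalization.

* **SNR screening.** The statistic is (peak amplitude of the strongest
  band) / (robust noise). Amplitude is the maximum of the smoothed,
  hull-corrected spectrum; because the maximum-over-channels of smoothed
  pure noise sits about two noise SDs above zero, that elevation is
  subtracted so a signal-free spectrum scores near 0 rather than ~3.
  Noise is 1.4826 × MAD of the linearly detrended intensity in a
  signal-free window (defaults 1800–2600 cm⁻¹ FT-IR, 1800–2500 cm⁻¹
  Raman — both inside the spectroscopically silent region). Default
  threshold `snr_min = 3`. If the noise estimate underflows (noiseless
  synthetic input) the SNR is +∞ and the spectrum is retained.
* **Savitzky–Golay.** `scipy.signal.savgol_filter` with `mode="interp"`:
  interior points are the center values of local least-squares polynomial
  fits; the first/last half-window is evaluated from the terminal window's
  fit, so the axis length never shrinks. Defaults: window 13 / order 5
  (FT-IR), 7 / 3 (Raman). Tests verify polynomial reproduction and
  equivalence with an explicit per-point refit oracle.
* **Rubberband baseline.** The lower convex hull of the
  (wavenumber, intensity) points, built by a monotone-chain scan in
  physical wavenumber coordinates (robust to non-uniform axes), linearly
  interpolated between hull vertices and subtracted. The corrected
  spectrum is non-negative and exactly zero at every hull vertex,
  including both endpoints; re-applying the correction is the identity.
  Verified against an O(n²) "highest chord below all points" oracle.
* **Cosmic-ray removal (Raman).** Candidate jumps are flagged by the
  modified z-score (0.6745·(d − median)/MAD) of the first differences,
  threshold 8. A spike is an up-jump matched by an opposite-signed jump
  within two channels; the bracketed one- or two-channel run is replaced
  by linear interpolation of its flanks. The pairing rule is what protects
  genuine bands: a band at least five points wide never has opposite
  extreme jumps two channels apart (at realistic noise floors), so it is
  left untouched — a property the tests assert directly.
* **Area normalization.** Trapezoidal integral over the axis scaled to 1.
  After this step all band integrals are in "fraction of total spectral
  area × cm⁻¹" units, which is what makes the 0.014 filter threshold
  transferable between spectra.

## Lipid quantification and filtering

The ester band is integrated over the closed window [1710, 1790] cm⁻¹
with a local linear baseline (the chord joining the window endpoints)
subtracted — the window isolates the triacylglycerol C=O stretch from the
Amide I band at 1656 cm⁻¹. The integral can be slightly negative for
noise-only windows; that is intentional (an unbiased local estimate).
Spectra with integral > 0.014 are removed; the FT-IR threshold is the only
published cutoff, and the Raman model uses the same value, which on the
calibrated Raman model removes only the extreme tail. Distribution
summaries report mean, median, max, the center of the most populated of 50
histogram bins as the mode, and adjusted Fisher–Pearson sample skewness.

## Discrimination

PCA is fitted on the pooled two-class matrix, mean-centered, unscaled,
with a deterministic full SVD. Eigenvector sign ambiguity is fixed in two
steps: every component is oriented so its largest-magnitude loading element
is positive, then PC1 is re-oriented so the margin class has the larger
mean score. AUC is computed from the ROC threshold sweep on PC1 with
margin as the positive class and is *not* folded to max(AUC, 1−AUC): a
value below 0.5 would be reported as such. Loading features are local
extrema (scipy `find_peaks`, prominence ≥ 0.02 by default) split by sign
and annotated from a static band table (nearest entry within ±8 cm⁻¹,
otherwise "unassigned"). Defaults: k = 10 components, full preprocessed
axis; both were left at these values because the analysis only consumes
PC1 and the axis is already normalized.

## Synthetic tissue model

Each spectrum is a non-negative mixture of unit-area pseudo-Voigt
component bases (storage lipid, membrane phospholipid, random-coil
protein, β-sheet protein, carbohydrate, nucleic acid) plus a low-order
polynomial background, additive Gaussian noise, a per-spectrum intensity
scale multiplying signal, background and noise alike (thickness/focus
variation — area normalization cancels it exactly), and, for Raman,
Poisson-count cosmic-ray spikes of width 1–2 channels.

Class structure:

* **Tumor**: lipid weight ~ Normal(0.012, 0.009) truncated at 0 — narrow,
  near-zero ester integrals (|skewness| < 0.5).
* **Margin**: a two-component mixture. Lipid-poor pixels draw from a
  lognormal matched to the tumor level ("areas of lipid content similar to
  the tumor"); with probability `p_rich` = 0.20 (FT-IR) a pixel lies in a
  lipid domain and draws a large weight from a scaled Beta distribution.
  Domains are spatially contiguous: a Gaussian random field on the map
  grid (default 32×32 pixels, smoothing 2.5 px) is thresholded at the
  exact per-map quantile, so the rich fraction is held fixed while the
  domains form blobs, as adipose tissue does.
* **Composition contrasts**: the tumor gains carbohydrate and random-coil
  protein weight, the margin gains β-sheet protein weight. These offsets
  are small relative to the lipid variance, so the unfiltered FT-IR PCA is
  lipid-dominated and weak, while the filtered PCA separates the classes
  almost perfectly — the mechanism under test.
* **Membrane phospholipid** is a separate component sharing the CH
  stretch/bend bands but lacking the strong ester carbonyl. Its
  class-independent variation adds lipid-axis PC1 variance to *both*
  classes without moving the 1746 cm⁻¹ integral; it is the knob that sets
  the margin/tumor PC1 SD ratio near 5 while keeping every tumor integral
  below the filter cutoff.

The FT-IR and Raman default models are calibrated (fixed seed, n = 2000
per class) so the pipeline reproduces the headline statistics: margin
ester-integral mean ≈ 0.016 and maximum ≈ 0.11 with positive skewness; no
tumor spectrum above the 0.014 cutoff; margin/tumor PC1 SD ratio ≈ 5;
unfiltered FT-IR AUC ≈ 0.60 vs ≥ 0.99 filtered; Raman unfiltered AUC
≈ 0.97. `calibrate_model` exposes the calibration procedure itself: a
deterministic coordinate search pairing each target statistic with one
scalar knob (rich-component scale ↔ margin mean, poor-component median ↔
margin median, p_rich ↔ retained fraction, noise ↔ SD ratio, ...) and
updating multiplicatively until all requested targets sit within a 15%
relative tolerance.

### What the printed statistics cannot jointly satisfy

Three published FT-IR statistics are mutually inconsistent under equal
class sizes and the single-band 0.014 cutoff, and the calibration had to
choose. (a) A margin median of 0.009 (< 0.014) forces at least half the
margin — hence ≥ 75% of all spectra — to survive the filter, so a
retained fraction of 67% is unreachable. (b) Conversely, any margin
fraction *f* above the cutoff sits far above every tumor spectrum on a
lipid-dominated PC1 whenever the SD ratio is ~5, bounding the unfiltered
AUC below by f + (1−f)/2; AUC ≈ 0.60 therefore caps *f* at ~0.2 and the
retained fraction at ~0.90. The calibration prioritizes the paired AUC
contrast (0.60 → ≥0.99), the SD ratio and the margin mean/max; as a
consequence the default model retains ≈ 90% of spectra at the 0.014
cutoff and its margin median sits near 0.001 rather than 0.009. These two
quantities are reported as measured, not adjusted.

## What passing tests show — and what they do not

The generator reproduces the *statistical mechanism* (lipid-domain
heterogeneity masking a small compositional contrast), not tissue physics:
no scattering or Mie distortion, no atmospheric interference, no
patient-level hierarchical variation (every map is exchangeable), and
band shapes are idealized pseudo-Voigts on a smooth polynomial background.
Passing the acceptance checks therefore demonstrates that the pipeline's
operators are correct and that the two-pass design behaves as published
under the modeled conditions; it does not certify performance on real
tissue maps.

## Numerical details and edge cases

* All window specifications are closed intervals in cm⁻¹; axes are stored
  strictly ascending (descending files are reversed on read).
* Problem sizes: acceptance runs use 1000 spectra/class (FT-IR: 726-point
  axis, Raman: 2701-point axis); unit tests use 80–400 spectra/class.
* PCA on a zero-variance matrix raises a degeneracy error; an SD ratio
  with zero tumor variance is reported as undefined (`None`), not ∞.
* The lipid filter warns (rather than fails) if a class is emptied;
  retained fractions are computed over the whole dataset.
* Rubberband correction clips residuals at 0 to absorb ~1e-16-level
  round-off below the hull.
* Seeds: every sampled quantity derives from one `numpy.random.Generator`
  seeded from the run configuration; identical seeds give bit-identical
  datasets and reports.
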