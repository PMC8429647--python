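# marginspec

Vibrational-spectroscopy discrimination of salivary-gland tumor tissue
(pleomorphic adenoma) from its healthy resection margin, for spectroscopists
and computational pathologists working with FT-IR or Raman hyperspectral
tissue maps.

The healthy margin is chemically heterogeneous at the micro scale: it mixes
adipose **lipid domains** (strong ester C=O band at 1746 cm⁻¹ and CH-stretch
bands at 2854/2924 cm⁻¹) with lipid-poor areas whose composition resembles
the tumor. That heterogeneity can dominate a pooled principal-component
analysis and mask the genuine tumor/margin contrast in proteins and
carbohydrates. `marginspec` implements the complete two-pass analysis:

1. **Preprocessing** — low-SNR rejection, Savitzky–Golay smoothing (13
   points / order 5 for FT-IR, 7 / 3 for Raman), rubberband (lower convex
   hull) baseline correction, cosmic-ray despiking (Raman) and
   area-under-the-curve normalization.
2. **Lipid-domain quantification** — per-spectrum, locally baselined
   trapezoidal integral *I* of the ester band over [1710, 1790] cm⁻¹, with
   per-class distribution summaries (mean, median, max, mode, skewness,
   histogram).
3. **Lipid filtering** — spectra with *I* > 0.014 (post-normalization
   units) are removed before the second pass.
4. **Discrimination** — pooled mean-centered PCA; the PC1 score *t*₁ of
   each spectrum is the classification axis (sign convention: margin mean ≥
   tumor mean). Performance is the ROC AUC of a threshold sweep on *t*₁,
   which equals the Mann–Whitney statistic
   P(*t*₁ margin > *t*₁ tumor) + ½ P(tie). PC1 loading extrema are
   extracted and annotated from a built-in band-assignment table.

Because the study's tissue spectra are not publicly deposited, the package
ships a calibrated synthetic tissue generator (`marginspec.synthetic`) that
reproduces the statistical structure the analysis depends on — a
homogeneous lipid-poor tumor class and a margin class with blob-shaped
lipid domains on the map grid — so the entire pipeline can be exercised and
tested end to end.

## Worked example

```python
from marginspec import RunConfig, run_filtered_analysis

report = run_filtered_analysis(RunConfig(modality="ftir", seed=1, n_per_class=500))
print(report["auc_full"], report["auc_filtered"],
      report["full"]["group_summary"]["sd_ratio"])
```

Running `python examples/03_ftir_two_pass_discrimination.py` prints:

```
full dataset   : AUC=0.612  SD ratio (margin/tumor)=5.46
lipid-filtered : AUC=0.993  (retained 90.0%)

full-dataset PC1 loading features (sign: margin-positive):
  negative   1048 cm^-1  carbohydrate
  positive   1164 cm^-1  lipid
  ...
  negative   1656 cm^-1  protein
  positive   1748 cm^-1  lipid
  positive   2852 cm^-1  lipid
  positive   2924 cm^-1  lipid
```

Reading: on the full dataset the margin's lipid domains dominate PC1 — the
margin score spread is ~5× the tumor's, and a PC1 threshold is barely
better than chance (AUC 0.61). Removing the lipid-rich spectra lets the
protein/carbohydrate contrast carry PC1 and the AUC jumps to 0.99. The
loading plot tells the same story: positive (margin-side) features are
lipid bands, negative (tumor-side) features are the carbohydrate 1047 cm⁻¹
and Amide I/II bands. The other examples cover preprocessing, band-integral
statistics, the Raman analysis (AUC ≈ 0.97 even without filtering) and file
I/O.

A thin CLI wraps the same pipeline:

```sh
marginspec filtered --modality ftir --seed 1 --n-per-class 500 --out out/
marginspec repro --seed 1 --out out/         # both modalities, headline table
```

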