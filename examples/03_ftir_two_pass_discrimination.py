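"""The central FT-IR result: weak PC1 discrimination on the full dataset,
near-perfect discrimination after removing lipid-rich spectra.

On the full dataset PC1 is dominated by the margin's lipid heterogeneity, so
the margin score spread is ~5x the tumor spread and a PC1 threshold barely
beats chance.  After the ester-band filter, the protein/carbohydrate
contrast carries PC1 and the AUC rises above 0.99.
"""

from marginspec import RunConfig, run_filtered_analysis

report = run_filtered_analysis(RunConfig(modality="ftir", seed=1, n_per_class=500))

full = report["full"]
print(f"full dataset   : AUC={report['auc_full']:.3f}  "
      f"SD ratio (margin/tumor)={full['group_summary']['sd_ratio']:.2f}")
print(f"lipid-filtered : AUC={report['auc_filtered']:.3f}  "
      f"(retained {report['retained_fraction']:.1%})")

print("\nfull-dataset PC1 loading features (sign: margin-positive):")
for f in full["loading_features"]:
    if f["magnitude"] > 0.02:
        print(f"  {f['sign']:8s} {f['wavenumber']:6.0f} cm^-1  {f['assignment']}")
print("\npositive features are lipid bands (margin side); negative features"
      "\nare the protein/carbohydrate bands enriched in the tumor.")
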