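"""Raman counterpart: despiking and lipid-to-protein-ratio discrimination.

Raman maps carry cosmic-ray spikes, removed before smoothing.  Unlike FT-IR,
the Raman PC1 separates the classes well even without lipid filtering,
because the modality is very sensitive to the overall lipid level.
"""

from marginspec import RunConfig, run_filtered_analysis

report = run_filtered_analysis(RunConfig(modality="raman", seed=2, n_per_class=400))

print(f"cosmic-ray spikes removed: {report['preprocess']['n_spikes_removed']}")
print(f"full dataset   : AUC={report['auc_full']:.3f}")
print(f"lipid-filtered : AUC={report['auc_filtered']:.3f} "
      f"(retained {report['retained_fraction']:.1%})")
print("\nboth AUCs are high and nearly equal: Raman discrimination rests on"
      "\nthe lipid-to-protein ratio and survives removal of the lipid-rich"
      "\ntail.")
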