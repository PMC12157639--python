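"""Cross-modal concordance: tissue burden correlations vs TDP-43 knockdown.

Runs both arms end to end on synthetic data: (tissue) Spearman correlation
of every protein against the cumulative CE burden score; (neuron) the
knockdown-vs-control proteome with technical-replicate averaging,
downshifted-normal imputation and Welch t-tests.  Proteins significant in
both arms (FDR < 0.1) with matching effect signs are concordant — the
generator plants 60 concordant-down (STMN2-like losses) and 40
concordant-up proteins, and the classifier recovers them.
"""

import ceburden as cb
from ceburden import synthetic as syn

meta, traits, truth = syn.generate_cohort(n_subjects=90, seed=5)
spec = syn.ModuleSpec(n_features=2000, module_sizes=(100, 80, 70, 50, 40, 30),
                      burden_assoc=(0.6, -0.6, 0, 0, 0.4, 0))
prot = syn.generate_proteome(meta, truth, spec, seed=5)
kd = syn.generate_kd_proteome(truth, n_per_group=4, seed=55)

# tissue arm
ct = syn.generate_ct_table(meta, truth, seed=5)
ce = cb.ce_matrix_from_ct(ct, list(meta.index[meta["group"] == "Control"]))
tissue = cb.spearman_burden(prot.biological().values, cb.burden_score(ce))
print(f"tissue arm: {int((tissue['q'] < 0.1).sum())} of {len(tissue)} proteins "
      "correlate with the burden score at FDR < 0.1")

# knockdown arm
averaged = cb.average_technical_replicates(kd, kd.annot["sample"].to_dict())
imputed = cb.perseus_impute(averaged, seed=5)
kd_res = cb.kd_differential(imputed)
counts = kd_res.table["class"].value_counts()
print(f"knockdown arm: {counts.get('increased', 0)} increased, "
      f"{counts.get('decreased', 0)} decreased (q < 0.05)")

# synthesis
conc = cb.classify_concordance(kd_res, tissue, alpha=0.1,
                               ce_gene_flags=truth.ce_gene_flags)
print("\nconcordance classes:", conc["class"].value_counts().to_dict())

pred = set(conc.index[conc["class"] == "concordant_down"])
true = set(truth.features.index[truth.features["concordant"] == "down"])
tp = len(pred & true)
print(f"concordant-down recovery: precision {tp / max(len(pred), 1):.2f}, "
      f"recall {tp / len(true):.2f} against the planted set")
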