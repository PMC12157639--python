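# ceburden

Cryptic-exon burden analysis for TDP-43 proteinopathy cohorts.

When TDP-43 loses its nuclear splicing-repressor function — as it does in
limbic-predominant age-related TDP-43 encephalopathy (LATE) and in a large
fraction of Alzheimer's disease — non-conserved *cryptic exons* (CEs) are
spliced into transcripts such as *STMN2* and *UNC13A*.  Their abundance is
a molecular readout of TDP-43 dysfunction that antibody-based pathology
staging does not capture.  `ceburden` implements the full analysis chain
that turns this readout into molecular subtypes and proteomic correlates:

- **ce_quant** — qPCR Ct → log2 relative CE expression by the ΔΔCt scheme:
  ΔCt = Ct_CE − geomean(Ct_RPLP0, Ct_GAPDH, Ct_CYC1), centered on the
  control group; output is −ΔΔCt so more expression is larger.
- **subtyping** — cumulative **CE Burden Score** (subjects ranked 1…n
  within each of 8 CE assays, ranks summed) and unsupervised hierarchical
  stratification into low / intermediate / high CE subtypes, PCA-validated.
- **preprocess** — TAMPOR median polish of log2 ratios to internal
  reference (GIS) channels, 50%-missingness filtering, iterative
  sample-connectivity outlier removal, and bootstrap regression that
  removes age/sex/PMI/batch variance while protecting diagnosis.
- **diffstats** — biweight midcorrelation (bicor), fast one-way ANOVA and
  Welch volcano contrasts with Benjamini–Hochberg correction, Spearman
  protein-vs-burden association, and the CE-transcript directional sign
  test.
- **network** — signed weighted co-expression network: a_ij =
  ((1+bicor)/2)^β with β = 24.5, topological overlap, dynamic hybrid tree
  cut (deepSplit 2, minimum module size 15, PAM stage), module
  eigenproteins, merge at 0.07, kME, module–trait and module–subtype
  statistics.
- **enrichment** — one-tailed Fisher exact tests of modules against GMT
  gene-set collections (cell-type markers, ontologies).
- **integration** — TDP-43-knockdown neuronal proteome arm (technical
  replicate averaging, downshifted-normal imputation, per-protein t-tests)
  and cross-modal concordance: proteins significant in both arms
  (FDR < 0.1) with matching effect signs are concordant-up/-down.
- **synthetic** — generators for every input (cohort, Ct table, multi-batch
  proteome with GIS channels, knockdown proteome) with planted ground truth
  so each stage is testable without human tissue data.

The package is used from Python; `examples/` contains one short narrative
script per capability.

## Worked example

```python
import ceburden as cb
from ceburden import synthetic as syn

meta, traits, truth = syn.generate_cohort(n_subjects=90, seed=2, separation_sd=4.0)
ct = syn.generate_ct_table(meta, truth, seed=2)
controls = list(meta.index[meta.group == "Control"])

ce = cb.ce_matrix_from_ct(ct, controls)          # 90 subjects x 8 CEs
burden = cb.burden_score(ce)                     # rank-sum score in [8, 720]
result = cb.assign_subtypes(ce, k=3)
print(result.labels.value_counts().to_dict())
print(result.ordering_stat.round(1).to_dict())
```

prints

```
{'low': 43, 'high': 29, 'intermediate': 18}
{'low': 176.1, 'intermediate': 419.7, 'high': 608.0}
```

— 43 subjects fall in the low-CE band, and the naming rule orders the
subtypes by mean burden score (low 176 < intermediate 420 < high 608 on
the 8…720 scale), mirroring the low/intermediate/high banding seen in
TDP-43 proteinopathy cohorts.  Running `examples/02_...py` additionally
reports the adjusted Rand index against the generator's planted subtype
labels (0.885 at 4-SD component separation) and the PCA check (PC1 carries
essentially all CE variance, silhouette 0.67).

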