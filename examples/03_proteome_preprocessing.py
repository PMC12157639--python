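"""Normalise and covariate-adjust a multi-batch TMT-style proteome.

Simulates a proteome with a planted batch offset (+2 on batch b2) and a
protected diagnosis effect (+1 in AD+LATE), then runs the preprocessing
chain: outlier screening, TAMPOR median polish of ratios to the GIS
reference channels, the 50% missingness filter, and bootstrap covariate
regression.  The printed contrasts show the nuisance variance disappearing
while the diagnosis signal survives.
"""

import numpy as np

import ceburden as cb
from ceburden import synthetic as syn

meta, traits, truth = syn.generate_cohort(n_subjects=90, seed=3)
spec = syn.ModuleSpec(
    fixed_batch_offset={"b2": 2.0},
    fixed_group_effect={"AD+LATE": 1.0},
)
prot = syn.generate_proteome(meta, truth, spec, seed=3)
print(f"proteome: {prot.values.shape[0]} proteins x {prot.values.shape[1]} channels "
      f"({int(prot.is_reference.sum())} GIS reference channels)")

outliers, _ = cb.detect_outliers(prot.biological())
print("outlier samples flagged:", outliers or "none")

norm, trace = cb.tampor_normalize(prot)
print(f"TAMPOR converged in {trace.n_iter} iterations; "
      f"max residual sample median {np.abs(np.median(np.nan_to_num(norm.values.to_numpy()), axis=0)).max():.1e}")

filtered = cb.filter_missingness(norm.biological(), 0.5)
print(f"missingness filter: {norm.values.shape[0]} -> {filtered.values.shape[0]} proteins")

adjusted = cb.regress_covariates(filtered, n_boot=200, seed=3, annot=meta)


def contrast(m, col, a, b):
    sel_a = (meta[col] == a).reindex(m.samples).to_numpy()
    sel_b = (meta[col] == b).reindex(m.samples).to_numpy()
    return float((m.values.loc[:, sel_a].mean(axis=1)
                  - m.values.loc[:, sel_b].mean(axis=1)).mean())


print(f"batch b2-b1 contrast: raw {contrast(prot.biological(), 'batch', 'b2', 'b1'):+.2f}, "
      f"post-TAMPOR {contrast(filtered, 'batch', 'b2', 'b1'):+.2f}, "
      f"post-regression {contrast(adjusted, 'batch', 'b2', 'b1'):+.2f}  (planted +2; "
      "the GIS ratio already absorbs shared batch shifts, regression mops up the rest)")
print(f"AD+LATE-Control contrast: raw {contrast(prot.biological(), 'group', 'AD+LATE', 'Control'):+.2f}, "
      f"post-regression {contrast(adjusted, 'group', 'AD+LATE', 'Control'):+.2f}  (planted +1, protected)")
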