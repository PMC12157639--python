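# Methods

`ceburden` implements a cryptic-exon (CE) burden analysis pipeline for
TDP-43 proteinopathy cohorts: relative CE quantification from qPCR,
molecular subtyping and cumulative burden scoring, multiplexed-proteome
normalisation and covariate adjustment, signed co-expression network
analysis, gene-set enrichment, and cross-modal concordance against a
TDP-43-knockdown neuronal proteome.  Every stage runs end to end on
synthetic data with planted ground truth; this note records the models, the
defaults and why, the numerical choices, and what the synthetic tests do
and do not establish about real data.

## Relative CE quantification (ddCt)

Cycle thresholds for the eight CE assays (STMN2, UNC13A, ELAVL3, KALRN,
ARHGAP32, CAMK2B, PFKP, SYT7) are normalised per subject by subtracting the
geometric mean of the housekeeping Ct values (RPLP0, GAPDH, CYC1) — the
geometric mean is taken over the Ct values themselves, not over linearised
expression.  Subtracting the control-group mean ΔCt per assay gives ΔΔCt;
the package reports −ΔΔCt (log2 relative expression), so more CE expression
is numerically larger.  Control-column means are therefore exactly zero, a
property asserted to 1e−12.  Undetermined wells propagate as missing by
default; an optional Ct cap (e.g. 40) substitutes a detection-limit value.

## Burden score and molecular subtyping

The cumulative CE Burden Score ranks subjects 1 (lowest) to n (highest)
within each assay (average ranks on ties) and sums the eight ranks, giving
a score in [8, 8n] that is invariant to any strictly monotone per-assay
transform.  An independent two-loop rank-sum oracle reproduces it exactly.

Subtypes come from unsupervised hierarchical clustering (Ward linkage,
Euclidean distance, raw log2 values — a z-score option exists for heatmap
parity) cut at k=3 and named low/intermediate/high by ascending mean burden
score.  Because a bare k-cluster tree cut places band boundaries poorly on
cohorts whose burden distribution is unbalanced, the default adds a
deterministic band refinement: the tree-cut clusters locate band centers on
the mean-CE-expression axis, and subjects are re-binned at the midpoints
between adjacent centers, iterating center/boundary updates to a fixed
point (a 1-D Lloyd refinement seeded by the dendrogram).  This replaces the
"inspect the dendrogram and bin by expression level" step of manual
practice with a reproducible rule; `refine_bins=False` gives the bare cut.

## Proteome preprocessing

**TAMPOR.**  Normalisation alternates two median polishes on the log2
scale: per feature within each batch, subtract the median over that batch's
GIS reference channels (the log ratio-to-reference); then per sample,
subtract the median over features.  Iteration stops when the largest
adjustment is below `tol` (1e−8; `max_iter` 250 with a warning on
non-convergence).  On a pure row+column-offset matrix one cycle suffices
and the result is idempotent.  The batch reference median (not mean) is
used throughout, per the method's name.

**Filtering and outliers.**  Features missing in ≥50% of samples are
dropped (boundary inclusive).  Outlier screening is iterative sample
connectivity: each sample's mean pairwise Pearson correlation to the others
is standardised and samples below z = −3 are removed, repeating until
clean.  The criterion and threshold are configurable; on homogeneous
simulated cohorts the false-flag rate is under 5%.

**Covariate regression.**  Per feature, abundance ~ diagnosis (protected) +
age + sex + PMI + batch is fit by least squares on `n_boot` (default 1000)
bootstrap resamples of the samples; each covariate coefficient is the
median over resamples, and only the covariate design times those medians is
subtracted, so diagnosis-attributable variance survives.  Missing cells are
handled by per-feature 0/1 observation weights in the normal equations
(with a 1e−8 ridge for resamples that drop a dummy level) and remain
missing in the output.  Note that with nothing to remove the procedure
still subtracts coefficient sampling noise of order sd/√(samples per
level); the bootstrap median converges to the full-sample estimate, not to
zero, so "no-op" behaviour holds only up to that noise.

**Trait floor.**  Below-detection pTDP-43 values are imputed at 0.1
(roughly half the lowest detected level); observed values are untouched.

## Robust statistics

The biweight midcorrelation centers each vector at its median, weights
observations by Tukey's biweight with zero weight beyond 9 MADs, and
correlates the weighted deviations; pairs with missing entries are dropped
first, and a zero (or numerically degenerate) MAD triggers a Pearson
fallback.  The all-pairs matrix routine computes medians/MADs per column
and renormalises cross-products over jointly observed samples — a fast
approximation to the scalar pairwise-complete definition, used for network
construction; the scalar routine is the reference and is checked against an
independently coded formula oracle to 1e−10.  p-values for correlations use
the Student-t approximation t = r√((n−2)/(1−r²)) with per-pair n.

One-way ANOVA is a vectorised between/within decomposition on available
values; two-group contrasts use Welch's t (log2FC = difference of group
means).  Benjamini–Hochberg q-values implement the exact step-up definition
(min over j ≥ i of m·p_j/j, capped at 1), one family per analysis call;
features whose test cannot run are excluded from the family.  The CE-gene
directional bias test counts negative vs positive significant Spearman
correlations (protein vs burden score) among CE-transcript genes and
applies an exact two-sided binomial sign test against 0.5.

## Signed co-expression network

Adjacency is a_ij = ((1 + bicor_ij)/2)^β with β = 24.5 (anticorrelation
maps to 0; the fractional power is well-defined on the nonnegative base).
The topological overlap matrix is TOM_ij = (Σ_u a_iu a_uj + a_ij) /
(min(k_i, k_j) + 1 − a_ij) with the diagonal excluded from connectivity,
verified against a triple-loop oracle to 1e−12.  Features above 5%
missingness are excluded from the network with a warning.

Modules are cut from the average-linkage tree of 1 − TOM by an in-package
dynamic hybrid tree cut.  At β = 24.5 the TOM dissimilarities compress into
a sliver below 1 and absolute merge-height criteria become uninformative,
so the port keeps the architecture of the published method (tree-guided
candidate branches, a deep-split ladder, a PAM stage, minimum module size,
an optional static height gate) but judges branches by the similarity
structure they span:

- **split test** — a node is split where both children are internally more
  similar than they are to each other by the deep-split factor (deepSplit
  0..4 → 8/6/4/3/2; genuine module boundaries show ratios in the tens to
  hundreds because the soft power amplifies contrasts multiplicatively,
  while within-module heterogeneity stays within a small factor);
- **purification** — candidate branches drop members whose connectivity
  falls an order of magnitude below the branch's upper tier (Otsu split of
  log-connectivity), then a mild relative floor;
- **acceptance** — a purified branch becomes a module if it keeps the
  majority of its node, meets the minimum size (15), and is internally more
  similar than to the rest of the network by the acceptance factor
  (deepSplit 0..4 → 50/30/20/12/8; chance-similar noise subtrees reach only
  single-digit ratios);
- **PAM stage** — leftover features join their nearest module only if at
  least twice as similar to it as to the feature population at large, and
  at least as connected as the module's own purification floor — so
  genuinely unclustered features and sub-minimum blocks stay unassigned;
- a homogeneous network with no separable substructure collapses to a
  single module provided its mean topological overlap exceeds 1%.

Module eigenproteins are the first right-singular vectors of the z-scored
module submatrices, sign-aligned to correlate nonnegatively with the module
mean profile; kME is the bicor of each feature with each eigenprotein.
Modules whose eigenproteins differ by less than 0.07 (1 − correlation) are
merged iteratively to a fixed point, and modules are renumbered M1, M2, …
by decreasing size with 0 reserved for unassigned.  Module–trait statistics
use bicor over all samples for continuous traits and, for disease types, a
0/1 group indicator restricted to control + that group; eigenprotein
differences across CE subtypes use one-way ANOVA with pairwise Welch
annotations.

## Enrichment

Gene sets are read from GMT (duplicates collapsed, symbols upper-cased with
isoform suffixes stripped at a configurable delimiter).  Enrichment is the
one-tailed Fisher exact test, p = P(X ≥ overlap) from the hypergeometric
distribution, with a 0.5 Haldane correction on the odds ratio only when a
cell is zero.  The default background is every feature in the analysed
matrix — enrichment conditions on detectability in the proteome, not on the
genome — and BH correction spans the full module × set grid.

## Knockdown arm and concordance

Technical replicates are averaged per sample (available-case mean) before
imputation.  Missing values are then drawn per sample column from
Normal(mean − 1.8·sd, (0.3·sd)²) of that column's observed values — the
conventional downshifted-normal parameters, recorded in output metadata.
Welch t-tests per protein with BH correction classify knockdown proteins as
increased/decreased at q < 0.05.  A protein shared with the tissue arm is
concordant when significant in both (BH q < 0.1 each; a flag switches to
nominal p) with matching signs of knockdown log2FC and burden-correlation
rho, discordant when the signs differ, ns otherwise.  Tissue-side
significance is the Spearman-to-burden-score q, and concordant sets are
tested for module overlap by one-tailed Fisher tests against the shared
feature background.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study design: 90 subjects at the composition
21 Control / 10 LATE / 24 AD / 35 AD+LATE (configurable); a latent burden
from a 3-Gaussian mixture (component means 0, s, 2s with within-component
SD 1; default separation s = 2 makes recovery achievable but nontrivial,
recovery tests use s = 4) whose weights skew high in AD+LATE, low in
Control/AD and mixed in LATE; true subtype labels thresholded at the
midpoints between component means.  pTDP-43 rises with burden at a
configurable correlation (default 0.6 — related but not co-dependent), with
~8% below-detection missingness to exercise floor imputation; pTau ratio
and Aβ42 shift with AD pathology independent of burden; MMSE declines with
burden.

Ct tables follow Ct = baseline + subject shift − loading·(centered burden)
+ noise with burden-independent housekeepers (equal housekeeping means, so
the geometric mean absorbs subject shifts exactly and the zero-noise
round-trip is algebraically exact).  The proteome is a factor model: module
features load (0.6) on factors that may track burden; CE-gene features load
directly on burden, 30 negative / 5 positive at ±0.7 (CE-bearing
transcripts are typically degraded, depleting the protein); 60/40
concordant-down/-up features are planted with matching knockdown log2FCs of
magnitude 3 (TDP-43-dependent losses such as STMN2 are near-complete).
Covariate effects (age, sex, PMI, batch) use per-feature random
coefficients with fixed-value overrides for recovery tests; GIS channels
carry baseline + batch effects only.  Missingness is 5% MCAR plus 5%
intensity-dependent MNAR with a steep logistic (steepness 4), reflecting
detection-limit censoring: only genuinely low-intensity cells go missing,
which is also the regime in which downshifted imputation is approximately
correct.  The knockdown arm simulates 4 samples per group with 2 technical
replicate injections each (replicate noise 0.15, biological noise 0.3).

Passing tests on these data show that the algorithms recover planted
structure under Gaussian factor models with realistic dimensions.  They do
not establish behaviour under peptide-to-protein roll-up artefacts,
ratio-compression or reporter-ion interference, non-Gaussian heavy tails,
nested batch structures, or informative missingness that correlates with
diagnosis — none of which the generator models.

## Problem sizes in the test suite

The default suite and the acceptance script run the study-scale cohort
(n = 90) throughout, proteomes of 1,500–2,000 features, 200 replicate
rank-sum oracle draws, 300–1,000 bicor oracle pairs, 100–1,000 TOM oracle
matrices, 500-resample bootstrap regression on 600–800 features, and 5–20
replicate seeds for the stochastic recovery rates; the full suite completes
in about a minute on one CPU.

## Known limitations

- The tree cut is a behavioural port: it preserves the published method's
  inputs, parameters and semantics but not its exact branch bookkeeping, so
  module boundaries can differ from the R implementation in borderline
  cases.
- The all-pairs bicor matrix uses column-wise moments under missingness
  (per-pair recomputation is the scalar reference).
- Bootstrap covariate regression subtracts estimated coefficients; with
  covariates nearly orthogonal to diagnosis this is unbiased but carries
  sampling noise of order sd/√n per dummy level.
- No amplification-efficiency correction in qPCR, no peptide-level
  modelling, no permutation p-values, no consensus clustering.
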