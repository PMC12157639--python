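"""Knockdown-neuron arm and cross-modal concordance synthesis.

Processes the TDP-43-knockdown vs control neuronal proteome (technical
replicate averaging, downshifted-normal missing-value imputation, per-protein
Welch t-tests with BH correction) and classifies every protein shared with
the tissue analysis as concordant-up / concordant-down / discordant / ns by
combining its knockdown fold change with its tissue burden correlation.
Concordance requires significance in both datasets (FDR < 0.1 by default)
with matching effect signs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix
from .diffstats import DiffResult, bh_adjust, group_contrast
from .enrichment import fisher_enrichment
from .diffstats import star_annotation

__all__ = [
    "average_technical_replicates",
    "perseus_impute",
    "kd_differential",
    "classify_concordance",
    "concordant_module_overlap",
]

CONCORDANCE_CLASSES = ("concordant_up", "concordant_down", "discordant", "ns")


def average_technical_replicates(
    matrix: AbundanceMatrix, replicate_map: dict[str, str]
) -> AbundanceMatrix:
    """Collapse technical-replicate columns to per-sample means.

    ``replicate_map`` assigns every column to a biological sample id; the
    mean ignores missing replicates, and a sample whose replicates are all
    missing stays missing.  Group annotations carry over when consistent.
    """
    unmapped = [c for c in matrix.samples if c not in replicate_map]
    if unmapped:
        raise ValueError(f"columns without a replicate mapping: {unmapped[:5]}")
    assign = pd.Series({c: replicate_map[c] for c in matrix.samples})
    samples = list(dict.fromkeys(assign))
    out = {}
    for s in samples:
        cols = assign.index[assign == s]
        out[s] = matrix.values[cols].mean(axis=1)
    annot_rows = {}
    for s in samples:
        cols = assign.index[assign == s]
        sub = matrix.annot.loc[cols]
        annot_rows[s] = {
            c: (sub[c].iloc[0] if sub[c].nunique(dropna=False) == 1 else None)
            for c in matrix.annot.columns
        }
    annot = pd.DataFrame(annot_rows).T if matrix.annot.shape[1] else None
    if annot is not None:
        annot.index.name = "sample_id"
    return AbundanceMatrix(pd.DataFrame(out), annot)


def perseus_impute(
    matrix: AbundanceMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
    min_observed: int = 3,
) -> AbundanceMatrix:
    """Downshifted-normal imputation of missing values, per sample column.

    Missing entries in column s are drawn from
    Normal(mean_s - downshift * sd_s, (width * sd_s)^2) where mean_s and
    sd_s come from the column's observed values — mimicking the
    left-censored, low-abundance origin of most proteomic missingness.
    Observed cells are never altered; a fixed seed gives identical draws.
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.to_numpy(dtype=float).copy()
    for j, col in enumerate(matrix.samples):
        x = values[:, j]
        obs = np.isfinite(x)
        n_miss = (~obs).sum()
        if obs.sum() < min_observed:
            raise ValueError(
                f"column {col!r} has only {obs.sum()} observed values; "
                f"need {min_observed} to estimate imputation moments"
            )
        if n_miss == 0:
            continue
        mu, sd = x[obs].mean(), x[obs].std(ddof=1)
        x[~obs] = rng.normal(mu - downshift * sd, width * sd, size=n_miss)
    return AbundanceMatrix(
        pd.DataFrame(values, index=matrix.features, columns=matrix.samples),
        matrix.annot.copy(),
    )


def kd_differential(
    matrix: AbundanceMatrix,
    groups: pd.Series | None = None,
    alpha: float = 0.05,
    kd_label: str = "kd",
    control_label: str = "control",
) -> DiffResult:
    """Welch t-test per protein, knockdown minus control, BH-corrected.

    This arm is two-group by design; any other grouping is an error.  The
    class column marks proteins increased / decreased in knockdown at
    q < ``alpha``.
    """
    g = groups if groups is not None else matrix.annot["group"]
    g = g.reindex(matrix.samples)
    seen = [x for x in g.dropna().unique()]
    if len(seen) != 2:
        raise ValueError(f"knockdown differential expects exactly 2 groups, got {seen}")
    if kd_label not in seen or control_label not in seen:
        kd_label, control_label = seen[0], seen[1]
    res = group_contrast(matrix.values, g, kd_label, control_label, alpha=alpha)
    res.test = "kd_welch"
    return res


def classify_concordance(
    kd_result: DiffResult,
    burden_corr: pd.DataFrame,
    alpha: float = 0.1,
    use_q: bool = True,
    ce_gene_flags: pd.Series | None = None,
) -> pd.DataFrame:
    """Cross-modal concordance classes for proteins shared by both arms.

    A protein significant in both the knockdown contrast and the tissue
    burden correlation (BH q < ``alpha`` each, or nominal p with
    ``use_q=False``) is concordant when its knockdown log2FC and tissue rho
    share a sign, discordant when they differ; everything else is ns.
    """
    kd = kd_result.table
    shared = kd.index.intersection(burden_corr.index)
    if len(shared) == 0:
        raise ValueError("no proteins shared between knockdown and tissue results")
    kd = kd.loc[shared]
    tis = burden_corr.loc[shared]
    crit_kd = kd["q"] if use_q else kd["p"]
    crit_t = tis["q"] if use_q else tis["p"]
    sig = (crit_kd < alpha) & (crit_t < alpha)
    lfc = kd["log2fc"]
    rho = tis["rho"]
    cls = np.where(
        sig & (lfc > 0) & (rho > 0),
        "concordant_up",
        np.where(
            sig & (lfc < 0) & (rho < 0),
            "concordant_down",
            np.where(sig & (lfc * rho < 0), "discordant", "ns"),
        ),
    )
    out = pd.DataFrame(
        {
            "kd_log2fc": lfc,
            "kd_q": kd["q"],
            "tissue_rho": rho,
            "tissue_q": tis["q"],
            "class": cls,
        },
        index=shared,
    )
    if ce_gene_flags is not None:
        out["ce_gene"] = ce_gene_flags.reindex(shared).fillna(False).astype(bool)
    return out


def concordance_summary(concordance: pd.DataFrame) -> pd.Series:
    counts = concordance["class"].value_counts()
    return counts.reindex(CONCORDANCE_CLASSES, fill_value=0)


def concordant_module_overlap(
    concordance: pd.DataFrame,
    labels: pd.Series,
    module_clusters: pd.Series | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of concordant-up/-down sets in each network module.

    Background = proteins shared by both arms that carry a network label.
    One row per (direction, module); BH across the grid.
    """
    lab = labels.reindex(concordance.index).dropna().astype(int)
    background = set(lab.index)
    rows = []
    for direction in ("concordant_up", "concordant_down"):
        query = set(concordance.index[concordance["class"] == direction]) & background
        for m in sorted(x for x in lab.unique() if x > 0):
            members = set(lab.index[lab == m])
            row = fisher_enrichment(query, members, background)
            row.update({"direction": direction, "module": f"M{m}"})
            if module_clusters is not None:
                row["module_cluster"] = module_clusters.get(f"M{m}")
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["stars"] = table["p"].map(star_annotation)
    return table
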