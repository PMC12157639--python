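"""Signed weighted co-expression network construction and module analysis.

The network follows the weighted co-expression recipe on proteins: a signed
adjacency a_ij = ((1 + bicor_ij)/2)^beta (anticorrelated pairs map to 0),
topological overlap to denoise the adjacency, average-linkage clustering of
1 - TOM with a dynamic hybrid tree cut (deepSplit, minimum module size, PAM
stage), module eigenproteins (first principal component per module),
closely-related-module merging at an eigenprotein dissimilarity threshold,
kME module memberships, and module-trait / module-subtype statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffstats import CorrelationResult, DiffResult, _bicor_t_p, bh_adjust, bicor, bicor_matrix
from .treecut import cutree_hybrid

__all__ = [
    "soft_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigenproteins",
    "merge_modules",
    "module_trait_association",
    "eigenprotein_anova",
    "build_network",
    "NetworkModel",
    "EigenproteinSet",
]


@dataclass
class NetworkModel:
    beta: float
    tom: np.ndarray
    labels: pd.Series  # feature -> module id (0 = unassigned)
    linkage: np.ndarray
    adjacency: np.ndarray | None = None

    @property
    def module_sizes(self) -> pd.Series:
        counts = self.labels[self.labels > 0].value_counts().sort_index()
        return counts


@dataclass
class EigenproteinSet:
    eigenproteins: pd.DataFrame  # samples x modules (columns M1, M2, ...)
    variance_explained: pd.Series
    kme: pd.DataFrame  # features x modules


def soft_adjacency(
    expr: pd.DataFrame, beta: float = 24.5, corr: np.ndarray | None = None
) -> np.ndarray:
    """Signed soft-threshold adjacency from biweight midcorrelation.

    a_ij = ((1 + bicor_ij) / 2)^beta, so bicor -1 -> 0, 0 -> 2^-beta, 1 -> 1.
    ``expr`` is features x samples; a precomputed correlation matrix may be
    passed to avoid recomputation.  The fractional default beta is fine since
    the base is nonnegative.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if corr is None:
        corr = bicor_matrix(expr.T)
    return ((1.0 + corr) / 2.0) ** beta


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with the
    diagonal excluded from connectivity k and TOM_ii = 1.  Similar nodes with
    shared neighborhoods score high even when their direct edge is weak.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    diss_tom: np.ndarray,
    deep_split: int = 2,
    min_module_size: int = 15,
    pam: bool = True,
    cut_height: float | None = None,
    linkage: np.ndarray | None = None,
) -> np.ndarray:
    """Dynamic hybrid tree cut of the TOM dissimilarity into module labels.

    Average-linkage clustering of ``diss_tom`` followed by the branch cut;
    modules are numbered 1..k by decreasing size, 0 marks unassigned.
    """
    diss_tom = np.asarray(diss_tom, dtype=float)
    if diss_tom.shape[0] != diss_tom.shape[1]:
        raise ValueError("TOM dissimilarity must be square")
    if np.abs(np.diag(diss_tom)).max() > 1e-8:
        raise ValueError("TOM dissimilarity must have a zero diagonal")
    return cutree_hybrid(
        diss_tom,
        linkage=linkage,
        deep_split=deep_split,
        min_cluster_size=min_module_size,
        cut_height=cut_height,
        pam=pam,
    )


def _module_names(labels: pd.Series) -> list[int]:
    return sorted(int(m) for m in labels.unique() if m > 0)


def module_eigenproteins(
    expr: pd.DataFrame, labels: pd.Series, kme: bool = True
) -> EigenproteinSet:
    """First principal component summary of each module.

    Features are z-scored across samples; the module eigenprotein is the
    first right-singular vector over samples, unit-normalised and sign-flipped
    so that it correlates nonnegatively with the module's mean standardized
    profile.  kME is the bicor of every feature with every eigenprotein.
    """
    labels = labels.reindex(expr.index)
    mods = _module_names(labels)
    if not mods:
        raise ValueError("no modules to summarise")
    X = expr.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd == 0, 1.0, sd)
    Z = np.where(np.isfinite(Z), Z, 0.0)  # missing -> mean after z-scoring
    me = {}
    varexp = {}
    for m in mods:
        idx = np.flatnonzero((labels == m).to_numpy())
        if len(idx) < 2:
            raise ValueError(f"module {m} has fewer than 2 features")
        sub = Z[idx]
        _, s, vt = np.linalg.svd(sub, full_matrices=False)
        v = vt[0]
        if np.corrcoef(v, sub.mean(axis=0))[0, 1] < 0:
            v = -v
        me[f"M{m}"] = v
        varexp[f"M{m}"] = float(s[0] ** 2 / (s**2).sum())
    eig = pd.DataFrame(me, index=expr.columns)
    if kme:
        kme_vals = np.full((len(expr.index), eig.shape[1]), np.nan)
        for j, col in enumerate(eig.columns):
            v = eig[col].to_numpy()
            for i in range(X.shape[0]):
                x = X[i]
                ok = np.isfinite(x)
                if ok.sum() >= 3:
                    kme_vals[i, j] = bicor(x[ok], v[ok])
        kme_df = pd.DataFrame(kme_vals, index=expr.index, columns=eig.columns)
    else:
        kme_df = pd.DataFrame(index=expr.index, columns=eig.columns, dtype=float)
    return EigenproteinSet(
        eigenproteins=eig, variance_explained=pd.Series(varexp), kme=kme_df
    )


def merge_modules(
    expr: pd.DataFrame, labels: pd.Series, cut_height: float = 0.07
) -> pd.Series:
    """Merge modules whose eigenproteins are nearly collinear.

    Eigenproteins are clustered by 1 - cor dissimilarity (average linkage);
    modules joining below ``cut_height`` merge, eigenproteins are recomputed,
    and the procedure iterates to a fixed point.  Labels are renumbered by
    decreasing module size.
    """
    labels = labels.reindex(expr.index).astype(int).copy()
    for _ in range(20):
        mods = _module_names(labels)
        if len(mods) < 2:
            break
        eps = module_eigenproteins(expr, labels, kme=False)
        E = eps.eigenproteins.to_numpy().T  # modules x samples
        corr = np.corrcoef(E)
        diss = 1.0 - corr
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2, 0, None)
        Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
        groups = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
        if len(set(groups)) == len(mods):
            break
        mapping = {}
        for g in set(groups):
            members = [mods[i] for i in range(len(mods)) if groups[i] == g]
            target = min(members)
            for m in members:
                mapping[m] = target
        labels = labels.map(lambda l: mapping.get(l, 0))
    # renumber by decreasing size
    counts = labels[labels > 0].value_counts()
    remap = {old: new for new, old in enumerate(counts.sort_values(ascending=False).index, 1)}
    return labels.map(lambda l: remap.get(l, 0)).rename("module")


def module_trait_association(
    eigenproteins: pd.DataFrame,
    traits: pd.DataFrame | None,
    meta: pd.DataFrame | None = None,
    control_group: str = "Control",
    min_group: int = 3,
) -> CorrelationResult:
    """Module-trait and module-disease-type bicor grid.

    Continuous traits are correlated with each eigenprotein over all shared
    samples.  Disease-type associations contrast each non-control group with
    controls only: samples are restricted to control + that group, group
    membership is coded 0/1, and bicor against the eigenprotein is computed.
    Cells with under ``min_group`` samples per side are reported missing.
    """
    cols = {}
    ns = {}
    samples = eigenproteins.index
    if traits is not None:
        for t in traits.columns:
            y = traits[t].reindex(samples).to_numpy(dtype=float)
            cols[t] = y
            ns[t] = None
    grid = {}
    nuse = {}
    for name, y in cols.items():
        r, n = {}, {}
        for m in eigenproteins.columns:
            x = eigenproteins[m].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n[m] = int(ok.sum())
            r[m] = bicor(x[ok], y[ok]) if ok.sum() >= 3 else np.nan
        grid[name] = r
        nuse[name] = n
    if meta is not None and "group" in meta.columns:
        groups = meta["group"].reindex(samples)
        for g in [g for g in groups.dropna().unique() if g and g != control_group]:
            r, n = {}, {}
            mask = (groups == control_group) | (groups == g)
            ind = (groups == g).astype(float)
            ok_samples = mask.to_numpy()
            if (groups[ok_samples] == g).sum() < min_group or (
                groups[ok_samples] == control_group
            ).sum() < min_group:
                grid[f"{g}_vs_{control_group}"] = {
                    m: np.nan for m in eigenproteins.columns
                }
                nuse[f"{g}_vs_{control_group}"] = {m: 0 for m in eigenproteins.columns}
                continue
            r = {}
            n = {}
            for m in eigenproteins.columns:
                x = eigenproteins[m].to_numpy(dtype=float)[ok_samples]
                y = ind.to_numpy()[ok_samples]
                n[m] = int(len(x))
                r[m] = bicor(x, y)
            grid[f"{g}_vs_{control_group}"] = r
            nuse[f"{g}_vs_{control_group}"] = n
    coef = pd.DataFrame(grid)
    nmat = pd.DataFrame(nuse).astype(float)
    p = pd.DataFrame(
        _bicor_t_p(coef.to_numpy(), nmat.to_numpy()), index=coef.index, columns=coef.columns
    )
    p = p.where(coef.notna())
    return CorrelationResult(coefficient=coef, p_value=p, n_used=nmat, method="bicor")


def eigenprotein_anova(eigenproteins: pd.DataFrame, subtype_labels: pd.Series) -> DiffResult:
    """One-way ANOVA of each module eigenprotein across CE-burden subtypes."""
    labels = subtype_labels.reindex(eigenproteins.index)
    if labels.isna().any():
        raise ValueError("subtype labels must cover all eigenprotein samples")
    groups = [g for g in labels.unique()]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 subtypes")
    rows = {}
    for m in eigenproteins.columns:
        vals = [eigenproteins.loc[labels == g, m].to_numpy() for g in groups]
        if any(len(v) < 2 for v in vals):
            raise ValueError("each subtype needs at least 2 samples")
        if all(np.allclose(v, vals[0].mean()) for v in vals):
            F, p = 0.0, 1.0
        else:
            F, p = stats.f_oneway(*vals)
        row = {"stat": float(F), "p": float(p)}
        for i in range(len(groups)):
            row[f"mean_{groups[i]}"] = float(np.mean(vals[i]))
            for j in range(i + 1, len(groups)):
                t = stats.ttest_ind(vals[i], vals[j], equal_var=False)
                row[f"p_{groups[i]}_vs_{groups[j]}"] = float(t.pvalue)
        rows[m] = row
    table = pd.DataFrame(rows).T
    table["q"] = bh_adjust(table["p"].to_numpy())
    return DiffResult(table=table, groups=list(groups), test="anova")


def build_network(
    expr: pd.DataFrame,
    beta: float = 24.5,
    deep_split: int = 2,
    min_module_size: int = 15,
    merge_height: float = 0.07,
    pam: bool = True,
    keep_adjacency: bool = False,
    max_missing: float = 0.05,
) -> tuple[NetworkModel, EigenproteinSet]:
    """Full network pipeline: bicor -> adjacency -> TOM -> cut -> merge -> MEs.

    Features missing in more than ``max_missing`` of samples are excluded
    from the network with a warning (pairwise-complete bicor degrades there).
    """
    frac = expr.isna().mean(axis=1)
    if (frac > max_missing).any():
        import warnings

        n_bad = int((frac > max_missing).sum())
        warnings.warn(
            f"excluding {n_bad} features above {max_missing:.0%} missingness from the network"
        )
        expr = expr.loc[frac <= max_missing]
    A = soft_adjacency(expr, beta=beta)
    tom = topological_overlap(A)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    Z = hierarchy.linkage(squareform(np.clip(diss, 0, None), checks=False), method="average")
    raw = detect_modules(
        diss, deep_split=deep_split, min_module_size=min_module_size, pam=pam, linkage=Z
    )
    labels = pd.Series(raw, index=expr.index, name="module")
    labels = merge_modules(expr, labels, cut_height=merge_height)
    eps = module_eigenproteins(expr, labels) if (labels > 0).any() else None
    model = NetworkModel(
        beta=beta,
        tom=tom,
        labels=labels,
        linkage=Z,
        adjacency=A if keep_adjacency else None,
    )
    return model, eps
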