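"""Robust correlation and differential-abundance statistics.

Implements the biweight midcorrelation (bicor) used throughout the pipeline,
feature-by-trait correlation grids with Student-t p-values, fast one-way ANOVA
and Welch two-group contrasts with Benjamini-Hochberg correction, Spearman
correlation of the proteome against the cryptic-exon burden score, and the
directional sign test for cryptic-exon-transcript proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bicor",
    "bicor_matrix",
    "correlate_grid",
    "anova_bh",
    "group_contrast",
    "spearman_burden",
    "ce_gene_bias",
    "bh_adjust",
    "star_annotation",
    "CorrelationResult",
    "DiffResult",
]

#: Tukey biweight tuning constant: observations beyond this many MADs from the
#: median receive zero weight (the standard published constant).
BIWEIGHT_MADS = 9.0


@dataclass
class CorrelationResult:
    """Feature-by-target correlation grid with pairwise-complete bookkeeping."""

    coefficient: pd.DataFrame  # features x targets
    p_value: pd.DataFrame
    n_used: pd.DataFrame
    method: str = "bicor"
    q_value: pd.DataFrame | None = None

    def stars(self) -> pd.DataFrame:
        return self.p_value.map(star_annotation)


@dataclass
class DiffResult:
    """Per-feature differential statistics (ANOVA or two-group contrast)."""

    table: pd.DataFrame  # columns: estimate/log2fc, stat, p, q, class, ...
    groups: list[str] = field(default_factory=list)
    test: str = "anova"


def star_annotation(p: float) -> str:
    """Conventional significance stars at 0.05 / 0.01 / 0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values stay NaN.

    q_i = min_{j: p_j >= p_i} (m * p_j / rank_j), capped at 1 — the exact
    step-up definition.  Features whose test could not be run (NaN p) are
    excluded from the family.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m:
        pv = p[ok]
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(stepped, 1.0)
        q[ok] = out
    return q


def _biweights(v: np.ndarray) -> tuple[np.ndarray, bool]:
    """Median-centered, Tukey-biweighted vector a_i = (v_i - med) * w_i.

    Returns (weighted deviations, fallback) where fallback=True signals a zero
    MAD, in which case the caller should use Pearson for this vector's pairs.
    """
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0.0:
        return v - np.mean(v), True
    u = (v - med) / (BIWEIGHT_MADS * mad)
    inside = np.abs(u) < 1.0
    w = np.where(inside, (1.0 - np.where(inside, u, 0.0) ** 2) ** 2, 0.0)
    return (v - med) * w, False


def bicor(x, y, min_n: int = 3) -> float:
    """Biweight midcorrelation of two vectors on pairwise-complete entries.

    Tukey biweights downweight observations further than 9 MADs from the
    median, giving a correlation robust to single outliers.  A vector with
    zero MAD (more than half its values tied) falls back to Pearson for the
    pair, mirroring reference behaviour.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_n:
        raise ValueError(
            f"bicor needs at least {min_n} pairwise-complete observations, got {ok.sum()}"
        )
    xs, ys = x[ok], y[ok]
    ax, fx = _biweights(xs)
    ay, fy = _biweights(ys)
    if fx or fy or (ax**2).sum() == 0.0 or (ay**2).sum() == 0.0:
        # zero (or numerically degenerate) MAD: Pearson fallback
        ax = xs - xs.mean()
        ay = ys - ys.mean()
    denom = np.sqrt((ax**2).sum() * (ay**2).sum())
    if denom == 0.0:
        return np.nan
    return float(np.clip((ax * ay).sum() / denom, -1.0, 1.0))


def bicor_matrix(data: np.ndarray | pd.DataFrame, max_missing: float = 0.05) -> np.ndarray:
    """All-pairs bicor of the columns of ``data`` (samples x features).

    Complete data uses a single vectorised pass.  With missing entries (up
    to ``max_missing`` fraction per column) medians, MADs and weights are
    computed column-wise on observed values and cross-products restricted to
    jointly observed samples, with per-pair renormalisation — the fast
    approximation used for large grids (the scalar :func:`bicor` recomputes
    moments per pair and is the reference for pairwise behaviour).  Columns
    above the missingness tolerance raise, since the caller should have
    filtered them.
    """
    X = np.asarray(data, dtype=float)
    n, m = X.shape
    miss = ~np.isfinite(X)
    frac = miss.mean(axis=0)
    if (frac > max_missing).any():
        bad = int((frac > max_missing).sum())
        raise ValueError(
            f"{bad} columns exceed the {max_missing:.0%} missingness tolerated for bicor"
        )
    A = np.empty_like(X)
    for j in range(m):
        x = X[:, j]
        obs = np.isfinite(x)
        a, fb = _biweights(x[obs])
        if fb:
            a = x[obs] - x[obs].mean()
        col = np.zeros(n)
        col[obs] = a
        A[:, j] = col
    if not miss.any():
        norms = np.sqrt((A**2).sum(axis=0))
        norms[norms == 0] = np.nan
        R = (A.T @ A) / np.outer(norms, norms)
    else:
        M = (~miss).astype(float)
        num = A.T @ A
        A2 = A**2
        pair_sq = A2.T @ M  # [i, j] = sum of a_i^2 over samples observed in j
        denom = np.sqrt(pair_sq * pair_sq.T)
        denom[denom == 0] = np.nan
        R = num / denom
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def _bicor_t_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Student-t approximation p-value for a correlation coefficient."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2.0) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2.0, 1.0))
    p = np.where(n < 3, np.nan, p)
    return np.maximum(p, np.finfo(float).tiny)


def correlate_grid(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    method: str = "bicor",
) -> CorrelationResult:
    """Correlate every feature (row) with every target column.

    ``features`` is features x samples; ``targets`` is samples x targets.
    Pairs are computed on pairwise-complete observations and the per-pair
    sample count drives the t-approximation degrees of freedom.
    """
    shared = features.columns.intersection(targets.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between features and targets")
    F = features[shared]
    T = targets.loc[shared]
    coef = pd.DataFrame(index=F.index, columns=T.columns, dtype=float)
    nuse = pd.DataFrame(index=F.index, columns=T.columns, dtype=float)
    for t in T.columns:
        y = T[t].to_numpy(dtype=float)
        for f in F.index:
            x = F.loc[f].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            nuse.loc[f, t] = ok.sum()
            if ok.sum() < 3:
                coef.loc[f, t] = np.nan
                continue
            if method == "bicor":
                coef.loc[f, t] = bicor(x, y)
            elif method == "spearman":
                coef.loc[f, t] = stats.spearmanr(x[ok], y[ok]).statistic
            else:
                coef.loc[f, t] = stats.pearsonr(x[ok], y[ok]).statistic
    p = pd.DataFrame(
        _bicor_t_p(coef.to_numpy(), nuse.to_numpy()), index=coef.index, columns=coef.columns
    )
    return CorrelationResult(coefficient=coef, p_value=p, n_used=nuse, method=method)


def _group_arrays(matrix: pd.DataFrame, groups: pd.Series) -> dict[str, np.ndarray]:
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        missing = list(matrix.columns[groups.isna()])
        raise ValueError(f"samples without a group label: {missing[:5]}")
    return {g: matrix.loc[:, groups == g].to_numpy(dtype=float) for g in groups.unique()}


def anova_bh(matrix: pd.DataFrame, groups: pd.Series, min_per_group: int = 2) -> DiffResult:
    """Vectorised one-way ANOVA across groups per feature, BH-corrected.

    Features lacking ``min_per_group`` non-missing values in every group are
    reported untested (NaN p) and excluded from the BH family.
    """
    arrays = _group_arrays(matrix, groups)
    names = list(arrays)
    if len(names) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    nf = matrix.shape[0]
    counts = np.column_stack([np.isfinite(a).sum(axis=1) for a in arrays.values()])
    testable = (counts >= min_per_group).all(axis=1)

    # classic between/within decomposition on available values
    sums = np.column_stack([np.nansum(a, axis=1) for a in arrays.values()])
    sqs = np.column_stack([np.nansum(a**2, axis=1) for a in arrays.values()])
    with np.errstate(divide="ignore", invalid="ignore"):
        gmeans = sums / counts
        N = counts.sum(axis=1)
        grand = sums.sum(axis=1) / N
        ss_between = (counts * (gmeans - grand[:, None]) ** 2).sum(axis=1)
        ss_within = (sqs - counts * gmeans**2).sum(axis=1)
        df_b = len(names) - 1
        df_w = N - len(names)
        F = (ss_between / df_b) / np.maximum(ss_within / np.maximum(df_w, 1), 0)
        F = np.where(ss_within <= 0, np.where(ss_between <= 1e-300, 0.0, np.inf), F)
        p = stats.f.sf(F, df_b, df_w)
    p = np.where(testable, p, np.nan)
    F = np.where(testable, F, np.nan)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            **{f"mean_{g}": gmeans[:, i] for i, g in enumerate(names)},
            "stat": F,
            "p": p,
            "q": q,
            "tested": testable,
        },
        index=matrix.index,
    )
    return DiffResult(table=table, groups=names, test="anova")


def group_contrast(
    matrix: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> DiffResult:
    """Welch two-group contrast per feature (volcano table), ``a`` minus ``b``.

    log2 fold change is the difference of group means of log2 abundance;
    classes {increased, decreased, ns} are decided at BH q < ``alpha``.
    """
    arrays = _group_arrays(matrix, groups)
    for g in (group_a, group_b):
        if g not in arrays:
            raise ValueError(f"group {g!r} not present")
        if arrays[g].shape[1] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    A, B = arrays[group_a], arrays[group_b]
    na = np.isfinite(A).sum(axis=1)
    nb = np.isfinite(B).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ma, mb = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
        va = np.nanvar(A, axis=1, ddof=1) / na
        vb = np.nanvar(B, axis=1, ddof=1) / nb
        t = (ma - mb) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    testable = (na >= 2) & (nb >= 2) & np.isfinite(p)
    p = np.where(testable, p, np.nan)
    p = np.where(testable & (np.nan_to_num(va + vb) == 0), 1.0, p)  # identical groups
    q = bh_adjust(p)
    log2fc = ma - mb
    cls = np.where(
        (q < alpha) & (log2fc > 0),
        "increased",
        np.where((q < alpha) & (log2fc < 0), "decreased", "ns"),
    )
    table = pd.DataFrame(
        {
            f"mean_{group_a}": ma,
            f"mean_{group_b}": mb,
            "log2fc": log2fc,
            "stat": t,
            "p": p,
            "q": q,
            "class": cls,
            "n_used": na + nb,
        },
        index=matrix.index,
    )
    return DiffResult(table=table, groups=[group_a, group_b], test="welch")


def spearman_burden(matrix: pd.DataFrame, burden: pd.Series) -> pd.DataFrame:
    """Spearman rho of every feature against the CE burden score.

    Pairwise-complete per feature; constant features get NaN rho.  Returns a
    table with rho, p, BH q, and n_used.
    """
    shared = matrix.columns.intersection(burden.index)
    if len(shared) == 0:
        raise ValueError("no samples shared between matrix and burden score")
    X = matrix[shared].to_numpy(dtype=float)
    b = burden.loc[shared].to_numpy(dtype=float)
    nf = X.shape[0]
    rho = np.full(nf, np.nan)
    n_used = np.zeros(nf, dtype=int)
    finite = np.isfinite(X)
    complete = finite.all(axis=1)
    # vectorised path for complete features: rank then Pearson
    if complete.any():
        Xc = X[complete]
        ranks = stats.rankdata(Xc, axis=1)
        rb = stats.rankdata(b)
        rc = ranks - ranks.mean(axis=1, keepdims=True)
        bc = rb - rb.mean()
        denom = np.sqrt((rc**2).sum(axis=1) * (bc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rho[complete] = (rc @ bc) / denom
        n_used[complete] = len(b)
    for i in np.where(~complete)[0]:
        ok = finite[i] & np.isfinite(b)
        n_used[i] = ok.sum()
        if ok.sum() >= 3 and np.ptp(X[i, ok]) > 0:
            rho[i] = stats.spearmanr(X[i, ok], b[ok]).statistic
    p = _bicor_t_p(rho, n_used)
    p = np.where(np.isfinite(rho), p, np.nan)
    q = bh_adjust(p)
    return pd.DataFrame({"rho": rho, "p": p, "q": q, "n_used": n_used}, index=matrix.index)


def ce_gene_bias(
    spearman_result: pd.DataFrame,
    ce_genes: list[str] | set[str],
    alpha: float = 0.05,
    use_q: bool = True,
) -> tuple[int, int, float]:
    """Directional bias of CE-transcript proteins in the burden correlation.

    Among proteins on the cryptic-exon transcript list that are significant at
    ``alpha`` (BH q by default), counts negative- vs positive-rho proteins and
    runs an exact two-sided binomial sign test against 0.5.  Transcripts that
    harbor cryptic exons are often degraded, so a negative skew is the
    biologically expected signature of TDP-43 loss of function.
    """
    ce = set(ce_genes) & set(spearman_result.index)
    if not ce:
        raise ValueError("CE gene list has no overlap with the feature set")
    sub = spearman_result.loc[sorted(ce)]
    crit = sub["q"] if use_q else sub["p"]
    sig = sub[(crit < alpha) & np.isfinite(sub["rho"])]
    n_neg = int((sig["rho"] < 0).sum())
    n_pos = int((sig["rho"] > 0).sum())
    if n_neg + n_pos == 0:
        return 0, 0, 1.0
    p = stats.binomtest(n_neg, n_neg + n_pos, 0.5).pvalue
    return n_neg, n_pos, float(p)
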