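"""Proteome preprocessing: TAMPOR normalisation, filtering, outliers, covariates.

The normalisation follows the tunable median-polish-of-ratio (TAMPOR) idea
for multiplexed isobaric batches: on the log2 scale, abundances are expressed
as ratios to each batch's internal reference (GIS) channel median per
feature, then a per-sample median polish removes loading differences; the two
sweeps alternate to convergence.  Downstream steps mirror the standard
pipeline order: sample-connectivity outlier removal, a 50% missingness
filter, and nonparametric bootstrap regression that removes age / sex / PMI /
batch variance while protecting the diagnosis signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix

__all__ = [
    "tampor_normalize",
    "filter_missingness",
    "detect_outliers",
    "regress_covariates",
    "impute_trait_floor",
]


@dataclass
class TamporTrace:
    """Per-iteration largest absolute adjustment, plus a convergence flag."""

    adjustments: list[float] = field(default_factory=list)
    converged: bool = False
    warning: str | None = None

    @property
    def n_iter(self) -> int:
        return len(self.adjustments)


def tampor_normalize(
    matrix: AbundanceMatrix, max_iter: int = 250, tol: float = 1e-8
) -> tuple[AbundanceMatrix, TamporTrace]:
    """Alternating two-way median polish of log2 ratios to GIS channels.

    Each iteration (1) subtracts, per feature within each batch, the median
    over that batch's reference samples (the log ratio-to-GIS), then
    (2) subtracts each sample's median over features.  Iterates until the
    largest absolute adjustment falls below ``tol``.  After convergence every
    sample's median log2 ratio is ~0 and every batch's per-feature reference
    median is ~0.
    """
    ref = matrix.is_reference
    batches = matrix.batch
    for b in batches.unique():
        if not (ref & (batches == b)).any():
            raise ValueError(f"batch {b!r} has no reference (GIS) sample")
    X = matrix.values.to_numpy(dtype=float).copy()
    cols = matrix.samples
    batch_ref_idx = {
        b: np.flatnonzero((batches == b) & ref).astype(int) for b in batches.unique()
    }
    batch_idx = {b: np.flatnonzero(batches == b).astype(int) for b in batches.unique()}

    def safe_nanmedian(arr, axis):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            return np.nanmedian(arr, axis=axis)

    trace = TamporTrace()
    for _ in range(max_iter):
        biggest = 0.0
        # sweep 1: per-feature, per-batch reference median
        for b, idx in batch_idx.items():
            med = safe_nanmedian(X[:, batch_ref_idx[b]], axis=1)
            med = np.where(np.isfinite(med), med, 0.0)
            X[:, idx] -= med[:, None]
            biggest = max(biggest, float(np.max(np.abs(med), initial=0.0)))
        # sweep 2: per-sample median over features
        smed = safe_nanmedian(X, axis=0)
        smed = np.where(np.isfinite(smed), smed, 0.0)
        X -= smed[None, :]
        biggest = max(biggest, float(np.max(np.abs(smed), initial=0.0)))
        trace.adjustments.append(biggest)
        if biggest < tol:
            trace.converged = True
            break
    if not trace.converged:
        trace.warning = (
            f"TAMPOR did not converge in {max_iter} iterations "
            f"(last adjustment {trace.adjustments[-1]:.3g})"
        )
    out = AbundanceMatrix(
        pd.DataFrame(X, index=matrix.features, columns=cols), matrix.annot.copy()
    )
    return out, trace


def filter_missingness(
    matrix: AbundanceMatrix, max_missing_fraction: float = 0.5
) -> AbundanceMatrix:
    """Drop features absent in ``max_missing_fraction`` of samples or more.

    The boundary is inclusive: a feature missing in exactly half the samples
    is removed.  Retained features are untouched.
    """
    if not 0 < max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in (0, 1]")
    frac = matrix.values.isna().mean(axis=1)
    keep = frac < max_missing_fraction
    return matrix.subset_features(matrix.features[keep])


def detect_outliers(
    matrix: AbundanceMatrix | pd.DataFrame,
    z_threshold: float = -3.0,
    max_rounds: int = 5,
) -> tuple[list[str], list[dict]]:
    """Iterative sample-connectivity outlier detection.

    Each round computes every sample's mean pairwise correlation to the other
    samples, standardises those connectivities, and flags samples whose
    z-score falls below ``z_threshold``; flagged samples are removed and the
    procedure repeats until no sample is flagged.  Returns the flagged sample
    ids in removal order plus a per-round report.
    """
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    if values.shape[1] < 4:
        raise ValueError("outlier detection needs at least 4 samples")
    current = values.copy()
    removed: list[str] = []
    report: list[dict] = []
    for rnd in range(max_rounds):
        corr = current.corr(method="pearson")  # pairwise-complete
        np.fill_diagonal(corr.values, np.nan)
        conn = corr.mean(axis=0)
        sd = conn.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            break
        z = (conn - conn.mean()) / sd
        flagged = list(z.index[z < z_threshold])
        report.append({"round": rnd + 1, "z": z, "flagged": flagged})
        if not flagged:
            break
        removed.extend(flagged)
        keep = [s for s in current.columns if s not in flagged]
        if not keep:
            raise ValueError("all samples flagged as outliers; matrix is degenerate")
        current = current[keep]
    return removed, report


def _build_design(
    annot: pd.DataFrame, covariates: list[str], protected: list[str]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Dummy-coded design [intercept | protected | covariates].

    Returns (design, column names, boolean mask of covariate columns whose
    contribution is to be removed).
    """
    blocks = [pd.Series(1.0, index=annot.index, name="intercept")]
    is_cov = [False]
    for role, names in (("protected", protected), ("covariate", covariates)):
        for c in names:
            col = annot[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
                dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
                for d in dummies.columns:
                    blocks.append(dummies[d])
                    is_cov.append(role == "covariate")
            else:
                centered = col.astype(float) - col.astype(float).mean()
                blocks.append(centered.rename(c))
                is_cov.append(role == "covariate")
    X = pd.concat(blocks, axis=1)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        # identify offending columns via QR pivots
        _, r = np.linalg.qr(Xv)
        bad = [names[j] for j in range(Xv.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    return Xv, names, np.asarray(is_cov)


def regress_covariates(
    matrix: AbundanceMatrix,
    covariates: list[str] = ("age", "sex", "pmi", "batch"),
    protected: list[str] = ("group",),
    n_boot: int = 1000,
    seed: int = 0,
    annot: pd.DataFrame | None = None,
) -> AbundanceMatrix:
    """Remove nuisance-covariate variance by bootstrap-aggregated regression.

    Per feature, ``abundance ~ protected + covariates`` is fit by least
    squares on ``n_boot`` bootstrap resamples of the samples; each covariate
    coefficient is the median over resamples (robust to influential cases).
    The output subtracts only the covariate design times those medians, so
    variance attributable to the protected terms (diagnosis) is retained.
    Missing cells stay missing.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ann = annot if annot is not None else matrix.annot
    need = list(covariates) + list(protected)
    absent = [c for c in need if c not in ann.columns]
    if absent:
        raise ValueError(f"sample annotations missing columns: {absent}")
    if ann[need].isna().any().any():
        raise ValueError("covariates must be present for all samples")

    X, names, is_cov = _build_design(ann, list(covariates), list(protected))
    Y = matrix.values.to_numpy(dtype=float).T  # n x F
    n, p = X.shape
    nf = Y.shape[1]
    obs = np.isfinite(Y)
    Y0 = np.where(obs, Y, 0.0)

    rng = np.random.default_rng(seed)
    betas = np.empty((n_boot, p, nf))
    ridge = 1e-8 * np.eye(p)
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        Xb = X[take]
        Mb = obs[take].astype(float)  # n x F
        Yb = Y0[take]
        # per-feature normal equations with 0/1 observation weights
        outer = Xb[:, :, None] * Xb[:, None, :]  # n x p x p
        A = np.tensordot(Mb.T, outer.reshape(n, p * p), axes=1).reshape(nf, p, p)
        rhs = (Xb.T @ (Mb * Yb)).T[:, :, None]  # F x p x 1
        betas[b] = np.linalg.solve(A + ridge, rhs)[:, :, 0].T
    med = np.nanmedian(betas, axis=0)  # p x F
    fitted_cov = X[:, is_cov] @ med[is_cov]  # n x F
    adjusted = np.where(obs, Y - fitted_cov, np.nan).T
    return AbundanceMatrix(
        pd.DataFrame(adjusted, index=matrix.features, columns=matrix.samples),
        matrix.annot.copy(),
    )


def impute_trait_floor(values: pd.Series, floor: float = 0.1) -> pd.Series:
    """Replace missing (below-detection) immunoassay values with a floor.

    The default 0.1 corresponds to roughly half the lowest detectable level
    of the pTDP-43 assay.  Observed entries are returned unchanged.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    return values.fillna(floor)
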