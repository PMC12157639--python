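"""Relative cryptic-exon quantification from qPCR cycle thresholds.

Implements the delta-delta-Ct scheme: per subject, the geometric mean of the
housekeeping assay Ct values (RPLP0, GAPDH, CYC1 by default) is subtracted
from each cryptic-exon Ct (delta Ct); the control-group mean delta Ct is then
subtracted per assay (delta-delta Ct).  Output is reported as -ddCt, i.e.
log2 relative expression, so higher CE burden is numerically larger.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import CE_ASSAYS, HK_ASSAYS

__all__ = ["delta_ct", "relative_log2_expression", "ce_matrix_from_ct"]


def delta_ct(
    ct_table: pd.DataFrame,
    ce_assays: list[str] | tuple[str, ...] = CE_ASSAYS,
    hk_assays: list[str] | tuple[str, ...] = HK_ASSAYS,
    ct_cap: float | None = None,
) -> pd.DataFrame:
    """Per-subject delta Ct: CE Ct minus housekeeping geometric-mean Ct.

    The geometric mean is taken over the housekeeping Ct values themselves.
    Missing CE wells propagate as NaN (configurably capped at ``ct_cap``
    first, emulating an "undetermined at 40 cycles" substitution); a missing
    housekeeping well is an error, since every subject's normaliser must be
    defined.
    """
    ce_assays = [a for a in ce_assays if a in ct_table.columns]
    missing_hk = [a for a in hk_assays if a not in ct_table.columns]
    if missing_hk:
        raise ValueError(f"housekeeping assays absent from table: {missing_hk}")
    if not ce_assays:
        raise ValueError("no CE assay columns found in the Ct table")
    overlap = set(ce_assays) & set(hk_assays)
    if overlap:
        raise ValueError(f"assays cannot be both CE and housekeeping: {sorted(overlap)}")

    hk = ct_table[list(hk_assays)]
    bad = hk.isna().any(axis=1)
    if bad.any():
        subject = hk.index[bad][0]
        assay = hk.columns[hk.loc[subject].isna()][0]
        raise ValueError(f"missing housekeeping Ct for subject {subject!r}, assay {assay!r}")
    ce = ct_table[ce_assays]
    if ct_cap is not None:
        ce = ce.fillna(ct_cap)
    if (hk.to_numpy() <= 0).any() or np.nanmin(ce.to_numpy()) <= 0:
        raise ValueError("Ct values must be positive")
    geo = np.exp(np.log(hk).mean(axis=1))
    return ce.sub(geo, axis=0)


def relative_log2_expression(
    delta_ct_matrix: pd.DataFrame, control_ids: list[str]
) -> pd.DataFrame:
    """Log2 relative expression = -(delta Ct - mean control delta Ct).

    Centering on the control group makes each column's control mean exactly
    zero; the sign flip makes higher expression (lower Ct) positive.
    """
    control_ids = [c for c in control_ids]
    if not control_ids:
        raise ValueError("control_ids must be nonempty")
    absent = [c for c in control_ids if c not in delta_ct_matrix.index]
    if absent:
        raise ValueError(f"control subjects not in the delta-Ct matrix: {absent}")
    control_mean = delta_ct_matrix.loc[control_ids].mean(axis=0)
    return -(delta_ct_matrix - control_mean)


def ce_matrix_from_ct(
    ct_table: pd.DataFrame,
    control_ids: list[str],
    ce_assays=CE_ASSAYS,
    hk_assays=HK_ASSAYS,
    ct_cap: float | None = None,
) -> pd.DataFrame:
    """Full Ct -> log2 relative CE expression pipeline (ddCt with sign flip)."""
    return relative_log2_expression(
        delta_ct(ct_table, ce_assays, hk_assays, ct_cap=ct_cap), control_ids
    )
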