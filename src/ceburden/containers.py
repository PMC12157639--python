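"""Shared in-memory containers for the pipeline.

The proteome travels through every stage as an :class:`AbundanceMatrix`:
a features x samples frame of log2 abundance (NaN = missing) plus a sample
annotation frame carrying batch, reference-channel (GIS) flags and disease
group.  Thin wrapper over two aligned pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AbundanceMatrix:
    """Log2 abundance matrix with sample annotations.

    Parameters
    ----------
    values : DataFrame
        features (rows) x samples (columns), log2 scale, NaN where missing.
    annot : DataFrame
        One row per sample (index matches ``values.columns``).  Recognised
        columns: ``batch``, ``is_reference`` (bool; GIS channels), ``group``.
    """

    values: pd.DataFrame
    annot: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.annot is None:
            self.annot = pd.DataFrame(index=self.values.columns)
        if not self.values.columns.equals(self.annot.index):
            self.annot = self.annot.reindex(self.values.columns)
        if self.values.index.has_duplicates:
            raise ValueError("feature identifiers must be unique")
        with np.errstate(invalid="ignore"):
            arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("abundance values must be finite where present")

    # -- convenience accessors -------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def is_reference(self) -> pd.Series:
        if "is_reference" in self.annot:
            return self.annot["is_reference"].astype(bool)
        return pd.Series(False, index=self.samples)

    @property
    def batch(self) -> pd.Series:
        if "batch" not in self.annot:
            raise KeyError("sample annotation has no 'batch' column")
        return self.annot["batch"]

    def subset_samples(self, keep) -> "AbundanceMatrix":
        keep = list(keep)
        return AbundanceMatrix(self.values[keep], self.annot.loc[keep])

    def subset_features(self, keep) -> "AbundanceMatrix":
        keep = list(keep)
        return AbundanceMatrix(self.values.loc[keep], self.annot)

    def biological(self) -> "AbundanceMatrix":
        """Drop reference (GIS) channels, keeping biological samples only."""
        return self.subset_samples(self.samples[~self.is_reference.to_numpy()])

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.annot.copy())

    def write(self, values_path, annot_path=None) -> None:
        """Write the matrix (and optionally annotations) as TSV."""
        self.values.to_csv(values_path, sep="\t", index_label="feature")
        if annot_path is not None:
            self.annot.to_csv(annot_path, sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, values_path, annot_path=None) -> "AbundanceMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        annot = None
        if annot_path is not None:
            annot = pd.read_csv(annot_path, sep="\t", index_col=0)
        return cls(values, annot)
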