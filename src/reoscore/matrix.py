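"""Gene-by-sample expression container.

The whole pipeline is rank-based: only the within-sample ordering of values
is ever used, so the matrix may hold any monotone-consistent measurement
scale (background-adjusted array intensities, FPKM, raw counts). Missing
values are NaN and are distinct from zero; a missing value means "this gene
was not measured in this sample" and removes the gene's pairs from that
sample's evaluable set downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix with unique string identifiers.

    Parameters
    ----------
    data
        DataFrame indexed by gene id, columns sample ids, float values;
        NaN encodes a missing measurement.
    cohort_label
        Free-text label for the cohort/platform the samples came from.
    """

    data: pd.DataFrame
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene id(s): {', '.join(map(str, dupes[:5]))}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample id(s): {', '.join(map(str, dupes[:5]))}")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression values: {exc}") from exc
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        vals = self.data.to_numpy()
        if np.isinf(vals).any():
            raise ValidationError("expression values must be finite (use NA for missing)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def value(self, gene: str, sample: str) -> float:
        """Single measurement; NaN if missing."""
        if gene not in self.data.index:
            raise ValidationError(f"unknown gene id: {gene!r}")
        if sample not in self.data.columns:
            raise ValidationError(f"unknown sample id: {sample!r}")
        return float(self.data.at[gene, sample])

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"unknown gene id(s): {', '.join(missing[:5])}")
        return ExpressionMatrix(self.data.loc[genes].copy(), self.cohort_label)


def concat_samples(matrices: list[ExpressionMatrix], cohort_label: str = "") -> ExpressionMatrix:
    """Pool samples from several matrices over their common gene universe.

    Used to merge datasets measured on the same platform into one cohort;
    genes absent from any input are dropped (ordering comparisons require
    both genes, so a partially shared universe would only add unevaluable
    pairs).
    """
    if not matrices:
        raise ValidationError("no matrices to concatenate")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValidationError("matrices share no gene ids")
    genes = sorted(common)
    frames = [m.data.loc[genes] for m in matrices]
    merged = pd.concat(frames, axis=1)
    return ExpressionMatrix(merged, cohort_label)
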