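"""Gene × sample expression container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """A genes × samples numeric table with optional per-sample group labels.

    ``values`` rows are indexed by gene identifier (probe id or symbol), columns
    by sample identifier. Values are on whatever scale the stage expects
    (raw intensities before normalization, log2 afterwards); the container does
    not track the scale itself.
    """

    values: pd.DataFrame
    groups: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            n_bad = int((~np.isfinite(arr)).sum())
            raise ValueError(f"{n_bad} non-finite values in expression matrix")
        if self.groups is not None:
            self.groups = pd.Series(self.groups)
            missing = set(self.values.columns) - set(self.groups.index)
            if missing:
                raise ValueError(f"samples without group label: {sorted(missing)[:5]}")
            self.groups = self.groups.reindex(self.values.columns)

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, label: str) -> list[str]:
        if self.groups is None:
            raise ValueError("matrix carries no group labels")
        return list(self.groups.index[self.groups == label])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.groups)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        groups = self.groups.loc[list(samples)] if self.groups is not None else None
        return ExpressionMatrix(self.values.loc[:, list(samples)], groups)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            self.groups.copy() if self.groups is not None else None,
        )
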