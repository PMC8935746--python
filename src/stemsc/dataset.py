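"""Expression dataset container used throughout the package.

A dataset is a dense gene-by-sample matrix of nonnegative, finite
expression values (RPKM/TPM/count-like units) with optional per-sample
metadata. All downstream operations consume only within-sample rank
information, so the units never matter beyond nonnegativity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset"]


@dataclass
class ExpressionDataset:
    """Gene-by-sample expression matrix with optional per-sample metadata.

    Parameters
    ----------
    dataset_id:
        Free-text label identifying the dataset.
    values:
        DataFrame with genes as the index and samples as the columns.
        All entries must be nonnegative and finite.
    sample_meta:
        Optional DataFrame indexed by sample identifier. When present it
        must cover exactly the sample set of ``values``. Recognised
        columns are ``time`` (real), ``group`` (text), ``state`` (text)
        and ``csc_flag`` (boolean), but arbitrary columns are allowed.
    """

    dataset_id: str
    values: pd.DataFrame
    sample_meta: Optional[pd.DataFrame] = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError(
                f"dataset {self.dataset_id!r}: expression values must be finite"
            )
        if arr.size and arr.min() < 0:
            raise ValueError(
                f"dataset {self.dataset_id!r}: expression values must be nonnegative"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(
                f"dataset {self.dataset_id!r}: duplicate gene identifiers: {dups}"
            )
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(
                f"dataset {self.dataset_id!r}: duplicate sample identifiers: {dups}"
            )
        if self.sample_meta is not None:
            meta_idx = set(self.sample_meta.index)
            samp_idx = set(self.values.columns)
            if meta_idx != samp_idx:
                missing = sorted(samp_idx - meta_idx)
                extra = sorted(meta_idx - samp_idx)
                raise ValueError(
                    f"dataset {self.dataset_id!r}: sample_meta must cover exactly "
                    f"the sample set (missing={missing}, extra={extra})"
                )
            # align metadata rows to column order
            self.sample_meta = self.sample_meta.loc[self.values.columns]

    # -- basic views -----------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        dataset_id: str,
        matrix: np.ndarray,
        genes: Sequence[str],
        samples: Sequence[str],
        sample_meta: Optional[pd.DataFrame] = None,
    ) -> "ExpressionDataset":
        values = pd.DataFrame(
            np.asarray(matrix, dtype=float), index=list(genes), columns=list(samples)
        )
        return cls(dataset_id=dataset_id, values=values, sample_meta=sample_meta)

    # -- manipulation ----------------------------------------------------

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        """Restrict to a gene subset (order follows ``genes``)."""
        genes = list(genes)
        unknown = [g for g in genes if g not in self.values.index]
        if unknown:
            raise ValueError(
                f"dataset {self.dataset_id!r}: unknown gene identifiers: {unknown}"
            )
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            values=self.values.loc[genes],
            sample_meta=self.sample_meta,
        )

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionDataset":
        samples = list(samples)
        unknown = [s for s in samples if s not in self.values.columns]
        if unknown:
            raise ValueError(
                f"dataset {self.dataset_id!r}: unknown sample identifiers: {unknown}"
            )
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[samples]
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            values=self.values[samples],
            sample_meta=meta,
        )

    def times(self) -> pd.Series:
        """Per-sample differentiation time; raises when absent."""
        if self.sample_meta is None or "time" not in self.sample_meta.columns:
            raise ValueError(
                f"dataset {self.dataset_id!r}: sample_meta lacks a 'time' column"
            )
        return self.sample_meta["time"].astype(float)
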