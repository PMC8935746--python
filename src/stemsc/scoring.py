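"""Scoring samples against a reference gene-pair signature.

The score of a sample is k/n: of the n reference pairs evaluable in the
sample (both genes measured with strictly different values), k agree
with the reference direction. The score is exactly invariant under any
strictly increasing transform of the sample's values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Union

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .training import ReferenceSignature

__all__ = ["StemSCScore", "score_sample", "score_dataset"]


@dataclass(frozen=True)
class StemSCScore:
    """Per-sample score: n evaluable pairs, k concordant, score = k/n.

    ``score`` is NaN and ``undefined_flag`` True when no reference pair
    is evaluable in the sample; an undefined score never silently
    collapses to 0 or 1.
    """

    sample: str
    n_evaluable: int
    k_concordant: int
    score: float
    undefined_flag: bool

    @classmethod
    def make(cls, sample: str, n: int, k: int) -> "StemSCScore":
        if n == 0:
            return cls(sample, 0, 0, float("nan"), True)
        return cls(sample, n, k, k / n, False)


def _signature_arrays(signature: ReferenceSignature):
    pairs = signature.pairs()
    high = np.asarray([p.gene_high for p in pairs], dtype=object)
    low = np.asarray([p.gene_low for p in pairs], dtype=object)
    return high, low


def score_sample(
    sample_expression: Union[Mapping[str, float], pd.Series],
    signature: ReferenceSignature,
    sample_id: str = "sample",
) -> StemSCScore:
    """Score one sample's expression vector against the signature.

    A pair is evaluable iff both genes are present in the sample's gene
    universe and their values strictly differ; ties (including both-zero
    dropout pairs) carry no ordering evidence and are excluded from n.
    Zero is a measured value, so (positive, zero) pairs ARE evaluable.
    """
    if not isinstance(sample_expression, pd.Series):
        sample_expression = pd.Series(sample_expression, dtype=float)
    vals = sample_expression.to_numpy(dtype=float)
    if vals.size and (np.any(~np.isfinite(vals)) or np.nanmin(vals) < 0):
        raise ValueError(f"sample {sample_id!r}: values must be nonnegative and finite")

    high, low = _signature_arrays(signature)
    v_high = sample_expression.reindex(high).to_numpy(dtype=float)
    v_low = sample_expression.reindex(low).to_numpy(dtype=float)
    present = ~np.isnan(v_high) & ~np.isnan(v_low)
    evaluable = present & (v_high != v_low)
    n = int(evaluable.sum())
    k = int((v_high[evaluable] > v_low[evaluable]).sum())
    return StemSCScore.make(sample_id, n, k)


def score_dataset(
    dataset: ExpressionDataset, signature: ReferenceSignature
) -> List[StemSCScore]:
    """One score per sample, order-aligned with ``dataset.samples``."""
    arr = dataset.values.to_numpy(dtype=float)
    if arr.size and (np.any(~np.isfinite(arr)) or arr.min() < 0):
        raise ValueError(
            f"dataset {dataset.dataset_id!r}: values must be nonnegative and finite"
        )
    high, low = _signature_arrays(signature)
    index = dataset.values.index
    hi_pos = index.get_indexer(high)
    lo_pos = index.get_indexer(low)
    present = (hi_pos >= 0) & (lo_pos >= 0)

    out: List[StemSCScore] = []
    vh = arr[hi_pos[present], :]
    vl = arr[lo_pos[present], :]
    evaluable = vh != vl
    concordant = evaluable & (vh > vl)
    n_per_sample = evaluable.sum(axis=0)
    k_per_sample = concordant.sum(axis=0)
    for j, sample in enumerate(dataset.samples):
        out.append(StemSCScore.make(sample, int(n_per_sample[j]), int(k_per_sample[j])))
    return out
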