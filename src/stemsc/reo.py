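"""Relative expression orderings (REOs): stable-pair identification and
cross-dataset consistency.

A REO is the within-sample order relation between the expression values
of two genes. A pair is *stable* in a dataset when the same strict
ordering holds in every sample; ties (including zero-zero dropouts)
disqualify a pair, because only strict orderings survive arbitrary
monotone per-sample transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .dataset import ExpressionDataset

__all__ = [
    "DirectedGenePair",
    "StableREOSet",
    "ConsistencyResult",
    "identify_stable_reos",
    "binomial_consistency_pvalue",
    "consistency",
    "recovery_rate",
]

PairKey = Tuple[str, str]  # lexicographically sorted gene pair


class DirectedGenePair(NamedTuple):
    """An ordered gene pair meaning expression(gene_high) > expression(gene_low)."""

    gene_high: str
    gene_low: str

    @property
    def key(self) -> PairKey:
        a, b = self.gene_high, self.gene_low
        return (a, b) if a < b else (b, a)

    @property
    def first_is_high(self) -> bool:
        """Direction flag relative to the canonical (sorted) key."""
        return self.gene_high < self.gene_low


@dataclass
class StableREOSet:
    """The set of gene pairs with an invariant ordering across a dataset.

    Pairs are stored canonically: the key is the lexicographically sorted
    identifier pair, the value is True when the lexicographically smaller
    gene is the higher-expressed one. Both-direction collisions are
    therefore structurally impossible.
    """

    source_id: str
    n_samples_used: int
    directions: Dict[PairKey, bool] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls, source_id: str, n_samples_used: int, pairs: Iterable[DirectedGenePair]
    ) -> "StableREOSet":
        directions: Dict[PairKey, bool] = {}
        for p in pairs:
            if p.gene_high == p.gene_low:
                raise ValueError(f"degenerate pair {p!r}: genes must differ")
            key = p.key
            flag = p.first_is_high
            if key in directions and directions[key] != flag:
                raise ValueError(f"pair {key} given with both directions")
            directions[key] = flag
        return cls(source_id=source_id, n_samples_used=n_samples_used, directions=directions)

    def __len__(self) -> int:
        return len(self.directions)

    def __contains__(self, pair: DirectedGenePair) -> bool:
        key = pair.key
        return key in self.directions and self.directions[key] == pair.first_is_high

    def pairs(self) -> list[DirectedGenePair]:
        """Directed pairs in deterministic lexicographic order."""
        out = []
        for (a, b) in sorted(self.directions):
            if self.directions[(a, b)]:
                out.append(DirectedGenePair(gene_high=a, gene_low=b))
            else:
                out.append(DirectedGenePair(gene_high=b, gene_low=a))
        return out


@dataclass(frozen=True)
class ConsistencyResult:
    """Cross-dataset agreement of two stable-REO sets.

    ``n_shared`` unordered pairs are present in both sets; ``s_concordant``
    of them carry the same direction. When no pairs are shared both the
    consistency and the p-value are undefined (None).
    """

    n_shared: int
    s_concordant: int
    consistency: Optional[float]
    p_value: Optional[float]
    p0: float = 0.5


def identify_stable_reos(
    dataset: ExpressionDataset,
    gene_subset: Optional[Sequence[str]] = None,
    min_samples: int = 4,
) -> StableREOSet:
    """Find all gene pairs with an identical strict ordering in every sample.

    A tie in any sample (equal values, including both zero) disqualifies
    the pair. Restricted to ``gene_subset`` when given.
    """
    if dataset.n_samples < min_samples:
        raise ValueError(
            f"dataset {dataset.dataset_id!r} has {dataset.n_samples} samples; "
            f"at least {min_samples} are required"
        )
    if gene_subset is not None:
        work = dataset.subset_genes(gene_subset)
    else:
        work = dataset

    genes = np.asarray(work.genes, dtype=object)
    X = work.values.to_numpy(dtype=float)
    g, m = X.shape

    directions: Dict[PairKey, bool] = {}
    if g < 2:
        return StableREOSet(work.dataset_id, m, directions)

    # chunk rows so the (chunk, g, m) comparison tensor stays small
    chunk = max(1, int(2e7 // max(1, g * m)))
    for start in range(0, g - 1, chunk):
        stop = min(start + chunk, g - 1)
        block = X[start:stop][:, None, :]  # (c, 1, m)
        gt = (block > X[None, :, :]).all(axis=2)  # (c, g)
        lt = (block < X[None, :, :]).all(axis=2)
        for local, i in enumerate(range(start, stop)):
            js = np.nonzero(gt[local] | lt[local])[0]
            js = js[js > i]
            for j in js:
                gi, gj = genes[i], genes[j]
                high, low = (gi, gj) if gt[local, j] else (gj, gi)
                key = (gi, gj) if gi < gj else (gj, gi)
                directions[key] = high == key[0]
    return StableREOSet(source_id=work.dataset_id, n_samples_used=m, directions=directions)


def binomial_consistency_pvalue(s: int, n: int, p0: float = 0.5) -> float:
    """Upper-tail probability P(X >= s) for X ~ Binomial(n, p0).

    Evaluated through the survival function so it stays accurate for the
    pair counts seen in practice (n up to ~1e6).
    """
    if not (0 <= s <= n):
        raise ValueError(f"require 0 <= s <= n, got s={s}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"require 0 < p0 < 1, got p0={p0}")
    if s == 0:
        return 1.0
    return float(stats.binom.sf(s - 1, n, p0))


def consistency(set_a: StableREOSet, set_b: StableREOSet, p0: float = 0.5) -> ConsistencyResult:
    """Fraction s/n of shared stable pairs carrying the same direction.

    Significance comes from the cumulative binomial model with chance
    agreement probability ``p0``.
    """
    if len(set_a.directions) > len(set_b.directions):
        set_a, set_b = set_b, set_a
    shared = [k for k in set_a.directions if k in set_b.directions]
    n = len(shared)
    s = sum(1 for k in shared if set_a.directions[k] == set_b.directions[k])
    if n == 0:
        return ConsistencyResult(0, 0, None, None, p0)
    return ConsistencyResult(
        n_shared=n,
        s_concordant=s,
        consistency=s / n,
        p_value=binomial_consistency_pvalue(s, n, p0),
        p0=p0,
    )


def _pool_datasets(datasets: Sequence[ExpressionDataset], genes: Sequence[str], pool_id: str) -> ExpressionDataset:
    import pandas as pd

    mats = []
    for idx, ds in enumerate(datasets):
        sub = ds.values.loc[list(genes)]
        sub = sub.rename(columns={c: f"{ds.dataset_id}:{c}" for c in sub.columns})
        mats.append(sub)
    merged = pd.concat(mats, axis=1)
    return ExpressionDataset(dataset_id=pool_id, values=merged)


def recovery_rate(
    training_sets: Sequence[ExpressionDataset],
    holdout: ExpressionDataset,
    gene_subset: Optional[Sequence[str]] = None,
    min_samples: int = 4,
) -> Optional[float]:
    """Fraction of merged-training stable REOs retained in the holdout.

    All training samples are pooled into one collection, its stable REOs
    are identified on the genes shared by every dataset, and the returned
    value is the fraction of those pairs that are also stable with the
    same direction in the holdout. Returns None when the merged stable
    set is empty.
    """
    if not training_sets:
        raise ValueError("at least one training dataset is required")
    shared = set(holdout.genes)
    for ds in training_sets:
        shared &= set(ds.genes)
    if gene_subset is not None:
        shared &= set(gene_subset)
    genes = sorted(shared)
    if len(genes) < 2:
        raise ValueError(f"datasets share only {len(genes)} genes after subsetting")

    merged = _pool_datasets(training_sets, genes, pool_id="merged-training")
    train_stable = identify_stable_reos(merged, min_samples=min_samples)
    if len(train_stable) == 0:
        return None
    hold_stable = identify_stable_reos(holdout, gene_subset=genes, min_samples=min_samples)
    kept = sum(
        1
        for key, flag in train_stable.directions.items()
        if hold_stable.directions.get(key) == flag
    )
    return kept / len(train_stable)
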