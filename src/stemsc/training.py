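"""Training of the reference gene-pair signature.

Two stages: (1) select genes whose expression tracks differentiation
time in every training time course (Spearman, per-dataset BH-FDR);
(2) among those genes, keep the pairs whose ordering is stable in both
the pooled single-cell and pooled bulk reference (ESC-like) samples and
agrees in direction between the two pools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset
from .reo import DirectedGenePair, PairKey, identify_stable_reos

__all__ = [
    "GeneTimeCorrelation",
    "StemnessGenePanel",
    "ReferenceSignature",
    "spearman_time_correlation",
    "bh_fdr",
    "select_stemness_genes",
    "build_reference_signature",
]


@dataclass(frozen=True)
class GeneTimeCorrelation:
    """Spearman association of one gene with differentiation time in one dataset."""

    dataset_id: str
    gene: str
    rho: float  # NaN when the gene has zero variance
    p: float
    q: Optional[float] = None  # BH-adjusted, filled during selection


@dataclass
class StemnessGenePanel:
    """Genes significantly time-associated in every contributing dataset."""

    genes: List[str]
    evidence: List[GeneTimeCorrelation] = field(default_factory=list)
    fdr_threshold: float = 0.05

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ReferenceSignature:
    """Directed gene pairs stable, with concordant direction, in both
    the single-cell and bulk reference pools.

    ``provenance`` records the pair counts at each stage:
    ``n_sc_stable``, ``n_bulk_stable``, ``n_shared``, ``n_concordant``.
    """

    directions: Dict[PairKey, bool]
    provenance: Dict[str, int]
    panel: Optional[StemnessGenePanel] = None

    def __len__(self) -> int:
        return len(self.directions)

    def pairs(self) -> list[DirectedGenePair]:
        out = []
        for (a, b) in sorted(self.directions):
            if self.directions[(a, b)]:
                out.append(DirectedGenePair(a, b))
            else:
                out.append(DirectedGenePair(b, a))
        return out

    @classmethod
    def from_pairs(
        cls,
        pairs: Sequence[DirectedGenePair],
        provenance: Optional[Dict[str, int]] = None,
        panel: Optional[StemnessGenePanel] = None,
    ) -> "ReferenceSignature":
        directions: Dict[PairKey, bool] = {}
        for p in pairs:
            if p.gene_high == p.gene_low:
                raise ValueError(f"degenerate pair {p!r}")
            if directions.get(p.key, p.first_is_high) != p.first_is_high:
                raise ValueError(f"pair {p.key} given with both directions")
            directions[p.key] = p.first_is_high
        return cls(directions=directions, provenance=provenance or {}, panel=panel)


def spearman_time_correlation(dataset: ExpressionDataset) -> List[GeneTimeCorrelation]:
    """Per-gene Spearman correlation with differentiation time.

    Average ranks are used for ties and the two-sided p-value comes from
    the t-distribution approximation. Zero-variance genes are emitted
    with an undefined (NaN) rho and p = 1 so they never pass selection.
    """
    times = dataset.times()
    if times.isna().any():
        bad = times.index[times.isna()].tolist()
        raise ValueError(
            f"dataset {dataset.dataset_id!r}: samples missing time values: {bad}"
        )
    n = len(times)
    if n < 4:
        raise ValueError(
            f"dataset {dataset.dataset_id!r}: need >=4 time-bearing samples, have {n}"
        )

    X = dataset.values.to_numpy(dtype=float)
    t_rank = stats.rankdata(times.to_numpy())
    if np.all(t_rank == t_rank[0]):
        raise ValueError(
            f"dataset {dataset.dataset_id!r}: time values are constant"
        )
    g_rank = stats.rankdata(X, axis=1)

    gr = g_rank - g_rank.mean(axis=1, keepdims=True)
    tr = t_rank - t_rank.mean()
    g_ss = (gr**2).sum(axis=1)
    t_ss = float((tr**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (gr @ tr) / np.sqrt(g_ss * t_ss)
    rho = np.clip(rho, -1.0, 1.0)
    zero_var = g_ss == 0
    rho[zero_var] = np.nan

    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt(df / (1.0 - rho**2))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals[np.abs(rho) == 1.0] = 0.0
    pvals[zero_var] = 1.0
    pvals = np.clip(pvals, 0.0, 1.0)

    return [
        GeneTimeCorrelation(dataset.dataset_id, gene, float(r), float(p))
        for gene, r, p in zip(dataset.genes, rho, pvals)
    ]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_stemness_genes(
    time_datasets: Sequence[ExpressionDataset],
    fdr_threshold: float = 0.05,
    require_common_sign: bool = False,
) -> StemnessGenePanel:
    """Genes significantly time-associated (BH-FDR < threshold) in ALL datasets.

    FDR is controlled within each dataset over its tested (finite-rho)
    genes; the panel is the intersection of the per-dataset significant
    sets. ``require_common_sign`` additionally demands the correlation
    sign agree across datasets (off by default).
    """
    if len(time_datasets) < 2:
        raise ValueError("at least two time-course datasets are required")

    evidence: List[GeneTimeCorrelation] = []
    significant_sets: List[set] = []
    signs: List[Dict[str, float]] = []
    for ds in time_datasets:
        rows = spearman_time_correlation(ds)
        tested = [r for r in rows if np.isfinite(r.rho)]
        qvals = bh_fdr([r.p for r in tested])
        sig = set()
        sgn: Dict[str, float] = {}
        adjusted = []
        qmap = {r.gene: q for r, q in zip(tested, qvals)}
        for r in rows:
            q = qmap.get(r.gene)
            adjusted.append(
                GeneTimeCorrelation(r.dataset_id, r.gene, r.rho, r.p, q)
            )
            if q is not None and q < fdr_threshold:
                sig.add(r.gene)
                sgn[r.gene] = np.sign(r.rho)
        evidence.extend(adjusted)
        significant_sets.append(sig)
        signs.append(sgn)

    panel_genes = set.intersection(*significant_sets) if significant_sets else set()
    if require_common_sign:
        panel_genes = {
            g for g in panel_genes if len({s[g] for s in signs}) == 1
        }
    if not panel_genes:
        warnings.warn(
            "no gene was significant in every dataset; the panel is empty",
            stacklevel=2,
        )
    return StemnessGenePanel(
        genes=sorted(panel_genes), evidence=evidence, fdr_threshold=fdr_threshold
    )


def _pool(datasets: Sequence[ExpressionDataset], genes: Sequence[str], pool_id: str) -> ExpressionDataset:
    mats = []
    for ds in datasets:
        sub = ds.values.loc[list(genes)]
        sub = sub.rename(columns={c: f"{ds.dataset_id}:{c}" for c in sub.columns})
        mats.append(sub)
    return ExpressionDataset(dataset_id=pool_id, values=pd.concat(mats, axis=1))


def build_reference_signature(
    sc_datasets: Sequence[ExpressionDataset],
    bulk_datasets: Sequence[ExpressionDataset],
    panel: StemnessGenePanel,
    min_samples: int = 4,
) -> ReferenceSignature:
    """Reference REOs: panel-gene pairs stable and direction-concordant in
    both the pooled single-cell and the pooled bulk reference samples.
    """
    if not sc_datasets or not bulk_datasets:
        raise ValueError("both the single-cell and bulk pools must be nonempty")
    if len(panel) == 0:
        raise ValueError("the stemness gene panel is empty")

    shared = set(panel.genes)
    for ds in list(sc_datasets) + list(bulk_datasets):
        shared &= set(ds.genes)
    genes = sorted(shared)
    if len(genes) < 2:
        raise ValueError("fewer than two panel genes are present in every pool dataset")

    sc_pool = _pool(sc_datasets, genes, "sc-pool")
    bulk_pool = _pool(bulk_datasets, genes, "bulk-pool")
    sc_stable = identify_stable_reos(sc_pool, min_samples=min_samples)
    bulk_stable = identify_stable_reos(bulk_pool, min_samples=min_samples)

    shared_keys = [k for k in sc_stable.directions if k in bulk_stable.directions]
    directions: Dict[PairKey, bool] = {
        k: sc_stable.directions[k]
        for k in shared_keys
        if sc_stable.directions[k] == bulk_stable.directions[k]
    }
    provenance = {
        "n_sc_stable": len(sc_stable),
        "n_bulk_stable": len(bulk_stable),
        "n_shared": len(shared_keys),
        "n_concordant": len(directions),
        "n_sc_samples": sc_pool.n_samples,
        "n_bulk_samples": bulk_pool.n_samples,
    }
    if not directions:
        raise ValueError(
            "the reference signature is empty: no pair is stable with a "
            "concordant direction in both pools"
        )
    return ReferenceSignature(directions=directions, provenance=provenance, panel=panel)
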