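"""Score-driven downstream analyses.

Marker ranking, pre-ranked running-sum enrichment, hypergeometric
overlap tests, reference-guided threshold selection and stem-like
calling, trajectory-root selection, highly-variable-gene selection and
two-group comparison. All operations consume per-sample scores (or
expression) and are therefore invariant to per-sample monotone
distortions of the original data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset
from .scoring import StemSCScore

__all__ = [
    "EnrichmentResult",
    "ThresholdDecision",
    "RootCall",
    "rank_genes_by_score_correlation",
    "preranked_enrichment",
    "hypergeometric_enrichment",
    "select_stem_threshold",
    "classify_stem_like",
    "select_root_state",
    "select_hvg",
    "compare_groups",
]


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    nes: float
    p: float
    n_perm: int
    seed: int


@dataclass(frozen=True)
class ThresholdDecision:
    threshold: float
    precision_at_threshold: float
    group_sizes: Tuple[int, int]  # (stem-like, other)
    candidates_examined: int


@dataclass(frozen=True)
class RootCall:
    root_state: str
    state_means: Dict[str, float]


def _defined(scores: Sequence[StemSCScore]) -> np.ndarray:
    return np.asarray([not s.undefined_flag for s in scores], dtype=bool)


def rank_genes_by_score_correlation(
    dataset: ExpressionDataset, scores: Sequence[StemSCScore]
) -> pd.DataFrame:
    """Genes ranked by Spearman correlation with the per-sample scores.

    Returns a DataFrame with columns ``gene``, ``rho``, ``p`` sorted
    descending by rho; zero-variance genes carry NaN rho and sort last.
    """
    score_samples = [s.sample for s in scores]
    if score_samples != dataset.samples:
        raise ValueError("scores are not aligned with the dataset samples")
    mask = _defined(scores)
    if mask.sum() < 4:
        raise ValueError(f"need >=4 defined scores, have {int(mask.sum())}")

    vec = np.asarray([s.score for s in scores], dtype=float)[mask]
    X = dataset.values.to_numpy(dtype=float)[:, mask]
    s_rank = stats.rankdata(vec)
    g_rank = stats.rankdata(X, axis=1)
    gr = g_rank - g_rank.mean(axis=1, keepdims=True)
    sr = s_rank - s_rank.mean()
    g_ss = (gr**2).sum(axis=1)
    s_ss = float((sr**2).sum())
    if s_ss == 0:
        raise ValueError("scores are constant; correlation is undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.clip((gr @ sr) / np.sqrt(g_ss * s_ss), -1.0, 1.0)
    rho[g_ss == 0] = np.nan

    n = int(mask.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    pv = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    pv[np.abs(rho) == 1.0] = 0.0
    pv[np.isnan(rho)] = np.nan

    table = pd.DataFrame({"gene": dataset.genes, "rho": rho, "p": pv})
    table = table.sort_values(
        by=["rho", "gene"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return table


def _running_es(order_stats: np.ndarray, hit_mask: np.ndarray) -> float:
    """Extreme deviation of the weighted KS running sum (weight exponent 1)."""
    n = order_stats.size
    n_hit = int(hit_mask.sum())
    n_miss = n - n_hit
    if n_miss == 0:
        # the set IS the universe: hits exhaust the weight, no contrast exists
        return 0.0
    weights = np.abs(order_stats) * hit_mask
    total = weights.sum()
    if total == 0:
        # all hit stats are exactly zero: fall back to uniform hit weights
        weights = hit_mask.astype(float)
        total = weights.sum()
    running = np.cumsum(weights / total - (~hit_mask) / n_miss)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx])


def preranked_enrichment(
    ranked_stats: Mapping[str, float],
    gene_set: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Pre-ranked running-sum enrichment of a gene set.

    Genes are ordered by decreasing statistic; hits advance the running
    sum by |stat|/sum(|stat| over hits), misses decrement it uniformly.
    The enrichment score is the extreme deviation. The null distribution
    comes from random gene sets of the same size (gene-label
    permutation); NES = ES / mean |null ES of the same sign| and the
    p-value is one-sided among same-sign permutations.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = np.asarray(sorted(ranked_stats, key=lambda g: (-ranked_stats[g], g)), dtype=object)
    order_stats = np.asarray([ranked_stats[g] for g in genes], dtype=float)
    in_set = np.isin(genes, np.asarray(list(set(gene_set)), dtype=object))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranked genes")

    es = _running_es(order_stats, in_set)

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    n = genes.size
    for b in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_hit, replace=False)] = True
        null_es[b] = _running_es(order_stats, perm)

    same_sign = null_es * np.sign(es) > 0 if es != 0 else np.zeros(n_perm, dtype=bool)
    n_same = int(same_sign.sum())
    if es == 0 or n_same == 0:
        nes = 0.0
        p = 1.0
    else:
        nes = float(es / np.abs(null_es[same_sign]).mean())
        extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
        p = (1 + extreme) / (1 + n_same)
    return EnrichmentResult(es=float(es), nes=nes, p=float(p), n_perm=n_perm, seed=seed)


def hypergeometric_enrichment(
    overlap_k: int, set_size_K: int, selected_n: int, universe_N: int
) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (
        0 <= overlap_k <= min(set_size_K, selected_n)
        and set_size_K <= universe_N
        and selected_n <= universe_N
    ):
        raise ValueError(
            f"inconsistent counts: k={overlap_k}, K={set_size_K}, "
            f"n={selected_n}, N={universe_N}"
        )
    if overlap_k == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap_k - 1, universe_N, set_size_K, selected_n))


def select_stem_threshold(
    scores: Sequence[StemSCScore],
    csc_flags: Sequence[bool],
    min_group: int = 1,
    criterion: str = "precision",
) -> ThresholdDecision:
    """Score threshold whose >=t group maximises the reference-cell fraction.

    Candidate thresholds are the distinct observed scores; for each, the
    stem-like group is {score >= t} with size >= min_group and the
    objective is the fraction of flagged (reference) cells inside it
    (``criterion='recall'`` optimises the fraction of flagged cells
    captured instead). Ties go to the smallest threshold, i.e. the
    largest qualifying group.
    """
    if len(scores) != len(csc_flags):
        raise ValueError("scores and csc_flags differ in length")
    if any(s.undefined_flag for s in scores):
        raise ValueError("all scores must be defined for threshold selection")
    flags = np.asarray(csc_flags, dtype=bool)
    if flags.all() or not flags.any():
        raise ValueError("both flagged and unflagged samples are required")
    if criterion not in ("precision", "recall"):
        raise ValueError(f"unknown criterion {criterion!r}")

    vals = np.asarray([s.score for s in scores], dtype=float)
    candidates = np.unique(vals)
    best: Optional[Tuple[float, float, int]] = None  # (objective, -threshold, size)
    chosen = None
    n_flagged = int(flags.sum())
    for t in candidates:
        group = vals >= t
        size = int(group.sum())
        if size < min_group:
            continue
        hits = int((flags & group).sum())
        obj = hits / size if criterion == "precision" else hits / n_flagged
        key = (obj, -t)
        if best is None or key > best[:2]:
            best = (obj, -t, size)
            chosen = (float(t), hits / size, size)
    if chosen is None:
        raise ValueError("no candidate threshold yields a group of the required size")
    t, precision, size = chosen
    return ThresholdDecision(
        threshold=t,
        precision_at_threshold=precision,
        group_sizes=(size, len(scores) - size),
        candidates_examined=len(candidates),
    )


def classify_stem_like(
    scores: Sequence[StemSCScore], threshold: float
) -> List[str]:
    """Label each sample 'stem-like' (score >= threshold) or 'other'."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    labels = []
    n_undef = 0
    for s in scores:
        if s.undefined_flag:
            n_undef += 1
            labels.append("other")
        else:
            labels.append("stem-like" if s.score >= threshold else "other")
    if n_undef:
        warnings.warn(
            f"{n_undef} undefined score(s) were classified as 'other'", stacklevel=2
        )
    return labels


def select_root_state(
    scores: Sequence[StemSCScore], state_labels: Sequence[str]
) -> RootCall:
    """Trajectory root = the state with the highest mean score.

    Exact ties break toward the lexicographically smallest state label
    (with a warning). A state whose scores are all undefined is an error.
    """
    if len(scores) != len(state_labels):
        raise ValueError("scores and state_labels differ in length")
    states = sorted(set(state_labels))
    if len(states) < 2:
        raise ValueError("at least two states are required")
    means: Dict[str, float] = {}
    for st in states:
        vals = [
            s.score
            for s, lab in zip(scores, state_labels)
            if lab == st and not s.undefined_flag
        ]
        if not vals:
            raise ValueError(f"state {st!r} has no defined scores")
        means[st] = float(np.mean(vals))
    best = max(means.values())
    winners = [st for st in states if means[st] == best]
    if len(winners) > 1:
        warnings.warn(
            f"states {winners} tie on mean score; choosing {winners[0]!r}",
            stacklevel=2,
        )
    return RootCall(root_state=winners[0], state_means=means)


def select_hvg(
    dataset: ExpressionDataset, min_cells: int = 10, top_n: int = 5000
) -> List[str]:
    """Highly variable genes by the CV-squared-times-mean statistic.

    Genes detected (value > 0) in fewer than ``min_cells`` cells are
    removed; the rest are ranked by sample variance / mean (algebraically
    CV^2 x mean) and the top ``top_n`` returned. Zero-mean genes are
    excluded.
    """
    X = dataset.values.to_numpy(dtype=float)
    detected = (X > 0).sum(axis=1)
    keep = detected >= min_cells
    means = X.mean(axis=1)
    keep &= means > 0
    if not keep.any():
        return []
    idx = np.nonzero(keep)[0]
    var = X[idx].var(axis=1, ddof=1)
    stat = var / means[idx]
    genes = np.asarray(dataset.genes, dtype=object)[idx]
    order = sorted(range(len(idx)), key=lambda i: (-stat[i], genes[i]))
    return [str(genes[i]) for i in order[:top_n]]


def compare_groups(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    equal_variance: bool = True,
) -> Tuple[float, float]:
    """Two-sample t-test (pooled variance by default, Welch optional)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_variance)
    return float(t), float(p)
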