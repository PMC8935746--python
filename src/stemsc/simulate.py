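"""Synthetic data generators with planted ground truth.

All generators are pure functions of their configuration and seed. The
generative model is log-normal: each gene has a latent log2 baseline
(the reference, time-0 state) and planted genes carry a monotone linear
trend in time (half increasing, half decreasing). Because only
within-sample orderings matter downstream, monotone per-sample
distortions of the output never change the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_differentiation_course",
    "generate_esc_pool",
    "generate_tumor_mixture",
    "apply_batch_distortion",
    "apply_dropout",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic generative model.

    ``effect_size`` is the slope of the planted monotone trend in log2
    expression per unit time; ``noise_sd`` the log2-scale Gaussian sd;
    ``dropout_rate`` the per-entry zeroing probability applied to
    single-cell-like outputs. ``seed`` is mandatory.
    """

    seed: int
    n_genes: int = 300
    n_stemness_genes: int = 40
    n_samples: int = 60
    n_timepoints: int = 6
    effect_size: float = 1.0
    noise_sd: float = 0.5
    dropout_rate: float = 0.0
    baseline_sd: float = 2.0
    count_mode: bool = False  # Poisson counts around scaled means

    def __post_init__(self) -> None:
        if self.n_stemness_genes > self.n_genes:
            raise ValueError("n_stemness_genes cannot exceed n_genes")
        if min(self.n_genes, self.n_samples, self.n_timepoints) < 1:
            raise ValueError("n_genes, n_samples and n_timepoints must be positive")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise_sd and baseline_sd must be nonnegative")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticDataset:
    """An ExpressionDataset plus planted ground truth."""

    dataset: ExpressionDataset
    gene_roles: pd.Series  # 'stem_up' | 'stem_down' | 'null' per gene
    true_time: Optional[pd.Series] = None
    true_origin_state: Optional[str] = None
    true_csc_flags: Optional[pd.Series] = None

    @property
    def planted_genes(self) -> List[str]:
        return list(self.gene_roles.index[self.gene_roles != "null"])


def _gene_names(n: int) -> List[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _latent_model(config: SyntheticConfig):
    """Baseline log2 means and planted slopes; depends only on the seed
    and the gene-structure fields, so courses, reference pools and
    mixtures built from one config share a single latent ordering."""
    rng = np.random.default_rng([config.seed, 0])
    base = rng.normal(loc=6.0, scale=config.baseline_sd, size=config.n_genes)
    slopes = np.zeros(config.n_genes)
    n_up = config.n_stemness_genes // 2
    slopes[:n_up] = config.effect_size
    slopes[n_up : config.n_stemness_genes] = -config.effect_size
    roles = np.array(["null"] * config.n_genes, dtype=object)
    roles[:n_up] = "stem_up"
    roles[n_up : config.n_stemness_genes] = "stem_down"
    return base, slopes, roles


def _materialise(
    log2_means: np.ndarray, rng: np.random.Generator, config: SyntheticConfig
) -> np.ndarray:
    noisy = log2_means + rng.normal(0.0, config.noise_sd, size=log2_means.shape)
    values = np.exp2(noisy)
    if config.count_mode:
        values = rng.poisson(values).astype(float)
    return values


def _maybe_dropout(values: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return values
    mask = (values > 0) & (rng.random(values.shape) < rate)
    out = values.copy()
    out[mask] = 0.0
    return out


def generate_differentiation_course(
    config: SyntheticConfig, dataset_id: str = "course", stream: int = 1
) -> SyntheticDataset:
    """A time course: samples spread evenly over the timepoints, planted
    genes trending monotonically (half up, half down) in log2 space."""
    base, slopes, roles = _latent_model(config)
    rng = np.random.default_rng([config.seed, stream])
    genes = _gene_names(config.n_genes)

    times = np.arange(config.n_samples) % config.n_timepoints
    times = np.sort(times).astype(float)
    log2_means = base[:, None] + slopes[:, None] * times[None, :]
    values = _materialise(log2_means, rng, config)
    values = _maybe_dropout(values, config.dropout_rate, rng)

    samples = [f"{dataset_id}_s{j:03d}" for j in range(config.n_samples)]
    meta = pd.DataFrame({"time": times}, index=samples)
    ds = ExpressionDataset.from_arrays(dataset_id, values, genes, samples, meta)
    return SyntheticDataset(
        dataset=ds,
        gene_roles=pd.Series(roles, index=genes),
        true_time=pd.Series(times, index=samples),
        true_origin_state="t0",
    )


def generate_esc_pool(
    config: SyntheticConfig, n_datasets_sc: int, n_datasets_bulk: int
) -> List[SyntheticDataset]:
    """Reference (maximal-stemness, time-0) datasets around one latent
    ordering: per-dataset scale factors and noise; single-cell-like
    datasets additionally pass through dropout."""
    if n_datasets_sc < 0 or n_datasets_bulk < 0:
        raise ValueError("dataset counts must be nonnegative")
    base, _slopes, roles = _latent_model(config)
    genes = _gene_names(config.n_genes)
    out: List[SyntheticDataset] = []
    kinds = [("sc", i) for i in range(n_datasets_sc)] + [
        ("bulk", i) for i in range(n_datasets_bulk)
    ]
    for d, (kind, i) in enumerate(kinds):
        rng = np.random.default_rng([config.seed, 100 + d])
        dataset_id = f"esc_{kind}_{i}"
        scale = rng.uniform(0.5, 2.0)  # monotone, order-preserving
        log2_means = np.repeat(base[:, None], config.n_samples, axis=1)
        values = _materialise(log2_means, rng, config) * scale
        if kind == "sc":
            values = _maybe_dropout(values, config.dropout_rate, rng)
        samples = [f"{dataset_id}_s{j:03d}" for j in range(config.n_samples)]
        meta = pd.DataFrame({"time": np.zeros(config.n_samples)}, index=samples)
        ds = ExpressionDataset.from_arrays(dataset_id, values, genes, samples, meta)
        out.append(
            SyntheticDataset(
                dataset=ds,
                gene_roles=pd.Series(roles, index=genes),
                true_time=pd.Series(np.zeros(config.n_samples), index=samples),
            )
        )
    return out


def generate_tumor_mixture(
    config: SyntheticConfig,
    csc_fraction: float,
    separation: float,
    dataset_id: str = "tumor",
) -> SyntheticDataset:
    """A two-component mixture: stem-like cells at the latent reference
    state (time 0) and differentiated cells at latent time ``separation``."""
    if not (0.0 < csc_fraction < 1.0):
        raise ValueError("csc_fraction must lie strictly between 0 and 1")
    base, slopes, roles = _latent_model(config)
    rng = np.random.default_rng([config.seed, 2])
    genes = _gene_names(config.n_genes)

    n_csc = int(round(csc_fraction * config.n_samples))
    n_csc = min(max(n_csc, 1), config.n_samples - 1)
    flags = np.zeros(config.n_samples, dtype=bool)
    flags[:n_csc] = True
    times = np.where(flags, 0.0, float(separation))

    log2_means = base[:, None] + slopes[:, None] * times[None, :]
    values = _materialise(log2_means, rng, config)
    values = _maybe_dropout(values, config.dropout_rate, rng)

    samples = [f"{dataset_id}_c{j:03d}" for j in range(config.n_samples)]
    meta = pd.DataFrame({"time": times, "csc_flag": flags}, index=samples)
    ds = ExpressionDataset.from_arrays(dataset_id, values, genes, samples, meta)
    return SyntheticDataset(
        dataset=ds,
        gene_roles=pd.Series(roles, index=genes),
        true_time=pd.Series(times, index=samples),
        true_csc_flags=pd.Series(flags, index=samples),
    )


def apply_batch_distortion(dataset: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Independent strictly increasing map per sample: x -> a * x**b with
    random a > 0 and b in [0.5, 2]. Zeros are preserved; within-sample
    ranks are unchanged."""
    rng = np.random.default_rng(seed)
    X = dataset.values.to_numpy(dtype=float).copy()
    m = X.shape[1]
    a = rng.uniform(0.2, 5.0, size=m)
    b = rng.uniform(0.5, 2.0, size=m)
    X = a[None, :] * np.power(X, b[None, :])
    values = pd.DataFrame(X, index=dataset.values.index, columns=dataset.values.columns)
    return ExpressionDataset(
        dataset_id=dataset.dataset_id, values=values, sample_meta=dataset.sample_meta
    )


def apply_dropout(dataset: ExpressionDataset, rate: float, seed: int) -> ExpressionDataset:
    """Zero each positive entry independently with probability ``rate``."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    X = dataset.values.to_numpy(dtype=float)
    mask = (X > 0) & (rng.random(X.shape) < rate)
    out = X.copy()
    out[mask] = 0.0
    values = pd.DataFrame(out, index=dataset.values.index, columns=dataset.values.columns)
    return ExpressionDataset(
        dataset_id=dataset.dataset_id, values=values, sample_meta=dataset.sample_meta
    )
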