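import numpy as np
import pandas as pd
import pytest

from stemsc import ExpressionDataset


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    # g1 always highest; (g2, g3) flips between samples
    values = pd.DataFrame(
        {
            "s1": [5.0, 1.0, 3.0],
            "s2": [6.0, 2.0, 1.0],
            "s3": [7.0, 3.0, 5.0],
            "s4": [8.0, 4.0, 2.0],
        },
        index=["g1", "g2", "g3"],
    )
    return ExpressionDataset(dataset_id="tiny", values=values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_dataset(
    rng: np.random.Generator,
    n_genes: int,
    n_samples: int,
    dataset_id: str = "random",
    tie_fraction: float = 0.0,
) -> ExpressionDataset:
    values = rng.lognormal(mean=2.0, sigma=1.0, size=(n_genes, n_samples))
    if tie_fraction > 0:
        # inject exact ties / zeros to exercise the tie rules
        mask = rng.random(values.shape) < tie_fraction
        values[mask] = np.round(values[mask])
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return ExpressionDataset.from_arrays(dataset_id, values, genes, samples)
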