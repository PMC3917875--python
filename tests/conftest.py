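import numpy as np
import pytest
from hypothesis import settings

from coexmod.preprocess import ExpressionDataset, zscore_genes

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


def make_dataset(
    values, dataset_id="T", context="tumor", gene_ids=None, sample_ids=None
):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionDataset(
        dataset_id=dataset_id,
        context=context,
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        sample_ids=sample_ids or [f"s{j}" for j in range(n)],
        values=values,
    )


@pytest.fixture(scope="session")
def small_bimodal_dataset():
    """60 genes x 120 samples: two 10-gene on/off groups with distinct latents
    plus 40 pure-noise genes; z-scored."""
    rng = np.random.default_rng(20)
    n = 120
    lat_a = rng.binomial(1, 0.4, n)
    lat_b = rng.binomial(1, 0.4, n)
    rows = []
    for _ in range(10):
        rows.append(3.0 * lat_a + rng.standard_normal(n))
    for _ in range(10):
        rows.append(3.0 * lat_b + rng.standard_normal(n))
    for _ in range(40):
        rows.append(rng.standard_normal(n))
    ds = make_dataset(np.array(rows), dataset_id="SB")
    return zscore_genes(ds)
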