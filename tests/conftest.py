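import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pdxnet import enrichment, normalize, simulate

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene, 20-sample cohort with marker, cluster and target effects."""
    cfg = simulate.CohortConfig(
        n_genes=300,
        n_samples=20,
        n_cluster_a=12,
        n_cluster_genes=50,
        resistant_fraction=0.3,
        seed=11,
    )
    return simulate.generate_expression_cohort(cfg)


@pytest.fixture(scope="session")
def log2_cohort(small_cohort):
    expr, _ = small_cohort
    transformed, _ = normalize.normalize(expr)
    return transformed


@pytest.fixture(scope="session")
def rank_stats(log2_cohort):
    return enrichment.kernel_cdf_statistic(log2_cohort)


@pytest.fixture()
def target_set():
    return enrichment.GeneSet("tumorigenic_network", simulate.TARGET_SET)


def make_rank_stats(rank: np.ndarray, gene_ids=None, sample_ids=None):
    """RankStatistics from an explicit 1-based rank matrix (z unused by the scorer)."""
    p, n = rank.shape
    gene_ids = gene_ids or [f"G{i:03d}" for i in range(p)]
    sample_ids = sample_ids or [f"S{j}" for j in range(n)]
    return enrichment.RankStatistics(
        z=np.zeros((p, n)), rank=rank.astype(np.int64),
        gene_ids=list(gene_ids), sample_ids=list(sample_ids),
    )
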