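import numpy as np
import pandas as pd
import pytest

from rtksubtyper import ExpressionSimConfig, generate_expression
from rtksubtyper.phenotype import PhenotypeCentroids, build_centroids


@pytest.fixture(scope="session")
def planted():
    """A small well-separated three-subtype cohort with known truth."""
    cfg = ExpressionSimConfig(
        n_samples_per_subtype=(10, 10, 20),
        n_genes=200,
        n_marker_genes_per_block=20,
        marker_effect=4.0,
        noise_sd=0.5,
        seed=42,
    )
    return generate_expression(cfg)


@pytest.fixture(scope="session")
def phenotype_genes(planted):
    """Phenotype signature genes: all planted block markers plus AXL/MERTK."""
    genes = [g for s in ("S1", "S2", "S3") for g in planted.true_marker_sets[s]]
    return genes + ["AXL", "MERTK"]


@pytest.fixture(scope="session")
def reference_centroids(phenotype_genes):
    """Invasive/proliferative centroids from an independent reference cohort."""
    cfg = ExpressionSimConfig(
        n_samples_per_subtype=(10, 10, 20),
        n_genes=200,
        n_marker_genes_per_block=20,
        marker_effect=4.0,
        noise_sd=0.5,
        seed=977,
    )
    ref = generate_expression(cfg)
    return build_centroids(ref.matrix, ref.true_phenotype, phenotype_genes)


def random_distance_matrix(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A random symmetric zero-diagonal distance matrix on n points."""
    d = rng.uniform(0.05, 2.0, (n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame(d, index=ids, columns=ids)
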