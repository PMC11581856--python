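import numpy as np
import pandas as pd
import pytest

from immunosubtype import io, scoring, synthetic


@pytest.fixture(scope="session")
def default_cfg():
    """The generator's default study conditions (200 samples, 2000 genes)."""
    return synthetic.SimConfig(seed=11)


@pytest.fixture(scope="session")
def default_bulk(default_cfg):
    return synthetic.generate_bulk_cohort(default_cfg)


@pytest.fixture(scope="session")
def default_lognorm(default_bulk):
    return io.lognormalize(default_bulk.expression)


@pytest.fixture(scope="session")
def default_gene_sets(default_cfg):
    return synthetic.export_gene_sets(default_cfg)


@pytest.fixture(scope="session")
def default_immune_scores(default_lognorm, default_gene_sets):
    return scoring.immune_stromal_scores(
        default_lognorm, default_gene_sets["immune"],
        default_gene_sets["stromal_set"])


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced cohort for the slower network/clustering paths."""
    return synthetic.SimConfig(seed=23, n_samples=100, n_genes=500)


@pytest.fixture(scope="session")
def small_bulk(small_cfg):
    return synthetic.generate_bulk_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_lognorm(small_bulk):
    return io.lognormalize(small_bulk.expression)


@pytest.fixture
def toy_counts():
    """A tiny deterministic counts matrix."""
    return io.ExpressionMatrix(pd.DataFrame(
        [[10.0, 0.0, 3.0], [0.0, 5.0, 2.0], [1.0, 1.0, 0.0]],
        index=["g1", "g2", "g3"], columns=["s1", "s2", "s3"]))
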