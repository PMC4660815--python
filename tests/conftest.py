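import numpy as np
import pytest

from bhit.data import Column, MixedDataset
from bhit.priors import PriorConfig


@pytest.fixture
def toy3():
    """Three independent columns (2 discrete + 1 continuous, 40 rows): a flat
    posterior over the 5 set partitions, good for exactness checks."""
    rng = np.random.default_rng(0)
    ds = MixedDataset(
        [
            Column("D1", "discrete", "genotype", rng.integers(0, 3, 40), 3),
            Column("D2", "discrete", "genotype", rng.integers(0, 3, 40), 3),
            Column("Y", "continuous", "phenotype", rng.standard_normal(40)),
        ]
    )
    return ds, PriorConfig.empirical(ds)


@pytest.fixture
def dependent3():
    """Three columns where D2 tracks D1 and Y shifts with D1: the dependent
    grouping should dominate the posterior."""
    rng = np.random.default_rng(7)
    d1 = rng.integers(0, 3, 60)
    d2 = (d1 + (rng.random(60) < 0.15)).astype(int) % 3
    y = 2.0 * d1 + rng.standard_normal(60)
    ds = MixedDataset(
        [
            Column("D1", "discrete", "genotype", d1, 3),
            Column("D2", "discrete", "genotype", d2, 3),
            Column("Y", "continuous", "phenotype", y),
        ]
    )
    return ds, PriorConfig.empirical(ds)
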