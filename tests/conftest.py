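import numpy as np
import pandas as pd
import pytest

import teointro as t
from teointro.simulate import Scenario, Tract


@pytest.fixture(scope="session")
def small_layout() -> t.GenomeLayout:
    chroms = ("chr1", "chr2")
    return t.GenomeLayout(
        chroms, {c: 50_000_000 for c in chroms}, {c: 22_000_000 for c in chroms}
    )


@pytest.fixture(scope="session")
def tract_scenario(small_layout) -> Scenario:
    tracts = (
        Tract("chr1", 5_000_000, 7_000_000, 0.8),
        Tract("chr2", 30_000_000, 32_000_000, 0.8),
    )
    return Scenario(layout=small_layout, tracts=tracts)


@pytest.fixture(scope="session")
def tract_table(tract_scenario):
    table, truth = t.simulate_sitefreq(tract_scenario, seed=42)
    return table, truth


@pytest.fixture(scope="session")
def f2_map(small_layout) -> pd.DataFrame:
    return t.true_map_table(small_layout, markers_per_chrom=80, map_length_cM=100, rng=7)


@pytest.fixture(scope="session")
def f2_matrix(f2_map):
    mat, truth = t.simulate_f2(
        f2_map, n=170, error_rate=0.01, missing_rate=0.05, seed=11
    )
    return mat, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
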