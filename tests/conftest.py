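import numpy as np
import pytest

from cnasl.cna import AlterationMatrix, ContingencyTable2x2
from cnasl.io import GisticTable
from cnasl.simulate import SimConfig, simulate_cohort, simulate_garp, simulate_pathways


@pytest.fixture
def table1():
    """The published 2x2 cell-line classification by TP53 (A) and CTCF (B)
    mutation state: 466 WT/WT, 6 WT/MUT, 584 MUT/WT, 17 MUT/MUT."""
    return ContingencyTable2x2(n11=17, n10=584, n01=6, n00=466)


@pytest.fixture
def small_gistic():
    scores = np.array([[-2, 0], [1, -1], [0, 2]], dtype=np.int8)
    return GisticTable(["g1", "g2", "g3"], ["s1", "s2"], scores)


@pytest.fixture
def small_matrix():
    M = np.array([
        [1, 1, 0, 0, 0],
        [0, 0, 1, 1, 0],
        [1, 0, 1, 0, 0],
    ], dtype=np.uint8)
    return AlterationMatrix(["a", "b", "c"], [f"p{i}" for i in range(5)], M)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study: 500 patients, 20 segments, one planted
    mutually exclusive driver pair (eps=0.05) with GARP and pathway signal."""
    cfg = SimConfig(seed=1)
    gistic, loci, truth = simulate_cohort(cfg)
    return cfg, gistic, loci, truth


@pytest.fixture(scope="session")
def default_garp(default_cohort):
    cfg, _, _, truth = default_cohort
    return simulate_garp(truth, cfg)


@pytest.fixture(scope="session")
def default_pathways(default_cohort):
    cfg, _, _, truth = default_cohort
    return simulate_pathways(truth, cfg)
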