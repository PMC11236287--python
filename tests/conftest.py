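from pathlib import Path

import pytest

from famcluster import (
    ClusterParams,
    FamilyTable,
    GeneRecord,
    GenomeInfo,
    find_clusters,
)
from famcluster.simulate import SimParams, simulate_family, simulate_tree


def make_table(intervals, family="fam", scaffold="chr1"):
    """Build a FamilyTable from (start, end) or (scaffold, start, end) tuples."""
    records = []
    for i, iv in enumerate(intervals):
        if len(iv) == 2:
            scf, (start, end) = scaffold, iv
        else:
            scf, start, end = iv
        records.append(GeneRecord(scf, start, end, f"g{i + 1}", "+", family))
    return FamilyTable(family, records)


@pytest.fixture
def genome():
    return GenomeInfo(10.0)  # 10 Mb


@pytest.fixture
def small_family(genome):
    # consecutive gaps on chr1: 10 kb, 15 kb, 485 kb
    table = make_table([(0, 1000), (11_000, 12_000), (27_000, 28_000),
                        (513_000, 514_000)])
    return table


@pytest.fixture
def sim_default():
    params = SimParams(seed=11)
    table, truth = simulate_family(params)
    return params, table, truth


@pytest.fixture
def sim_with_tree(sim_default):
    params, table, truth = sim_default
    newick = simulate_tree(truth, params)
    return params, table, truth, newick
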