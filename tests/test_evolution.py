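"""Patristic distances, C_ST and the Mann-Whitney rank test."""

import io
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from famcluster import (
    ClusterParams,
    EvolDistMatrix,
    GenomeInfo,
    compute_cst,
    find_clusters,
    mann_whitney_u,
    parse_newick,
    patristic_matrix,
)
from famcluster.errors import ConsistencyError, InputError, ParseError
from famcluster.simulate import SimParams, simulate_family, simulate_tree

from conftest import make_table


# ---------------------------------------------------------------------------
# Newick parsing

class TestParseNewick:
    def test_three_leaf_tree(self):
        tree = parse_newick("((A:1,B:2):1,C:4);")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == ["A", "B", "C"]

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            parse_newick("((A:1,A:2):1,C:4);")

    def test_polytomy_accepted(self):
        tree = parse_newick("((A:1,B:2,C:0.5):1,D:4);")
        assert len(list(tree.leaf_node_iter())) == 4

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ParseError, match="branch length"):
            parse_newick("((A:1,B):1,C:4);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ParseError):
            parse_newick("((A:1,B:2:1,C:4);")

    def test_quoted_labels_and_scientific_notation(self):
        tree = parse_newick("(('sp one':1e-3,B:2.5e0):1,C:4);")
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        assert "sp one" in labels

    def test_file_path_input(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:2):1,C:4);\n")
        assert len(list(parse_newick(p).leaf_node_iter())) == 3


# ---------------------------------------------------------------------------
# patristic distances

def _random_newick(rng, labels):
    """Random binary Newick with exponential branch lengths (independent of
    the package's tree machinery)."""

    def sub(lbls):
        if len(lbls) == 1:
            return f"{lbls[0]}:{rng.exponential(0.5) + 0.01:.6f}"
        k = int(rng.integers(1, len(lbls)))
        return f"({sub(lbls[:k])},{sub(lbls[k:])}):{rng.exponential(0.5) + 0.01:.6f}"

    return sub(list(labels)).rsplit(":", 1)[0] + ";"


class TestPatristicMatrix:
    def test_hand_computed_example(self):
        m = patristic_matrix(parse_newick("((A:1,B:2):1,C:4);"))
        f = m.to_frame()
        assert f.loc["A", "B"] == 3
        assert f.loc["A", "C"] == 6
        assert f.loc["B", "C"] == 7
        assert np.all(np.diag(m.values) == 0)

    def test_star_tree_all_distances_two(self):
        m = patristic_matrix(parse_newick("(A:1,B:1,C:1,D:1);"))
        off = m.values[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 2.0)

    def test_agrees_with_independent_biopython_oracle(self):
        from Bio import Phylo

        rng = np.random.default_rng(5)
        for _ in range(20):
            labels = [f"t{i}" for i in range(8)]
            nwk = _random_newick(rng, labels)
            m = patristic_matrix(parse_newick(nwk))
            btree = Phylo.read(io.StringIO(nwk), "newick")
            for a, b in itertools.combinations(labels, 2):
                expected = btree.distance(a, b)
                got = m.to_frame().loc[a, b]
                assert got == pytest.approx(expected, rel=1e-9)

    def test_root_invariance(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            labels = [f"t{i}" for i in range(8)]
            tree = parse_newick(_random_newick(rng, labels))
            before = patristic_matrix(tree).to_frame()
            internal = [
                nd for nd in tree.preorder_node_iter()
                if not nd.is_leaf() and nd is not tree.seed_node
            ]
            node = internal[int(rng.integers(len(internal)))]
            tree.reroot_at_node(node, update_bipartitions=False)
            after = patristic_matrix(tree).to_frame()
            assert np.allclose(
                before.loc[labels, labels].values,
                after.loc[labels, labels].values,
                atol=1e-9,
            )

    def test_triangle_inequality(self):
        rng = np.random.default_rng(23)
        labels = [f"t{i}" for i in range(10)]
        m = patristic_matrix(parse_newick(_random_newick(rng, labels))).values
        n = len(labels)
        for i, j, k in itertools.permutations(range(n), 3):
            assert m[i, j] <= m[i, k] + m[k, j] + 1e-9

    def test_single_leaf_rejected(self):
        with pytest.raises((InputError, ParseError)):
            patristic_matrix(parse_newick("(A:1);"))


# ---------------------------------------------------------------------------
# Mann-Whitney

def exact_mwu_two_sided(x, y):
    """Enumeration oracle: exact two-sided p for tie-free samples by
    enumerating all C(n+m, n) rank assignments."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n, m = len(x), len(y)

    def u_of(xs):
        return sum(1 for xi in xs for yj in set(pooled) - set(xs) if xi > yj)

    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = [u_of(set(c)) for c in itertools.combinations(pooled, n)]
    mean_u = n * m / 2
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u))
    return u_obs, extreme / len(us)


class TestMannWhitney:
    def test_spec_example_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1, abs=1e-12)
        # enumeration oracle agrees
        u_o, p_o = exact_mwu_two_sided([1, 2, 3], [4, 5, 6])
        assert (u_o, p_o) == (0, 0.1)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0] * 4, [1.0, 2.0, 3.0] * 4)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_u([], [1.0])

    def test_agreement_with_enumeration_on_random_samples(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n, m = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            x = list(np.round(rng.normal(size=n), 6))
            y = list(np.round(rng.normal(size=m), 6))
            u, p = mann_whitney_u(x, y)
            u_o, p_o = exact_mwu_two_sided(x, y)
            assert u == u_o
            assert p == pytest.approx(p_o, abs=1e-6)


# ---------------------------------------------------------------------------
# C_ST

def _matrix(ids, fill):
    n = len(ids)
    values = np.full((n, n), float(fill))
    np.fill_diagonal(values, 0.0)
    return EvolDistMatrix(list(ids), values)


def _clustered_setup(genome_mb=10.0):
    table = make_table([(0, 1000), (2000, 3000), (10**6, 10**6 + 1000),
                        (2 * 10**6, 2 * 10**6 + 1000)])
    genome = GenomeInfo(genome_mb)
    cs = find_clusters(table, ClusterParams.from_g(10_000, 4, genome))
    assert [c.members for c in cs.clusters] == [["g1", "g2"]]
    return table, cs


class TestComputeCst:
    def test_equal_distances_give_zero(self):
        table, cs = _clustered_setup()
        m = _matrix(table.gene_ids, 0.4)
        res = {r.scope: r for r in compute_cst(m, cs, table)}
        assert res["genome"].c_st == pytest.approx(0.0)
        assert res["chr1"].c_st == pytest.approx(0.0)

    def test_identical_clustered_copies_give_one(self):
        table, cs = _clustered_setup()
        m = _matrix(table.gene_ids, 0.4)
        m.values[0, 1] = m.values[1, 0] = 0.0  # g1,g2 are the cluster
        res = {r.scope: r for r in compute_cst(m, cs, table)}
        assert res["genome"].c_st == pytest.approx(1.0)

    def test_direct_substitution(self):
        # D_T = 0.4, D_C = 0.1 -> C_ST = 0.75
        table, cs = _clustered_setup()
        m = _matrix(table.gene_ids, 0.5)
        m.values[0, 1] = m.values[1, 0] = 0.1
        res = {r.scope: r for r in compute_cst(m, cs, table)}
        d_t = res["genome"].d_t
        assert res["genome"].c_st == pytest.approx((d_t - 0.1) / d_t)

    def test_missing_when_no_within_pairs(self):
        table = make_table([(0, 1000), (10**6, 10**6 + 1000)])
        genome = GenomeInfo(10.0)
        cs = find_clusters(table, ClusterParams.from_g(10_000, 2, genome))
        m = _matrix(table.gene_ids, 0.4)
        res = {r.scope: r for r in compute_cst(m, cs, table)}
        assert res["genome"].c_st is None
        assert res["genome"].missing_reason == "no_within_cluster_pairs"

    def test_missing_when_total_distance_zero(self):
        table, cs = _clustered_setup()
        m = _matrix(table.gene_ids, 0.0)
        res = {r.scope: r for r in compute_cst(m, cs, table)}
        assert res["genome"].c_st is None
        assert res["genome"].missing_reason == "zero_total_distance"

    def test_gene_missing_from_matrix_is_error(self):
        table, cs = _clustered_setup()
        m = _matrix(table.gene_ids[:-1], 0.4)
        with pytest.raises(ConsistencyError):
            compute_cst(m, cs, table)

    def test_invariant_to_gene_ordering(self, sim_with_tree):
        params, table, truth, newick = sim_with_tree
        cs = find_clusters(table, truth.params)
        m = patristic_matrix(parse_newick(newick))
        res1 = compute_cst(m, cs, table)
        shuffled = EvolDistMatrix(m.gene_ids[::-1],
                                  m.values[::-1, ::-1].copy())
        res2 = compute_cst(shuffled, cs, table)
        for a, b in zip(res1, res2):
            assert a.scope == b.scope
            assert a.c_st == pytest.approx(b.c_st)
            assert a.mwu_p == pytest.approx(b.mwu_p)

    def test_scopes_cover_scaffolds_and_genome(self, sim_with_tree):
        params, table, truth, newick = sim_with_tree
        cs = find_clusters(table, truth.params)
        m = patristic_matrix(parse_newick(newick))
        scopes = [r.scope for r in compute_cst(m, cs, table)]
        assert scopes == table.scaffolds + ["genome"]


class TestCstOnSimulations:
    def test_shrink_produces_positive_cst_increasing_as_s_decreases(self):
        means = {}
        for s in (1.0, 0.5, 0.2):
            vals = []
            for seed in range(40):
                params = SimParams(seed=seed, within_shrink_s=s)
                table, truth = simulate_family(params)
                cs = find_clusters(table, truth.params)
                m = patristic_matrix(parse_newick(simulate_tree(truth, params)))
                res = {r.scope: r for r in compute_cst(m, cs, table)}
                vals.append(res["genome"].c_st)
            means[s] = float(np.mean(vals))
        assert means[0.2] > means[0.5] > 0
        assert abs(means[1.0]) < 0.1  # null centred near zero

    def test_null_pvalues_uniform(self):
        # Kolmogorov-Smirnov on the rank-test p-values across null replicates
        ps = []
        for seed in range(500):
            params = SimParams(seed=seed, within_shrink_s=1.0)
            table, truth = simulate_family(params)
            cs = find_clusters(table, truth.params)
            m = patristic_matrix(parse_newick(simulate_tree(truth, params)))
            res = {r.scope: r for r in compute_cst(m, cs, table)}
            ps.append(res["genome"].mwu_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
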