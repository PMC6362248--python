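import math

import numpy as np
import pytest
import skbio
from skbio import DistanceMatrix

from tssmine import msa
from tssmine import phylogeny as phylo
from tssmine import synthetic_data as sd


def _aln(rows):
    return msa.MultipleAlignment(tuple(rows))


def _random_rows(rng, n_rows, n_cols, p_diff=0.1):
    base = rng.choice(list("ACGT"), size=n_cols)
    rows = []
    for i in range(n_rows):
        row = base.copy()
        mask = rng.random(n_cols) < p_diff
        row[mask] = rng.choice(list("ACGT"), size=int(mask.sum()))
        rows.append((f"t{i}", "".join(row)))
    return rows


class TestDistances:
    def test_identical_rows_zero(self):
        aln = _aln([("a", "ACGTAC"), ("b", "ACGTAC"), ("c", "ACGTAC")])
        dm = phylo.pairwise_distances(aln, "p")
        assert np.allclose(dm.data, 0.0)

    def test_p_distance_arithmetic(self):
        base = "ACGT" * 25
        # 10 transitions (A->G) at fixed sites of a 100-nt row
        changed = list(base)
        sites = [0, 4, 8, 12, 16, 20, 24, 28, 32, 36]
        for s in sites:
            changed[s] = "G"
        aln = _aln([("a", base), ("b", "".join(changed)), ("c", base)])
        dm = phylo.pairwise_distances(aln, "p")
        assert dm["a", "b"] == pytest.approx(0.10)

    def test_k2p_matches_closed_form(self, rng):
        """Independent per-pair tally + closed form vs the implementation."""
        rows = _random_rows(rng, 5, 400, p_diff=0.15)
        aln = _aln(rows)
        dm = phylo.pairwise_distances(aln, "k2p")
        purines = set("AG")
        for i in range(5):
            for j in range(i + 1, 5):
                a, b = rows[i][1], rows[j][1]
                P = sum(1 for x, y in zip(a, b)
                        if x != y and ((x in purines) == (y in purines))) / len(a)
                Q = sum(1 for x, y in zip(a, b)
                        if x != y and ((x in purines) != (y in purines))) / len(a)
                expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
                assert dm[rows[i][0], rows[j][0]] == pytest.approx(expected)

    def test_gap_sites_pairwise_deleted(self):
        aln = _aln([("a", "ACGT--GT"), ("b", "ACCT--GT"), ("c", "ACGTACGT")])
        dm = phylo.pairwise_distances(aln, "p")
        assert dm["a", "b"] == pytest.approx(1 / 6)

    def test_no_comparable_columns_error_names_pair(self):
        aln = _aln([("a", "AC--"), ("b", "--GT"), ("c", "ACGT")])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            phylo.pairwise_distances(aln, "p")

    def test_saturation_raises(self):
        # all-different rows saturate the K2P log
        aln = _aln([("a", "A" * 50), ("b", "G" * 50), ("c", "C" * 50)])
        with pytest.raises(ValueError, match="saturation"):
            phylo.pairwise_distances(aln, "k2p")


def _additive_matrix_from_tree(rng, n_taxa):
    """Random bifurcating topology with positive branch lengths -> exact
    leaf-to-leaf path-length (additive) matrix plus the true bipartitions."""
    nodes = [{"leaves": frozenset([i]), "children": None} for i in range(n_taxa)]
    lengths = {}
    items = list(range(n_taxa))
    next_id = n_taxa
    parent = {}
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False).tolist())
        a, b = items[i], items[j]
        for child in (a, b):
            lengths[child] = float(rng.uniform(0.05, 0.5))
            parent[child] = next_id
        nodes.append({"leaves": nodes[a]["leaves"] | nodes[b]["leaves"], "children": (a, b)})
        items = [x for x in items if x not in (a, b)] + [next_id]
        next_id += 1
    root = items[0]
    # path lengths between leaves
    def path_to_root(leaf):
        path, node, dist = {}, leaf, 0.0
        while node != root:
            path[node] = dist
            dist += lengths[node]
            node = parent[node]
        path[root] = dist
        return path
    D = np.zeros((n_taxa, n_taxa))
    paths = [path_to_root(i) for i in range(n_taxa)]
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            shared = set(paths[i]) & set(paths[j])
            d = min(paths[i][k] + paths[j][k] for k in shared)
            D[i, j] = D[j, i] = d
    bipartitions = set()
    leaf_names = [f"t{i}" for i in range(n_taxa)]
    for node in nodes[n_taxa:]:
        side = frozenset(leaf_names[i] for i in node["leaves"])
        other = frozenset(leaf_names) - side
        if len(side) >= 2 and len(other) >= 2:
            bipartitions.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return DistanceMatrix(D, leaf_names), bipartitions


class TestNeighborJoining:
    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_exact_recovery_on_additive_matrices(self, n_taxa):
        rng = np.random.default_rng(1000 + n_taxa)
        for rep in range(5):
            dm, true_parts = _additive_matrix_from_tree(rng, n_taxa)
            tree = phylo.neighbor_joining(dm)
            assert phylo._bipartitions(tree) == true_parts
            # additive matrices are reproduced exactly by the NJ tree
            for i, a in enumerate(dm.ids):
                for b in list(dm.ids)[i + 1:]:
                    ta, tb = tree.find(a), tree.find(b)
                    assert ta.distance(tb) == pytest.approx(dm[a, b], abs=1e-9)

    def test_four_taxon_topology_beats_alternatives(self):
        # additive matrix for ((A,B),(C,D)): the AB|CD split, not AC|BD or AD|BC
        dm = DistanceMatrix(
            [[0, 0.2, 0.7, 0.8], [0.2, 0, 0.7, 0.8], [0.7, 0.7, 0, 0.3], [0.8, 0.8, 0.3, 0]],
            ["A", "B", "C", "D"],
        )
        tree = phylo.neighbor_joining(dm)
        assert phylo._bipartitions(tree) == {frozenset({"A", "B"})}

    def test_star_matrix_gives_zero_internal_branches(self):
        n = 5
        D = np.full((n, n), 1.0)
        np.fill_diagonal(D, 0.0)
        tree = phylo.neighbor_joining(DistanceMatrix(D, [f"t{i}" for i in range(n)]))
        assert {t.name for t in tree.tips()} == {f"t{i}" for i in range(n)}
        for node in tree.non_tips(include_self=False):
            assert node.length == pytest.approx(0.0, abs=1e-12)

    def test_matches_skbio_on_random_matrices(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 9))
            dm, _ = _additive_matrix_from_tree(rng, n)
            mine = phylo._bipartitions(phylo.neighbor_joining(dm))
            theirs = phylo._bipartitions(skbio.tree.nj(dm))
            assert mine == theirs

    def test_leaf_set_and_newick_round_trip(self, rng):
        dm, _ = _additive_matrix_from_tree(rng, 6)
        tree = phylo.neighbor_joining(dm)
        assert {t.name for t in tree.tips()} == set(dm.ids)
        import io

        back = skbio.TreeNode.read(io.StringIO(phylo.tree_to_newick(tree)))
        assert phylo._bipartitions(back) == phylo._bipartitions(tree)


def _two_subfamily_alignment(model, n_per=8, seed=77):
    """Two sub-ancestors diverged from the model, copies from each."""
    params_div = sd.SimParams(seed=seed, genome_length=1, n_copies=1, p_sub=0.08)
    sub_a, _ = sd.mutate_copy(model.sequence, params_div, np.random.default_rng(seed))
    sub_b, _ = sd.mutate_copy(model.sequence, params_div, np.random.default_rng(seed + 1))
    params = sd.SimParams(seed=seed, genome_length=1, n_copies=1, p_sub=0.01)
    rows = []
    for i in range(n_per):
        sa, _ = sd.mutate_copy(sub_a, params, np.random.default_rng(seed + 10 + i))
        sb, _ = sd.mutate_copy(sub_b, params, np.random.default_rng(seed + 50 + i))
        rows.append((f"a{i}", sa))
        rows.append((f"b{i}", sb))
    return _aln(rows)


class TestBootstrap:
    def test_two_subfamilies_recovered_with_high_support(self, model):
        aln = _two_subfamily_alignment(model)
        tree = phylo.bootstrap_support(aln, n_replicates=100, seed=3)
        split = frozenset(f"a{i}" for i in range(8))
        parts = phylo._bipartitions(tree)
        assert split in parts or frozenset(f"b{i}" for i in range(8)) in parts
        supports = {
            frozenset(t.name for t in node.tips()): float(node.name)
            for node in tree.non_tips(include_self=False) if node.name
        }
        family_support = max(
            (s for side, s in supports.items()
             if side in (split, frozenset(f"b{i}" for i in range(8)))),
            default=0.0,
        )
        assert family_support >= 0.95

    def test_same_seed_same_supports(self, model):
        aln = _two_subfamily_alignment(model, n_per=4)
        t1 = phylo.bootstrap_support(aln, n_replicates=30, seed=9)
        t2 = phylo.bootstrap_support(aln, n_replicates=30, seed=9)
        assert phylo.tree_to_newick(t1) == phylo.tree_to_newick(t2)

    def test_identical_sequences_no_supported_structure(self):
        aln = _aln([(f"t{i}", "ACGTACGTACGT" * 10) for i in range(5)])
        tree = phylo.bootstrap_support(aln, n_replicates=20, seed=1, correction="p")
        for node in tree.non_tips(include_self=False):
            assert node.length == pytest.approx(0.0, abs=1e-12)
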