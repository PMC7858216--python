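import itertools

import dendropy
import numpy as np
import pytest

from plastbarcode.errors import DataError
from plastbarcode.phylo import (
    DistanceMatrix,
    SearchParams,
    bipartitions,
    bootstrap,
    fitch_score,
    mp_best_score,
    mp_search,
    nj_tree,
    p_distance_matrix,
    root_with_outgroup,
    strict_consensus,
    support_of,
)
from plastbarcode.seqio import Alignment, read_newick, write_newick

from conftest import random_alignment, random_topology_newick

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

STATE = {"A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T")}


def _state(ch):
    return STATE.get(ch, frozenset("ACGT"))  # gaps/ambiguity = wildcard


def oracle_fitch(topo, rows_by_label):
    """Recursive set-based Fitch on a nested-tuple topology, plain python."""
    L = len(next(iter(rows_by_label.values())))
    total = 0
    for c in range(L):
        def down(node):
            if isinstance(node, str):
                return _state(rows_by_label[node][c]), 0
            sets_costs = [down(ch) for ch in node]
            cur, cost = sets_costs[0]
            for s, extra in sets_costs[1:]:
                cost += extra
                inter = cur & s
                if inter:
                    cur = inter
                else:
                    cur = cur | s
                    cost += 1
            return cur, cost

        total += down(topo)[1]
    return total


def all_unrooted_topologies(labels):
    """Enumerate unrooted binary topologies as nested tuples rooted at
    labels[0] (pendant-edge rooting): recursive edge insertion."""
    if len(labels) == 3:
        yield (labels[0], (labels[1], labels[2]))
        return
    head, rest = labels[0], labels[1:]

    def insert(node, leaf):
        # yield all trees with `leaf` attached on an edge within `node`
        yield (node, leaf)
        if not isinstance(node, str):
            a, b = node
            for sub in insert(a, leaf):
                yield (sub, b)
            for sub in insert(b, leaf):
                yield (a, sub)

    def build(leaves):
        if len(leaves) == 1:
            yield leaves[0]
            return
        for partial in build(leaves[:-1]):
            yield from insert(partial, leaves[-1])

    for shape in build(rest):
        yield (head, shape)


def topo_bipartitions(topo, all_labels):
    """Canonical splits of a nested-tuple unrooted topology."""
    full = frozenset(all_labels)
    ref = sorted(all_labels)[0]
    out = set()

    def leaves(node):
        if isinstance(node, str):
            return frozenset([node])
        parts = [leaves(ch) for ch in node]
        s = frozenset().union(*parts)
        for p in parts:
            side = p if ref not in p else full - p
            if 2 <= len(side) <= len(all_labels) - 2:
                out.add(side)
        return s

    leaves(topo)
    return out


def nested_to_newick(topo):
    if isinstance(topo, str):
        return topo
    return "(" + ",".join(nested_to_newick(c) for c in topo) + ")"


def random_additive_matrix(rng, n):
    """Distance matrix of path lengths on a random binary tree with random
    positive branch lengths; returns (DistanceMatrix, true bipartitions)."""
    labels = [f"t{i}" for i in range(n)]
    nwk = random_topology_newick(rng, labels)
    tree = read_newick(nwk)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                m[i, j] = pdm.patristic_distance(taxa[a], taxa[b])
    return DistanceMatrix(tuple(labels), m), bipartitions(tree)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestDistances:
    def test_identical_zero(self):
        aln = Alignment(("a", "b"), ("ACGT", "ACGT"))
        assert p_distance_matrix(aln).matrix[0, 1] == 0.0

    def test_direct_count(self):
        aln = Alignment(("a", "b"), ("AAAA", "AATT"))
        assert p_distance_matrix(aln).matrix[0, 1] == pytest.approx(0.5)

    def test_jc_closed_form(self):
        # p = 0.1 -> d = -0.75 ln(1 - 0.4/3)
        aln = Alignment(("a", "b"), ("A" * 9 + "T", "A" * 10))
        d = p_distance_matrix(aln, model="jc").matrix[0, 1]
        assert d == pytest.approx(0.107326, abs=1e-6)

    def test_pairwise_deletion(self):
        aln = Alignment(("a", "b"), ("AA-T", "AANT"))
        assert p_distance_matrix(aln).matrix[0, 1] == 0.0

    def test_no_comparable_columns_names_pair(self):
        aln = Alignment(("a", "b"), ("A---", "-TTT"))
        with pytest.raises(DataError, match="'a' and 'b'"):
            p_distance_matrix(aln)

    def test_saturated_jc_capped_with_warning(self):
        aln = Alignment(("a", "b"), ("AAAA", "TTTT"))
        with pytest.warns(UserWarning, match="capped"):
            d = p_distance_matrix(aln, model="jc")
        assert np.isfinite(d.matrix[0, 1])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxa_unique_topology(self):
        d = DistanceMatrix(("a", "b", "c"), np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0.0]]))
        t = nj_tree(d)
        assert {lf.taxon.label for lf in t.leaf_node_iter()} == {"a", "b", "c"}
        assert bipartitions(t) == set()

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:1)) -> path-length matrix
        labels = ("a", "b", "c", "d")
        m = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
        )
        t = nj_tree(DistanceMatrix(labels, m))
        assert bipartitions(t) == {frozenset({"c", "d"})}
        lengths = {
            lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 3, "d": 1})

    def test_random_additive_recovery(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 11))
            d, true_bips = random_additive_matrix(rng, n)
            assert bipartitions(nj_tree(d)) == true_bips

    def test_matches_scikit_bio(self, rng):
        # independent NJ implementation as cross-check on noisy matrices
        import io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        for _ in range(10):
            n = int(rng.integers(5, 10))
            d, _ = random_additive_matrix(rng, n)
            noisy = d.matrix + rng.uniform(0, 0.01, size=d.matrix.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            dm = DistanceMatrix(d.ids, noisy)
            ours = nj_tree(dm)
            theirs_nwk = skbio_nj(SkbioDM(noisy, ids=list(d.ids))).write(
                io.StringIO()
            ).getvalue() if False else skbio_nj(SkbioDM(noisy, ids=list(d.ids)))
            buf = io.StringIO()
            theirs_nwk.write(buf)
            theirs = read_newick(buf.getvalue())
            assert bipartitions(ours) == bipartitions(theirs)

    def test_asymmetric_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(DataError):
            DistanceMatrix(("a", "b", "c"), m)


# ---------------------------------------------------------------------------
# Fitch score
# ---------------------------------------------------------------------------

class TestFitchScore:
    def test_invariant_alignment_zero(self):
        aln = Alignment(("t1", "t2", "t3", "t4"), ("AA",) * 4)
        assert fitch_score(read_newick("((t1,t2),(t3,t4));"), aln) == 0

    def test_single_change_column(self):
        aln = Alignment(("t1", "t2", "t3", "t4"), ("A", "A", "T", "T"))
        assert fitch_score(read_newick("((t1,t2),(t3,t4));"), aln) == 1

    def test_two_change_column(self):
        # A,T,A,T on ((1,2),(3,4)): every internal labeling costs >= 2
        aln = Alignment(("t1", "t2", "t3", "t4"), ("A", "T", "A", "T"))
        assert fitch_score(read_newick("((t1,t2),(t3,t4));"), aln) == 2

    def test_gaps_are_free_wildcards(self):
        aln = Alignment(("t1", "t2", "t3", "t4"), ("A", "-", "T", "N"))
        assert fitch_score(read_newick("((t1,t2),(t3,t4));"), aln) == 1

    def test_leaf_mismatch_rejected(self):
        aln = Alignment(("t1", "t2", "t3", "x"), ("A",) * 4)
        with pytest.raises(DataError):
            fitch_score(read_newick("((t1,t2),(t3,t4));"), aln)

    def test_matches_recursive_oracle_random(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            aln = random_alignment(rng, n, int(rng.integers(3, 30)), gap_frac=0.05)
            rows = dict(zip(aln.ids, aln.rows))
            topos = list(all_unrooted_topologies(labels))
            topo = topos[int(rng.integers(len(topos)))]
            tree = read_newick(nested_to_newick(topo) + ";")
            assert fitch_score(tree, aln) == oracle_fitch(topo, rows)


# ---------------------------------------------------------------------------
# maximum parsimony search
# ---------------------------------------------------------------------------

class TestMPSearch:
    def test_clean_four_taxon_signal(self):
        aln = Alignment(("t1", "t2", "t3", "t4"), ("AAAAA", "AAAAA", "TTTTT", "TTTTT"))
        trees = mp_search(aln, SearchParams(n_addition_replicates=3, seed=1))
        assert len(trees) == 1
        assert bipartitions(trees[0]) == {frozenset({"t3", "t4"})}
        assert fitch_score(trees[0], aln) == 5

    def test_determinism_under_fixed_seed(self, rng):
        aln = random_alignment(rng, 7, 40)
        p = SearchParams(n_addition_replicates=4, seed=99)
        t1 = [write_newick(t) for t in mp_search(aln, p)]
        t2 = [write_newick(t) for t in mp_search(aln, p)]
        assert t1 == t2

    def test_fewer_than_four_taxa_rejected(self, rng):
        with pytest.raises(DataError):
            mp_search(random_alignment(rng, 3, 10))

    def test_matches_exhaustive_on_small_instances(self, rng):
        for _ in range(12):
            n = int(rng.integers(5, 8))
            aln = random_alignment(rng, n, 20, gap_frac=0.03)
            rows = dict(zip(aln.ids, aln.rows))
            best_oracle = min(
                oracle_fitch(t, rows) for t in all_unrooted_topologies(list(aln.ids))
            )
            got = mp_best_score(aln, SearchParams(n_addition_replicates=5, seed=7))
            assert got == best_oracle

    def test_mp_beats_or_ties_nj(self, rng):
        for _ in range(5):
            aln = random_alignment(rng, 8, 60)
            nj = nj_tree(p_distance_matrix(aln))
            best = mp_best_score(aln, SearchParams(n_addition_replicates=5, seed=3))
            assert best <= fitch_score(nj, aln)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

class TestStrictConsensus:
    def test_idempotent_on_identical_trees(self):
        t = read_newick("((a,b),(c,(d,e)));")
        cons = strict_consensus([t, read_newick("((a,b),(c,(d,e)));")])
        assert bipartitions(cons) == bipartitions(t)

    def test_totally_conflicting_trees_give_star(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,c),(b,d));")
        assert bipartitions(strict_consensus([t1, t2])) == set()

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(DataError):
            strict_consensus([read_newick("((a,b),(c,d));"), read_newick("((a,b),(c,e));")])

    def test_random_sets_equal_intersection_oracle(self, rng):
        labels = [f"t{i}" for i in range(9)]
        for _ in range(20):
            trees = [
                read_newick(random_topology_newick(rng, labels)) for _ in range(3)
            ]
            expected = set.intersection(*(bipartitions(t) for t in trees))
            assert bipartitions(strict_consensus(trees)) == expected

    def test_consensus_agrees_with_dendropy(self, rng):
        # independent implementation cross-check
        labels = [f"t{i}" for i in range(8)]
        ns = dendropy.TaxonNamespace()
        trees = dendropy.TreeList(taxon_namespace=ns)
        for _ in range(3):
            trees.append(
                dendropy.Tree.get(
                    data=random_topology_newick(rng, labels),
                    schema="newick",
                    taxon_namespace=ns,
                )
            )
        theirs = trees.consensus(min_freq=1.0)
        ours = strict_consensus(list(trees))
        assert bipartitions(ours) == bipartitions(theirs)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_saturated_signal_full_support(self):
        aln = Alignment(
            ("a1", "a2", "b1", "b2"),
            ("A" * 30 + "C" * 30, "A" * 30 + "C" * 30, "T" * 30 + "C" * 30, "T" * 30 + "C" * 30),
        )
        t = bootstrap(aln, builder="nj", n_reps=50, seed=4)
        sup = [support_of(nd) for nd in t.postorder_internal_node_iter() if support_of(nd) is not None]
        assert sup and all(s == 100 for s in sup)

    def test_single_replicate_supports_binary(self, rng):
        aln = random_alignment(rng, 6, 40)
        t = bootstrap(aln, builder="nj", n_reps=1, seed=4)
        sup = [support_of(nd) for nd in t.postorder_internal_node_iter() if support_of(nd) is not None]
        assert set(sup) <= {0, 100}

    def test_two_seeds_agree_within_sampling_error(self, rng):
        aln = random_alignment(rng, 8, 200)
        t1 = bootstrap(aln, builder="nj", n_reps=200, seed=11)
        t2 = bootstrap(aln, builder="nj", n_reps=200, seed=22)
        from plastbarcode.phylo import supports_by_bipartition

        s1, s2 = supports_by_bipartition(t1), supports_by_bipartition(t2)
        for b in set(s1) & set(s2):
            assert abs(s1[b] - s2[b]) <= 10

    def test_row_permutation_invariance(self, rng):
        aln = random_alignment(rng, 6, 80)
        perm = sorted(aln.ids, key=lambda x: -int(x[1:]))
        from plastbarcode.phylo import supports_by_bipartition

        s1 = supports_by_bipartition(bootstrap(aln, builder="nj", n_reps=60, seed=5))
        s2 = supports_by_bipartition(bootstrap(aln.subset(perm), builder="nj", n_reps=60, seed=5))
        assert s1 == s2

    def test_mp_builder_runs(self, rng):
        aln = random_alignment(rng, 6, 60)
        t = bootstrap(
            aln, builder="mp", n_reps=20, seed=6,
            search_params=SearchParams(n_addition_replicates=1, seed=6),
        )
        assert {lf.taxon.label for lf in t.leaf_node_iter()} == set(aln.ids)


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

class TestRooting:
    def test_single_outgroup_pendant_root(self):
        t = root_with_outgroup(read_newick("((a,b),(c,o));"), ["o"])
        assert t.is_rooted
        kids = t.seed_node.child_nodes()
        sides = [{lf.taxon.label for lf in k.leaf_iter()} for k in kids]
        assert {"o"} in sides

    def test_outgroup_cherry_stem_root(self):
        t = root_with_outgroup(read_newick("((a,b),(o1,o2));"), ["o1", "o2"])
        sides = [
            {lf.taxon.label for lf in k.leaf_iter()} for k in t.seed_node.child_nodes()
        ]
        assert {"o1", "o2"} in sides

    def test_scattered_outgroup_rejected(self):
        with pytest.raises(DataError, match="monophyletic"):
            root_with_outgroup(read_newick("((a,o1),(b,o2));"), ["o1", "o2"])

    def test_supports_ride_along(self):
        t = read_newick("((a,b)91,((c,d)88,o));")
        rooted = root_with_outgroup(t, ["o"])
        from plastbarcode.phylo import supports_by_bipartition

        assert supports_by_bipartition(rooted) == supports_by_bipartition(t)
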