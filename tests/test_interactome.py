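"""Network assembly, pairwise-alignment distances, NJ trees, PHA candidate
expansion, expression clustering and database overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix

import crispra_screen as cs
from crispra_screen.fixtures import table1_edges, toy_expression_matrix
from crispra_screen.interactome import InteractionEdge


class TestBuildNetwork:
    def test_validated_interaction_counts(self):
        s = cs.build_network(table1_edges())
        assert s.n_edges == 22
        assert s.edges_by_library == {"TM1": 18, "TM2+": 4}
        assert s.n_ligands == 12
        assert s.ligands_by_library == {"TM1": 8, "TM2+": 4}

    def test_empty_edge_list(self):
        s = cs.build_network([])
        assert s.n_edges == 0
        assert s.n_ligands == 0

    def test_duplicate_pair_rejected(self):
        e = InteractionEdge("L1", "R1", "TM1", "Screen")
        swapped = InteractionEdge("R1", "L1", "TM1", "PHA")
        with pytest.raises(ValueError, match="duplicate"):
            cs.build_network([e, swapped])

    def test_counts_invariant_to_edge_order(self):
        edges = table1_edges()
        s1 = cs.build_network(edges)
        s2 = cs.build_network(list(reversed(edges)))
        assert s1.n_edges == s2.n_edges
        assert s1.ligands_by_library == s2.ligands_by_library

    def test_vocabulary_enforced(self):
        with pytest.raises(ValueError):
            InteractionEdge("L", "R", "TM9", "Screen")
        with pytest.raises(ValueError):
            InteractionEdge("L", "R", "TM1", "Guess")


def brute_force_alignments(a, b, open_=-10.0, extend=-1.0):
    """All global alignments of two short sequences with affine gaps:
    yields (score, identity) for every alignment path."""
    blosum = substitution_matrices.load("BLOSUM62")
    out = []

    def rec(i, j, prev, score, matches, length):
        if i == len(a) and j == len(b):
            out.append((score, matches / length if length else 0.0))
            return
        if i < len(a) and j < len(b):
            s = blosum[a[i], b[j]]
            rec(i + 1, j + 1, "D", score + s, matches + (a[i] == b[j]),
                length + 1)
        if i < len(a):
            gap = extend if prev == "U" else open_
            rec(i + 1, j, "U", score + gap, matches, length + 1)
        if j < len(b):
            gap = extend if prev == "L" else open_
            rec(i, j + 1, "L", score + gap, matches, length + 1)

    rec(0, 0, "", 0.0, 0, 0)
    return out


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert cs.pairwise_identity("MKTAYIAKQR", "MKTAYIAKQR") == 1.0

    @pytest.mark.parametrize("a,b", [("ACDE", "EDCA"), ("AAAA", "WWWW")])
    def test_matches_exhaustive_enumeration(self, a, b):
        alignments = brute_force_alignments(a, b)
        best = max(s for s, _ in alignments)
        optimal_identities = {
            round(ident, 12) for s, ident in alignments if s == best
        }
        assert round(cs.pairwise_identity(a, b), 12) in optimal_identities

    def test_disjoint_alphabets_give_zero(self):
        assert cs.pairwise_identity("AAAA", "WWWW") == 0.0

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            cs.pairwise_identity("ACDE", "AC1E")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.pairwise_identity("", "ACDE")


class TestDistanceMatrix:
    seqs = {"a": "MKTAYIAKQR", "b": "MKTAYIAKQW", "c": "GGGGSSGGGG"}

    def test_self_distance_zero_and_symmetry(self):
        dm = cs.distance_matrix(self.seqs)
        assert np.allclose(np.diag(dm.data), 0.0)
        assert np.allclose(dm.data, dm.data.T, atol=1e-12)

    def test_composition_of_pairwise_calls(self):
        dm = cs.distance_matrix(self.seqs)
        for x, y in itertools.combinations(self.seqs, 2):
            expected = 1.0 - cs.pairwise_identity(self.seqs[x], self.seqs[y])
            assert dm[x, y] == pytest.approx(expected, abs=1e-12)
        assert dm["a", "b"] < dm["a", "c"]  # identity bounds respected


def quartet_split(tree):
    """The non-trivial bipartition of a 4-taxon unrooted tree."""
    tips = {t.name for t in tree.tips()}
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if 1 < len(side) < len(tips) - 1:
            return frozenset([frozenset(side), frozenset(tips - side)])
    # skbio roots trivially; check children of root too
    for child in tree.children:
        side = {t.name for t in child.tips()}
        if 1 < len(side) < len(tips) - 1:
            return frozenset([frozenset(side), frozenset(tips - side)])
    raise AssertionError("no internal split found")


def least_squares_quartet(dm, split):
    """Fit branch lengths for a given quartet topology by least squares;
    returns the residual sum of squares."""
    (pair1, pair2) = [sorted(s) for s in split]
    a, b = pair1
    c, d = pair2
    # parameters: La, Lb, Lc, Ld, Lint
    rows, rhs = [], []
    paths = {
        (a, b): [1, 1, 0, 0, 0],
        (c, d): [0, 0, 1, 1, 0],
        (a, c): [1, 0, 1, 0, 1],
        (a, d): [1, 0, 0, 1, 1],
        (b, c): [0, 1, 1, 0, 1],
        (b, d): [0, 1, 0, 1, 1],
    }
    for (x, y), row in paths.items():
        rows.append(row)
        rhs.append(dm[x, y])
    sol, *_ = np.linalg.lstsq(np.array(rows, float), np.array(rhs), rcond=None)
    resid = np.array(rows) @ sol - np.array(rhs)
    return float(resid @ resid)


class TestNJTree:
    def additive_quartet(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        d = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        return DistanceMatrix(d, ids=list("ABCD"))

    def test_additive_quartet_exact(self):
        dm = self.additive_quartet()
        tree = cs.nj_tree(dm)
        td = tree.tip_tip_distances()
        for x, y in itertools.combinations("ABCD", 2):
            assert td[x, y] == pytest.approx(dm[x, y], abs=1e-9)

    def test_topology_matches_least_squares_minimum(self):
        dm = self.additive_quartet()
        splits = [
            frozenset([frozenset("AB"), frozenset("CD")]),
            frozenset([frozenset("AC"), frozenset("BD")]),
            frozenset([frozenset("AD"), frozenset("BC")]),
        ]
        rss = {s: least_squares_quartet(dm, s) for s in splits}
        best = min(rss, key=rss.get)
        assert quartet_split(cs.nj_tree(dm)) == best

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        dm = DistanceMatrix(d, ids=list("abc"))
        tree = cs.nj_tree(dm)
        td = tree.tip_tip_distances()
        for x, y in itertools.combinations("abc", 2):
            assert td[x, y] == pytest.approx(dm[x, y], abs=1e-9)

    def test_ultrametric_hierarchy(self):
        # A,B closest (d=2), then C (d=6), then D (d=10)
        d = np.array(
            [[0, 2, 6, 10], [2, 0, 6, 10], [6, 6, 0, 10], [10, 10, 10, 0]],
            float,
        )
        tree = cs.nj_tree(DistanceMatrix(d, ids=list("ABCD")))
        split = quartet_split(tree)
        assert frozenset("AB") in split

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            cs.nj_tree(DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"]))

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        tree = cs.nj_tree(DistanceMatrix(d, ids=[f"t{i}" for i in range(6)]))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0


class TestPhaCandidates:
    def engineered(self):
        labels = ["SEED", "N1", "N2", "FAR"]
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 0.2
        d[0, 2] = d[2, 0] = 0.5
        d[0, 3] = d[3, 0] = 0.9
        d[1, 2] = d[2, 1] = 0.4
        d[1, 3] = d[3, 1] = 0.8
        d[2, 3] = d[3, 2] = 0.6
        return DistanceMatrix(d, ids=labels)

    def test_delta_zero_empty(self):
        seqs = {"a": "MKTAYIAKQR", "b": "MKTAYIAKQW"}
        assert cs.pha_candidates("a", seqs, delta=0.0) == []

    def test_delta_one_returns_all(self):
        dm = self.engineered()
        assert [c for c, _ in cs.pha_candidates("SEED", dm, 1.0)] == [
            "N1", "N2", "FAR",
        ]

    def test_engineered_threshold(self):
        dm = self.engineered()
        assert [c for c, _ in cs.pha_candidates("SEED", dm, 0.6)] == ["N1", "N2"]

    def test_missing_seed(self):
        with pytest.raises(KeyError):
            cs.pha_candidates("NOPE", self.engineered(), 0.5)


def ward_oracle(dist):
    """Brute-force agglomeration recomputing the Ward (Lance-Williams)
    update at every step; returns the merge order (as frozensets)."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {
        frozenset((i, j)): dist[i, j]
        for i, j in itertools.combinations(range(n), 2)
    }
    merges = []
    next_id = n
    while len(clusters) > 1:
        key = min(
            (k for k in d if k.issubset(clusters.keys())),
            key=lambda k: (d[k], sorted(k)),
        )
        i, j = sorted(key)
        merges.append(clusters[i] | clusters[j])
        ni, nj = sizes[i], sizes[j]
        dij = d[frozenset((i, j))]
        for k in list(clusters):
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d[frozenset((i, k))]
            djk = d[frozenset((j, k))]
            new = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            d[frozenset((next_id, k))] = new
        clusters[next_id] = clusters[i] | clusters[j]
        sizes[next_id] = ni + nj
        del clusters[i], clusters[j]
        next_id += 1
    return merges


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self):
        expr = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [9, 1, 7, 2]],
            index=["a", "b", "c"],
            columns=["t1", "t2", "t3", "t4"],
        ).astype(float)
        # a and b are perfectly correlated -> correlation distance 0
        res = cs.hierarchical_cluster(expr)
        first = res.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        from crispra_screen.interactome import _correlation_condensed

        values = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert _correlation_condensed(values)[0] == pytest.approx(2.0)

    def test_merge_order_matches_ward_oracle(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            np.abs(rng.normal(5, 2, size=(5, 8))),
            index=[f"g{i}" for i in range(5)],
        )
        from scipy.spatial.distance import squareform

        from crispra_screen.interactome import _correlation_condensed

        res = cs.hierarchical_cluster(expr)
        dist = squareform(_correlation_condensed(expr.to_numpy()))
        expected = ward_oracle(dist)
        got = []
        members = {i: frozenset([i]) for i in range(5)}
        for step, row in enumerate(res.linkage):
            merged = members[int(row[0])] | members[int(row[1])]
            members[5 + step] = merged
            got.append(merged)
        assert got == expected

    def test_constant_row_warns(self):
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]],
            index=["const", "a", "b"],
        )
        with pytest.warns(UserWarning, match="constant"):
            cs.hierarchical_cluster(expr)

    def test_two_way_mode(self):
        expr = toy_expression_matrix()
        genes, tissues = __import__(
            "crispra_screen.interactome", fromlist=["two_way_cluster"]
        ).two_way_cluster(expr)
        assert sorted(genes.leaf_order) == sorted(expr.index)
        assert sorted(tissues.leaf_order) == sorted(expr.columns)

    def test_coexpression_blocks_cluster_together(self):
        expr = toy_expression_matrix()
        res = cs.hierarchical_cluster(expr)
        order = res.leaf_order
        block_a = {"LIG_A", "REC_A", "LIG_B"}
        positions = [order.index(g) for g in block_a]
        assert max(positions) - min(positions) == 2  # contiguous block


class TestCorrelationHeatmap:
    def test_diagonal_and_symmetry(self):
        expr = toy_expression_matrix()
        corr = cs.correlation_heatmap(expr)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T, atol=1e-12)

    def test_anticorrelated_rows(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["x", "y"]
        )
        assert cs.correlation_heatmap(expr).loc["x", "y"] == pytest.approx(-1.0)

    def test_three_gene_hand_computation(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 4.0], [2.0, 4.0, 8.0], [5.0, 1.0, 3.0]],
            index=["a", "b", "c"],
        )
        corr = cs.correlation_heatmap(expr)
        for x, y in itertools.combinations("abc", 2):
            expected = np.corrcoef(expr.loc[x], expr.loc[y])[0, 1]
            assert corr.loc[x, y] == pytest.approx(expected, abs=1e-12)


class TestDatabaseOverlap:
    pairs = [("LIG1", "REC1"), ("LIG2", "REC2"), ("LIG3", "REC3")]

    def test_self_overlap_full(self):
        res = cs.database_overlap(self.pairs, {"db": self.pairs})
        assert res["intersections"]["db"] == 3

    def test_disjoint_sets(self):
        res = cs.database_overlap(self.pairs, {"db": [("X", "Y")]})
        assert res["intersections"]["db"] == 0

    def test_unordered_and_case_normalization(self):
        res = cs.database_overlap(
            self.pairs, {"db": [("rec1", "lig1")]}
        )
        assert res["intersections"]["db"] == 1

    def test_three_set_venn_partition(self):
        a = [("l1", "r1"), ("l2", "r2")]
        b = [("l2", "r2"), ("l3", "r3")]
        res = cs.database_overlap(a, {"B": b, "C": [("l9", "r9")]})
        venn = {tuple(sorted(k)): v for k, v in res["venn"].items()}
        assert venn[("screen",)] == 1          # l1-r1 only ours
        assert venn[("B", "screen")] == 1      # l2-r2 shared
        assert venn[("B",)] == 1               # l3-r3 only B
        assert venn[("C",)] == 1               # l9-r9 only C
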