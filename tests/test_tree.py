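"""Neighbour joining, bootstrap support, clusters and monophyly."""

import numpy as np
import pytest

from barcodekit import (BarcodeLibrary, BarcodeRecord, DistanceMatrix,
                        bootstrap_support, build_nj, distance_matrix,
                        extract_clusters, patristic_distances,
                        species_monophyly, tree_bipartitions)
from barcodekit.simulate import evolve, random_barcode


def _dm(ids, d):
    return DistanceMatrix(ids, np.asarray(d, dtype=float), set())


def _tip_dist(tree, a, b):
    dm = tree.tip_tip_distances()
    return float(dm[a, b])


class TestBuildNJ:
    def test_three_leaves_closed_form(self):
        m = _dm(list("ABC"), [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = build_nj(m)
        # three-point formulas: a=(3+4-5)/2=1, b=(3+5-4)/2=2, c=(4+5-3)/2=3
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_four_leaf_additive_example(self):
        # Additive matrix of tree ((A:1,B:2):1,(C:3,D:4))
        m = _dm(list("ABCD"), [[0, 3, 5, 6],
                               [3, 0, 6, 7],
                               [5, 6, 0, 7],
                               [6, 7, 7, 0]])
        tree = build_nj(m)
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        # internal branch: path A-C minus leaf branches = 5-1-3 = 1
        assert _tip_dist(tree, "A", "C") == pytest.approx(5.0)

    def test_additive_path_lengths_recovered(self, rng):
        """On additive input, NJ path lengths reproduce the matrix."""
        for _ in range(10):
            n = int(rng.integers(4, 7))
            ids, d = _make_additive(rng, n)
            tree = build_nj(_dm(ids, d))
            pat = patristic_distances(tree)
            for i, a in enumerate(ids):
                for j in range(i + 1, n):
                    assert pat.get(a, ids[j]) == pytest.approx(d[i][j],
                                                               abs=1e-9)

    def test_matches_skbio_topology(self, rng):
        """Independent oracle: scikit-bio's NJ finds the same splits."""
        from skbio.tree import nj as skbio_nj
        from skbio import DistanceMatrix as SkbioDM
        for _ in range(5):
            ids, d = _make_additive(rng, 6)
            ours = build_nj(_dm(ids, d))
            theirs = skbio_nj(SkbioDM(np.asarray(d), ids))
            assert tree_bipartitions(ours) == tree_bipartitions(theirs)

    def test_undefined_pair_refused(self):
        m = DistanceMatrix(list("ABC"),
                           np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.]]),
                           {frozenset({"A", "B"})})
        with pytest.raises(ValueError, match="undefined"):
            build_nj(m)

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            build_nj(_dm(list("AB"), [[0, 1], [1, 0]]))

    def test_branch_lengths_non_negative(self, rng):
        for _ in range(5):
            n = 8
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            tree = build_nj(_dm([f"L{i}" for i in range(n)], d))
            for node in tree.traverse(include_self=False):
                assert node.length >= 0


def _make_additive(rng, n_leaves):
    """Random additive matrix via explicit join history."""
    names = [f"L{i}" for i in range(n_leaves)]
    clusters = [[(nm, 0.0)] for nm in names]
    acc = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        la, lb = rng.uniform(0.05, 1.0, size=2)
        a = [(leaf, dd + la) for leaf, dd in clusters[j]]
        b = [(leaf, dd + lb) for leaf, dd in clusters[i]]
        clusters = ([c for k, c in enumerate(clusters) if k not in (i, j)]
                    + [a + b])
        for leaf1, d1 in a:
            for leaf2, d2 in b:
                acc[frozenset({leaf1, leaf2})] = d1 + d2
    d = np.zeros((n_leaves, n_leaves))
    for i, x in enumerate(names):
        for j in range(i + 1, n_leaves):
            d[i, j] = d[j, i] = acc[frozenset({x, names[j]})]
    return names, d


def _two_cluster_library(rng, within=0.004, between=0.10, n_per=3):
    root = random_barcode(rng, 652)
    roots = [root, evolve(root, between, 4.0, rng)]
    recs = []
    for c, cr in enumerate(roots):
        sp = f"Genus01a sp{c + 1:02d}"
        for k in range(n_per):
            seq = evolve(cr, within / 2, 4.0, rng)
            recs.append(BarcodeRecord(f"S{c}{k}", seq, sp, "Genus01a",
                                      "Familia01", "Ordo01"))
    return BarcodeLibrary(recs)


class TestClusters:
    def test_planted_two_clusters(self, rng):
        lib = _two_cluster_library(rng)
        m = distance_matrix(lib)
        clusters = extract_clusters(build_nj(m), m, threshold=0.02,
                                    species_map=lib.species_map())
        assert len(clusters) == 2
        parts = {frozenset(c.member_ids) for c in clusters}
        assert parts == {frozenset({"S00", "S01", "S02"}),
                         frozenset({"S10", "S11", "S12"})}
        assert all(c.consensus_species for c in clusters)

    def test_all_identical_single_cluster(self):
        seq = ("ATTGCAGTC" * 80)[:652]
        recs = [BarcodeRecord(f"S{i}", seq, "Genus01a sp01", "Genus01a",
                              "Familia01", "Ordo01") for i in range(4)]
        lib = BarcodeLibrary(recs)
        m = distance_matrix(lib)
        clusters = extract_clusters(build_nj(m), m)
        assert len(clusters) == 1 and len(clusters[0].member_ids) == 4

    def test_partition_property(self, anomalous_sim):
        library, _ = anomalous_sim
        m = distance_matrix(library)
        clusters = extract_clusters(build_nj(m), m,
                                    species_map=library.species_map())
        members = [m_ for c in clusters for m_ in c.member_ids]
        assert sorted(members) == sorted(library.ids)
        for c in clusters:
            if not c.is_single_entry:
                assert c.max_within < 0.02

    def test_threshold_monotonicity(self, anomalous_sim):
        library, _ = anomalous_sim
        m = distance_matrix(library)
        tree = build_nj(m)
        counts = [len(extract_clusters(tree, m, threshold=t))
                  for t in (0.005, 0.01, 0.02, 0.035, 0.05)]
        assert counts == sorted(counts, reverse=True)


class TestMonophyly:
    def test_clean_species_monophyletic(self, rng):
        lib = _two_cluster_library(rng)
        m = distance_matrix(lib)
        mono = species_monophyly(build_nj(m), lib.species_map())
        assert set(mono.values()) == {"monophyletic"}

    def test_constructed_polyphyly(self):
        # Species X straddles species Y's clade: X = {S0, S4} at opposite
        # ends of a 5-leaf caterpillar.
        rng = np.random.default_rng(3)
        root = random_barcode(rng, 652)
        seqs, cur = [], root
        for _ in range(5):
            cur = evolve(cur, 0.05, 4.0, rng)
            seqs.append(cur)
        species = ["Genus01a sp01", "Genus01a sp02", "Genus01a sp02",
                   "Genus01a sp02", "Genus01a sp01"]
        recs = [BarcodeRecord(f"S{i}", s, sp, "Genus01a", "Familia01", "Ordo01")
                for i, (s, sp) in enumerate(zip(seqs, species))]
        lib = BarcodeLibrary(recs)
        m = distance_matrix(lib)
        mono = species_monophyly(build_nj(m), lib.species_map())
        assert mono["Genus01a sp01"] == "non_monophyletic"

    def test_singleton_not_evaluable(self, rng):
        root = random_barcode(rng, 652)
        recs = [BarcodeRecord("S0", evolve(root, 0.08, 4.0, rng),
                              "Genus01a sp01", "Genus01a", "Familia01",
                              "Ordo01")]
        for k in range(3):
            recs.append(BarcodeRecord(f"T{k}", evolve(root, 0.002, 4.0, rng),
                                      "Genus01a sp02", "Genus01a",
                                      "Familia01", "Ordo01"))
        lib = BarcodeLibrary(recs)
        m = distance_matrix(lib)
        mono = species_monophyly(build_nj(m), lib.species_map())
        assert mono["Genus01a sp01"] == "not_evaluable"
        assert mono["Genus01a sp02"] == "monophyletic"


class TestBootstrap:
    def test_clean_split_full_support(self, rng):
        lib = _two_cluster_library(rng, within=0.0, between=0.10)
        m = distance_matrix(lib)
        tree = build_nj(m)
        support = bootstrap_support(lib, tree, n_reps=50, seed=9)
        assert support  # the 3|3 split exists
        assert all(v == 100.0 for v in support.values())

    def test_single_replicate_support_binary(self, rng):
        lib = _two_cluster_library(rng, within=0.01, between=0.08)
        m = distance_matrix(lib)
        tree = build_nj(m)
        support = bootstrap_support(lib, tree, n_reps=1, seed=2)
        assert set(support.values()) <= {0.0, 100.0}

    def test_fixed_seed_deterministic(self, rng):
        lib = _two_cluster_library(rng, within=0.01, between=0.08)
        m = distance_matrix(lib)
        tree = build_nj(m)
        s1 = bootstrap_support(lib, tree, n_reps=20, seed=7)
        s2 = bootstrap_support(lib, tree, n_reps=20, seed=7)
        assert s1 == s2

    def test_supports_in_range(self, rng):
        lib = _two_cluster_library(rng, within=0.015, between=0.06)
        m = distance_matrix(lib)
        tree = build_nj(m)
        support = bootstrap_support(lib, tree, n_reps=30, seed=4)
        assert all(0.0 <= v <= 100.0 for v in support.values())
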