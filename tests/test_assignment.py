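"""Identity search, cluster-rule assignment, outcome audit, divergence flags."""

import numpy as np
import pytest

from barcodekit import (BarcodeLibrary, BarcodeRecord, Cluster,
                        SimulationConfig, assign_by_cluster, build_nj,
                        classify_outcome, distance_matrix, extract_clusters,
                        flag_deep_divergences, identity_search,
                        sequence_identity, simulate_library)
from barcodekit.assignment import IdentityHit, Provisional
from barcodekit.simulate import evolve, random_barcode


def _rec(sid, seq, species, genus="Genus01a"):
    return BarcodeRecord(sid, seq, species, genus, "Familia01", "Ordo01")


def _mutate(seq, k):
    """Flip the first k positions to a different base (transversion-ish)."""
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    return "".join(swap[c] if i < k else c for i, c in enumerate(seq))


@pytest.fixture(scope="module")
def base_seq():
    return random_barcode(np.random.default_rng(77), 652)


class TestIdentity:
    def test_exact_match_is_100(self, base_seq):
        lib = BarcodeLibrary([_rec("C1", base_seq, "Genus01a sp01")])
        hits = identity_search(base_seq, lib)
        assert hits[0].identity == 100.0 and hits[0].passes

    def test_identity_threshold_edge(self, base_seq):
        """13 mismatches over 652 clears 98%; 14 does not."""
        id13, n13 = sequence_identity(base_seq, _mutate(base_seq, 13))
        id14, n14 = sequence_identity(base_seq, _mutate(base_seq, 14))
        assert n13 == n14 == 652
        assert id13 == 100.0 * 639 / 652 and id13 >= 98.0
        assert id14 == 100.0 * 638 / 652 and id14 < 98.0

    def test_hits_ranked_and_below_threshold_marked(self, base_seq):
        lib = BarcodeLibrary([
            _rec("C1", _mutate(base_seq, 5), "Genus01a sp01"),
            _rec("C2", _mutate(base_seq, 40), "Genus01a sp02"),
        ])
        hits = identity_search(base_seq, lib)
        assert [h.candidate_species for h in hits] == ["Genus01a sp01",
                                                       "Genus01a sp02"]
        assert hits[0].passes and not hits[1].passes

    def test_species_absent_best_hit_below_threshold(self, base_seq, rng):
        relative = evolve(base_seq, 0.06, 4.0, rng)   # ~6% divergent congener
        lib = BarcodeLibrary([_rec("C1", relative, "Genus01a sp02")])
        hits = identity_search(base_seq, lib)
        assert hits[0].identity < 98.0 and not hits[0].passes
        assert hits[0].identity > 90.0

    def test_empty_candidates_error(self, base_seq):
        with pytest.raises(ValueError):
            identity_search(base_seq, BarcodeLibrary([]))

    def test_lower_floor_never_loses_hits(self, base_seq, rng):
        lib = BarcodeLibrary([
            _rec(f"C{i}", evolve(base_seq, t, 4.0, rng), f"Genus01a sp{i:02d}")
            for i, t in enumerate((0.005, 0.015, 0.03, 0.08))
        ])
        n_passing = [sum(h.passes for h in
                         identity_search(base_seq, lib, min_identity=f))
                     for f in (99.5, 99.0, 98.0, 95.0, 90.0)]
        assert n_passing == sorted(n_passing)


class TestClusterRule:
    def _clusters(self):
        return [
            Cluster("C0001", ["R1", "R2", "Q1"], 0.004,
                    {"Genus01a sp01": 2, "": 1}),
            Cluster("C0002", ["Q2"], 0.0, {"": 1}),
            Cluster("C0003", ["R3", "R4", "Q3"], 0.01,
                    {"Genus01a sp02": 1, "Genus01a sp03": 1, "": 1}),
        ]

    def test_pure_cluster_assigns(self):
        prov = assign_by_cluster(["Q1"], self._clusters())["Q1"]
        assert prov.status == "assigned" and prov.species == "Genus01a sp01"

    def test_reference_free_cluster_unassigned(self):
        prov = assign_by_cluster(["Q2"], self._clusters())["Q2"]
        assert prov.status == "unassigned"

    def test_mixed_cluster_ambiguous(self):
        prov = assign_by_cluster(["Q3"], self._clusters())["Q3"]
        assert prov.status == "ambiguous"

    def test_query_off_partition_errors(self):
        with pytest.raises(ValueError, match="not on the tree"):
            assign_by_cluster(["QX"], self._clusters())


class TestClassifyOutcome:
    def test_confirmed_and_mismatch(self):
        prov = Provisional("Q1", "assigned", "Genus01a sp01", "C0001")
        assert classify_outcome(prov, None, "Genus01a sp01").outcome == "confirmed"
        r = classify_outcome(prov, None, "Genus01a sp02")
        assert r.outcome == "mismatch" and r.assigned_species == "Genus01a sp01"

    def test_identity_fallback_confirms(self):
        prov = Provisional("Q1", "unassigned", None, "C0002")
        hits = [IdentityHit("Genus01a sp05", "C9", 99.8, 1.0, True)]
        r = classify_outcome(prov, hits, "Genus01a sp05")
        assert r.outcome == "confirmed" and r.identity == 99.8

    def test_top_identity_tie_is_ambiguous(self):
        prov = Provisional("Q1", "unassigned", None, "C0002")
        hits = [IdentityHit("Genus01a sp05", "C1", 100.0, 1.0, True),
                IdentityHit("Genus01a sp06", "C2", 100.0, 1.0, True),
                IdentityHit("Genus01a sp07", "C3", 99.0, 1.0, True)]
        r = classify_outcome(prov, hits, "Genus01a sp05")
        assert r.outcome == "ambiguous" and "identity_tie" in r.evidence

    def test_highest_identity_wins_within_range(self):
        prov = Provisional("Q1", "unassigned", None, "C0002")
        hits = [IdentityHit("Genus01a sp05", "C1", 99.7, 1.0, True),
                IdentityHit("Genus01a sp06", "C2", 98.4, 1.0, True)]
        r = classify_outcome(prov, hits, "Genus01a sp06")
        assert r.outcome == "mismatch" and r.assigned_species == "Genus01a sp05"

    def test_nothing_above_floor_is_no_match(self):
        prov = Provisional("Q1", "unassigned", None, "C0002")
        hits = [IdentityHit("Genus01a sp09", "C1", 94.0, 1.0, False)]
        r = classify_outcome(prov, hits, "Genus01a sp01")
        assert r.outcome == "no_match"
        assert "best_below_threshold" in r.evidence

    def test_no_candidates_is_new_record(self):
        prov = Provisional("Q1", "unassigned", None, "C0002")
        r = classify_outcome(prov, None, "Genus01a sp01")
        assert r.outcome == "new_record"


class TestBlindness:
    def test_assignment_invariant_to_query_labels(self):
        cfg = SimulationConfig(seed=41, query_fraction=0.3)
        library, _ = simulate_library(cfg)
        from barcodekit import run_analysis
        ref, qry = library.references(), library.queries()
        b1 = run_analysis(ref, qry)
        # permute morphology labels of the queries
        from dataclasses import replace
        shuffled = list(qry)
        labels = [(r.species, r.genus) for r in shuffled]
        labels = labels[1:] + labels[:1]
        qry2 = BarcodeLibrary([
            replace(r, species=sp, genus=ge)
            for r, (sp, ge) in zip(shuffled, labels)])
        b2 = run_analysis(ref, qry2)
        a1 = {r.query_id: r.assigned_species for r in b1.assignments}
        a2 = {r.query_id: r.assigned_species for r in b2.assignments}
        assert a1 == a2


class TestFlagging:
    def _library_with_split(self, depth, region_sorted=True):
        cfg = SimulationConfig(seed=51, n_families=2, genera_per_family=2,
                               species_per_genus=3, specimens_per_species=4,
                               cryptic_fraction=0.2, cryptic_depth=depth,
                               region_sorting=region_sorted,
                               query_fraction=0.0)
        return simulate_library(cfg)

    def test_planted_split_flagged_with_geography(self):
        library, truth = self._library_with_split(0.06)
        m = distance_matrix(library)
        clusters = extract_clusters(build_nj(m), m,
                                    species_map=library.species_map())
        flags = flag_deep_divergences(library, m, clusters)
        assert {f.species for f in flags} == truth.cryptic_species()
        for f in flags:
            assert f.n_subclusters == 2
            assert f.geographic_sorting
            assert f.max_intra > 2.0
            assert f.between_group_mean == pytest.approx(6.0, abs=2.0)

    def test_shallow_species_not_flagged(self, clean_sim):
        library, _ = clean_sim
        m = distance_matrix(library)
        clusters = extract_clusters(build_nj(m), m,
                                    species_map=library.species_map())
        assert flag_deep_divergences(library, m, clusters) == []

    def test_unsorted_split_reports_no_geography(self):
        library, truth = self._library_with_split(0.06, region_sorted=False)
        m = distance_matrix(library)
        clusters = extract_clusters(build_nj(m), m,
                                    species_map=library.species_map())
        flags = flag_deep_divergences(library, m, clusters)
        assert {f.species for f in flags} == truth.cryptic_species()
        # with random regions, perfect sorting of 2x2 specimens is unlikely
        # for every planted species simultaneously
        assert not all(f.geographic_sorting for f in flags)
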