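import networkx as nx
import numpy as np
import pytest
from sklearn.base import clone

from censat.families import (
    CanonicalMotif,
    RepeatFamilyClusterer,
    build_catalog,
    build_family_network,
    cluster_families,
    filter_centromeric_arrays,
    select_representative,
)
from censat.io import TandemRepeatArray
from censat.windows import GenomeWindow


def window(scaffold, start, end, chip, inp, ratio, flagged):
    return GenomeWindow(scaffold, start, end, chip, inp, ratio, flagged)


def array(scaffold="s", start=1000, end=2000, motif="AACCT"):
    return TandemRepeatArray(scaffold, start, end, len(motif), 2.0, motif)


class TestFilterCentromericArrays:
    def test_locally_enriched_array_in_flagged_window_kept(self):
        wins = [window("s", 0, 10_000, 80.0, 10.0, 3.0, True)]
        assert filter_centromeric_arrays([array()], wins) == [array()]

    def test_low_local_ratio_dropped_despite_flagged_window(self):
        wins = [window("s", 0, 10_000, 20.0, 10.0, 1.0, True)]
        assert filter_centromeric_arrays([array()], wins) == []

    def test_array_outside_flagged_windows_dropped(self):
        wins = [window("s", 0, 10_000, 80.0, 10.0, 3.0, False)]
        assert filter_centromeric_arrays([array()], wins) == []

    def test_noise_free_simulation_keeps_exactly_planted_arrays(self, noise_free_sim):
        sim = noise_free_sim
        assert sorted(
            (a.scaffold, a.start, a.end) for a in sim.kept_arrays
        ) == sorted(
            (a.scaffold, a.start, a.end) for a in sim.truth.planted_arrays
        )


class TestCatalog:
    def test_identical_canonical_forms_merged(self):
        arrays = [
            array(motif="AACCT", start=0, end=1000),
            array(motif="CCTAA", start=2000, end=2500),  # rotation
            array(motif="AGGTT", start=3000, end=3200),  # revcomp
        ]
        catalog = build_catalog(arrays)
        assert len(catalog) == 1
        assert catalog[0].canonical == "AACCT"
        assert catalog[0].n_arrays == 3
        assert catalog[0].total_bp == 1000 + 500 + 200


class TestNetwork:
    def motifs(self, seqs_bp):
        return [
            CanonicalMotif(canonical=s, members=[s], total_bp=bp, n_arrays=1)
            for s, bp in seqs_bp
        ]

    def test_similar_motifs_form_triangle(self):
        catalog = self.motifs(
            [("AACCTAACCT", 100), ("AACGTAACGT", 100), ("AACCTAACGT", 100)]
        )
        graph = build_family_network(catalog)
        assert graph.number_of_edges() == 3

    def test_exact_80_percent_similarity_is_an_edge(self):
        catalog = self.motifs([("AACCTAACCT", 100), ("AACGTAACGT", 100)])
        graph = build_family_network(catalog, threshold=80.0)
        assert graph.number_of_edges() == 1

    def test_dissimilar_motifs_unlinked(self):
        catalog = self.motifs([("AAAAC", 100), ("CGCGT", 100)])
        graph = build_family_network(catalog)
        assert graph.number_of_edges() == 0

    def test_catalog_cap_enforced(self):
        catalog = self.motifs([("AACCT", 1), ("AACGT", 1), ("AAGGT", 1)])
        with pytest.raises(ValueError, match="subsample"):
            build_family_network(catalog, max_motifs=2)


class TestClustering:
    def test_no_edges_gives_singletons(self):
        graph = nx.Graph()
        for i, s in enumerate(["AAAAC", "CCCCG", "GGGTT", "AACCG"]):
            graph.add_node(
                s, motif=CanonicalMotif(canonical=s, members=[s], total_bp=i, n_arrays=1)
            )
        families = cluster_families(graph)
        assert len(families) == 4
        assert all(len(f.members) == 1 for f in families)

    def test_families_numbered_by_descending_bp(self):
        graph = nx.Graph()
        for s, bp in [("AAAAC", 10), ("CCCCG", 1000)]:
            graph.add_node(
                s, motif=CanonicalMotif(canonical=s, members=[s], total_bp=bp, n_arrays=1)
            )
        families = cluster_families(graph)
        assert families[0].total_bp == 1000
        assert families[0].family_id == 1

    def test_partition_property(self, noise_free_sim):
        families = noise_free_sim.clusterer.families_
        seen = [m.canonical for f in families for m in f.members]
        assert len(seen) == len(set(seen))
        assert sorted(seen) == sorted(
            m.canonical for m in noise_free_sim.clusterer.catalog_
        )


class TestRepresentative:
    def motif(self, s, bp, n):
        return CanonicalMotif(canonical=s, members=[s], total_bp=bp, n_arrays=n)

    def test_singleton(self):
        m = self.motif("AACCT", 10, 1)
        assert select_representative([m]) is m

    def test_most_abundant_wins(self):
        a, b = self.motif("AACCT", 1000, 1), self.motif("AACGT", 500, 9)
        assert select_representative([a, b]) is a

    def test_degree_breaks_bp_and_count_tie(self):
        a, b = self.motif("AACCT", 100, 1), self.motif("AACGT", 100, 1)
        graph = nx.Graph()
        graph.add_edge("AACGT", "AAGGT")
        assert select_representative([a, b], graph) is b

    def test_lexicographic_final_tiebreak(self):
        a, b = self.motif("CCGGT", 100, 1), self.motif("AACGT", 100, 1)
        assert select_representative([a, b]).canonical == "AACGT"


class TestClustererEstimator:
    def test_recovers_planted_families(self, noise_free_sim):
        sim = noise_free_sim
        assert sim.clusterer.n_families_ == sim.config.n_families
        recovered = {}
        for label, arr in zip(sim.clusterer.labels_, sim.kept_arrays):
            recovered.setdefault(label, set()).add((arr.scaffold, arr.start))
        truth = {}
        for arr, fid in zip(sim.truth.planted_arrays, sim.truth.array_families):
            truth.setdefault(fid, set()).add((arr.scaffold, arr.start))
        assert sorted(map(frozenset, recovered.values())) == sorted(
            map(frozenset, truth.values())
        )

    def test_labels_parallel_to_input(self, noise_free_sim):
        sim = noise_free_sim
        assert len(sim.clusterer.labels_) == len(sim.kept_arrays)
        assert set(sim.clusterer.labels_) == {
            f.family_id for f in sim.clusterer.families_
        }

    def test_accepts_raw_motif_strings(self):
        clusterer = RepeatFamilyClusterer().fit(["AACCT", "CCTAA", "CGCGA"])
        assert clusterer.n_families_ == 2
        assert list(clusterer.labels_[:2]) == [clusterer.labels_[0]] * 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            RepeatFamilyClusterer().fit([])

    def test_sklearn_clone_round_trip(self):
        clusterer = RepeatFamilyClusterer(similarity_threshold=85.0, max_motifs=10)
        assert clone(clusterer).get_params() == clusterer.get_params()

    def test_fit_predict_matches_labels(self):
        motifs = ["AACCT", "CCTAA", "CGCGA"]
        clusterer = RepeatFamilyClusterer()
        labels = clusterer.fit_predict(motifs)
        assert np.array_equal(labels, clusterer.labels_)
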