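import numpy as np
import pytest

from censat.io import SequenceRecord
from censat.kmers import (
    KmerEnrichmentScorer,
    annotate_tandem_arrays,
    build_unitigs,
    canonical_kmer,
    count_kmers,
    detect_tandem_motif,
    enrichment_table,
    extract_enriched_reads,
    mad_cutoff,
)
from censat.motifs import reverse_complement


def reads_from(*seqs):
    return [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]


class TestCountKmers:
    def test_strand_min_windows_counted_individually(self):
        counts = count_kmers(reads_from("AACCTAA"), k=5)
        # strand canonicalization only, no rotation
        assert counts == {"AACCT": 1, "ACCTA": 1, "CCTAA": 1}

    def test_windows_with_n_skipped(self):
        assert count_kmers(reads_from("NNNNNN"), k=5) == {}

    def test_reverse_complementing_reads_preserves_counts(self):
        seqs = ["ACGTACGTTAGC", "GGGTTTACCCAT"]
        fwd = count_kmers(reads_from(*seqs), k=5)
        rev = count_kmers(reads_from(*[reverse_complement(s) for s in seqs]), k=5)
        assert fwd == rev

    def test_k_longer_than_all_reads_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            count_kmers(reads_from("ACGT"), k=10)


class TestEnrichmentTable:
    def test_equal_counts_give_unit_enrichment(self):
        table = enrichment_table(
            {"AAAAA": 10}, {"AAAAA": 10}, min_count=1,
            chip_total_bp=100, input_total_bp=100,
        )
        assert table[0].enrichment == pytest.approx(1.0)

    def test_min_count_applies_to_both_sets(self):
        table = enrichment_table(
            {"AAAAA": 99, "CCCCC": 200},
            {"AAAAA": 500, "CCCCC": 99},
            min_count=100, chip_total_bp=100, input_total_bp=100,
        )
        assert table == []

    def test_joint_rescaling_invariance(self):
        a = enrichment_table(
            {"AAAAA": 100}, {"AAAAA": 150}, min_count=1,
            chip_total_bp=1000, input_total_bp=2000,
        )
        b = enrichment_table(
            {"AAAAA": 200}, {"AAAAA": 300}, min_count=1,
            chip_total_bp=2000, input_total_bp=4000,
        )
        assert a[0].enrichment == pytest.approx(b[0].enrichment)


class TestMadCutoff:
    def test_worked_example(self):
        cut = mad_cutoff([1, 2, 3, 4, 100])
        assert cut.median == 3
        assert cut.mad == 1
        assert cut.cutoff == 28
        assert [v for v in [1, 2, 3, 4, 100] if cut.exceeds(v)] == [100]

    def test_constant_list_yields_empty_enriched_set(self):
        values = [2.0] * 100
        cut = mad_cutoff(values)
        assert cut.mad == 0
        assert not any(cut.exceeds(v) for v in values)  # strict '>' semantics

    def test_translation_equivariance(self):
        base = [1.0, 2.0, 5.0, 9.0, 40.0]
        shifted = [v + 7.5 for v in base]
        assert mad_cutoff(shifted).cutoff == pytest.approx(
            mad_cutoff(base).cutoff + 7.5
        )


class TestExtractReads:
    def test_empty_enriched_set_gives_empty_subset(self):
        assert extract_enriched_reads(reads_from("ACGTACGTAC"), set(), k=5) == []

    def test_subset_preserves_order_and_membership(self):
        reads = reads_from("AAAAAGGGGG", "CCCCCGGGGG", "AAAAACCCCC")
        hit = canonical_kmer("AAAAA")
        subset = extract_enriched_reads(reads, {hit}, k=5)
        assert [r.id for r in subset] == ["r0", "r2"]
        assert set(subset) <= set(reads)


@pytest.fixture(scope="module")
def source():
    rng = np.random.default_rng(42)
    return "".join(rng.choice(list("ACGT"), 300))


class TestUnitigs:
    def _tile(self, seq, read_len=40, step=10):
        return reads_from(
            *[seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, step)]
        )

    def test_tiling_reads_reconstruct_the_source(self, source):
        unitigs = build_unitigs(self._tile(source), k=21)
        assert len(unitigs) == 1
        rc = reverse_complement(source)
        assert unitigs[0].seq == min(source, rc)

    def test_disjoint_sources_give_two_unitigs(self, source):
        rng = np.random.default_rng(43)
        other = "".join(rng.choice(list("ACGT"), 300))
        reads = self._tile(source) + self._tile(other)
        unitigs = build_unitigs(reads, k=21)
        assert len(unitigs) == 2

    def test_read_order_permutation_invariance(self, source):
        reads = self._tile(source, read_len=35, step=7)
        a = build_unitigs(reads, k=21)
        b = build_unitigs(list(reversed(reads)), k=21)
        assert [u.seq for u in a] == [u.seq for u in b]


class TestTandemDetection:
    def test_pentamer_array_detected(self):
        hit = detect_tandem_motif("AACCT" * 6)
        assert hit is not None
        motif, period = hit
        assert period == 5
        assert motif == "AACCT"

    def test_random_sequence_rejected(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 120))
        assert detect_tandem_motif(seq) is None

    def test_annotation_records_span_and_copy_number(self):
        contigs = [SequenceRecord("u1", "ACGGT" * 8)]
        arrays = annotate_tandem_arrays(contigs)
        assert len(arrays) == 1
        assert arrays[0].period == 5
        assert arrays[0].copy_number == pytest.approx(8.0)


class TestScorer:
    def test_strand_symmetry_of_enrichment_table(self):
        chip = reads_from("AACCTAACCTAACCT", "GGGGGGGGGGGGGGG")
        ctrl = reads_from("AACCTAACCTAACCT", "GGGGGGGGGGGGGGG")
        fwd = KmerEnrichmentScorer(k=5, min_count=1).fit(chip, ctrl)
        flipped = [
            SequenceRecord(r.id, reverse_complement(r.seq)) for r in chip
        ]
        rev = KmerEnrichmentScorer(k=5, min_count=1).fit(flipped, ctrl)
        assert {(e.kmer, e.enrichment) for e in fwd.table_} == {
            (e.kmer, e.enrichment) for e in rev.table_
        }

    def test_empty_table_handled(self):
        scorer = KmerEnrichmentScorer(k=5, min_count=100).fit(
            reads_from("ACGTACGTA"), reads_from("ACGTACGTA")
        )
        assert scorer.table_ == []
        assert scorer.enriched_kmers_ == set()
        assert scorer.extract(reads_from("ACGTACGTA")) == []
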