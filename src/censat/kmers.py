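"""Assembly-free centromere detection from ChIP and input read sets.

Canonical (strand-min) 25-mers are counted in both read sets; k-mers passing
a minimum count in BOTH sets get a per-total-bp normalized enrichment ratio
(ChIP over input). Outliers strictly exceeding ``median + 25 * MAD`` of the
enrichment distribution (raw MAD, no consistency constant) are called
enriched; reads containing enriched k-mers are extracted and assembled into
unitigs — maximal non-branching paths of the bidirected de Bruijn graph — as
a minimal stand-in for an external assembler, and tandem repeats found in
the unitigs feed the same family-clustering machinery as the assembly route.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .families import RepeatFamily, RepeatFamilyClusterer
from .io import SequenceRecord, TandemRepeatArray
from .motifs import reverse_complement


def canonical_kmer(kmer: str) -> str:
    """Strand-min canonical form: min(kmer, revcomp(kmer)). No rotation."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def count_kmers(reads: Iterable[SequenceRecord], k: int = 25) -> dict[str, int]:
    """Count every length-k window of every read under strand canonicalization.

    Windows containing N are skipped; reads shorter than k contribute
    nothing. An error is raised only when no read is long enough.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    usable = False
    empty = True
    for read in reads:
        empty = False
        s = read.seq
        n = len(s)
        if n < k:
            continue
        usable = True
        rc = reverse_complement(s) if "N" not in s else None
        for i in range(n - k + 1):
            kf = s[i : i + k]
            if rc is None:
                if "N" in kf:
                    continue
                kr = reverse_complement(kf)
            else:
                kr = rc[n - k - i : n - i]
            key = kf if kf <= kr else kr
            counts[key] = counts.get(key, 0) + 1
    if not empty and not usable:
        raise ValueError(f"k={k} exceeds the length of every read")
    return counts


@dataclass(frozen=True)
class KmerEnrichment:
    """One canonical k-mer with counts, normalized abundances and ratio."""

    kmer: str
    chip_count: int
    input_count: int
    chip_norm: float
    input_norm: float
    enrichment: float


def enrichment_table(
    chip_counts: Mapping[str, int],
    input_counts: Mapping[str, int],
    min_count: int = 100,
    chip_total_bp: float = 0.0,
    input_total_bp: float = 0.0,
) -> list[KmerEnrichment]:
    """Enrichment ratios for k-mers found >= min_count times in BOTH sets.

    Abundances are normalized per total base pairs of the respective read
    set; the enrichment is the ratio of normalized ChIP to input abundance.
    """
    if chip_total_bp <= 0 or input_total_bp <= 0:
        raise ValueError("read-set total bp must be positive")
    table: list[KmerEnrichment] = []
    for kmer in chip_counts.keys() & input_counts.keys():
        c, i = chip_counts[kmer], input_counts[kmer]
        if c < min_count or i < min_count:
            continue
        cn, inn = c / chip_total_bp, i / input_total_bp
        table.append(KmerEnrichment(kmer, c, i, cn, inn, cn / inn))
    table.sort(key=lambda e: (-e.enrichment, e.kmer))
    return table


@dataclass(frozen=True)
class MadCutoff:
    """Robust outlier cutoff: median + n_mads * raw MAD of the enrichments."""

    median: float
    mad: float
    n_mads: float
    cutoff: float

    def exceeds(self, value: float) -> bool:
        """Strictly greater than the cutoff ('exceeding', not reaching)."""
        return value > self.cutoff


def mad_cutoff(enrichments: Sequence[float], n_mads: float = 25.0) -> MadCutoff:
    """Median + n_mads * MAD of the enrichment values (raw MAD, one-sided)."""
    if len(enrichments) == 0:
        raise ValueError("enrichment list must be non-empty")
    values = np.asarray(enrichments, dtype=float)
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return MadCutoff(median=med, mad=mad, n_mads=n_mads, cutoff=med + n_mads * mad)


def enriched_kmers(
    table: Sequence[KmerEnrichment], cutoff: MadCutoff
) -> list[KmerEnrichment]:
    return [e for e in table if cutoff.exceeds(e.enrichment)]


def extract_enriched_reads(
    reads: Sequence[SequenceRecord], enriched: set[str], k: int = 25
) -> list[SequenceRecord]:
    """Order-preserving subset of reads containing >= 1 enriched canonical k-mer."""
    if not enriched:
        return []
    out: list[SequenceRecord] = []
    for read in reads:
        s = read.seq
        n = len(s)
        if n < k:
            continue
        rc = reverse_complement(s) if "N" not in s else None
        for i in range(n - k + 1):
            kf = s[i : i + k]
            if rc is None:
                if "N" in kf:
                    continue
                kr = reverse_complement(kf)
            else:
                kr = rc[n - k - i : n - i]
            if (kf if kf <= kr else kr) in enriched:
                out.append(read)
                break
    return out


def build_unitigs(reads: Sequence[SequenceRecord], k: int = 25) -> list[SequenceRecord]:
    """Maximal non-branching paths of the bidirected de Bruijn graph.

    Nodes are (k-1)-mers, edges are the canonical k-mers observed in the
    reads; a path is extended while the junction has a unique successor whose
    entry node has a unique predecessor. Output is strand-canonicalized and
    deterministically ordered by descending length then sequence, so it is
    invariant under read-order permutation.
    """
    kmer_set = set(count_kmers(reads, k)) if reads else set()
    used: set[str] = set()
    contigs: list[str] = []
    alphabet = "ACGT"
    for seed in sorted(kmer_set):
        if seed in used:
            continue
        used.add(seed)
        contig = seed
        # extend right
        while True:
            v = contig[-(k - 1):]
            exts = [b for b in alphabet if canonical_kmer(v + b) in kmer_set]
            if len(exts) != 1:
                break
            w = v + exts[0]
            cw = canonical_kmer(w)
            if cw in used:
                break
            preds = [b for b in alphabet if canonical_kmer(b + w[1:]) in kmer_set]
            if len(preds) != 1:
                break
            contig += exts[0]
            used.add(cw)
        # extend left
        while True:
            v = contig[: k - 1]
            preds = [b for b in alphabet if canonical_kmer(b + v) in kmer_set]
            if len(preds) != 1:
                break
            w = preds[0] + v
            cw = canonical_kmer(w)
            if cw in used:
                break
            exts = [b for b in alphabet if canonical_kmer(w[: k - 1] + b) in kmer_set]
            if len(exts) != 1:
                break
            contig = preds[0] + contig
            used.add(cw)
        rc = reverse_complement(contig)
        contigs.append(contig if contig <= rc else rc)
    contigs.sort(key=lambda s: (-len(s), s))
    return [
        SequenceRecord(f"unitig_{i}", seq) for i, seq in enumerate(contigs, start=1)
    ]


def detect_tandem_motif(
    seq: str,
    min_period: int = 3,
    min_copies: float = 3.0,
    min_match: float = 0.85,
    min_length: int = 25,
) -> tuple[str, int] | None:
    """Minimal tandem-structure detector for unitigs/contigs.

    Scans periods from ``min_period`` upward and accepts the smallest period
    whose self-match fraction (seq[i] == seq[i+p]) reaches ``min_match`` with
    at least ``min_copies`` copies; returns (consensus motif, period) built
    from per-phase majority vote, or None. This is deliberately conservative
    plumbing — production contigs are annotated with an external tandem
    repeat finder and ingested via the .dat reader.
    """
    n = len(seq)
    if n < min_length:
        return None
    max_period = int(n / min_copies)
    for p in range(min_period, max_period + 1):
        matches = sum(1 for i in range(n - p) if seq[i] == seq[i + p])
        if matches / (n - p) < min_match:
            continue
        consensus = []
        for j in range(p):
            col = Counter(seq[j::p])
            # deterministic tie-break: highest count, then alphabetical
            top = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            consensus.append(top)
        motif = "".join(consensus)
        if set(motif) <= set("ACGT"):
            return motif, p
    return None


def annotate_tandem_arrays(
    contigs: Sequence[SequenceRecord], **detector_kwargs
) -> list[TandemRepeatArray]:
    """Run the minimal tandem detector over contigs, one array per hit."""
    arrays: list[TandemRepeatArray] = []
    for contig in contigs:
        hit = detect_tandem_motif(contig.seq, **detector_kwargs)
        if hit is None:
            continue
        motif, period = hit
        arrays.append(
            TandemRepeatArray(
                scaffold=contig.id,
                start=0,
                end=len(contig.seq),
                period=period,
                copy_number=round(len(contig.seq) / period, 1),
                motif=motif,
            )
        )
    return arrays


def kmer_route_families(
    contig_arrays: Sequence[TandemRepeatArray],
    similarity_threshold: float = 80.0,
    max_motifs: int = 2000,
) -> list[RepeatFamily]:
    """Cluster tandem repeats found on de novo contigs into families.

    Delegates to the same canonicalization/similarity/clustering code path as
    the assembly-based route.
    """
    if not contig_arrays:
        return []
    clusterer = RepeatFamilyClusterer(
        similarity_threshold=similarity_threshold, max_motifs=max_motifs
    )
    clusterer.fit(list(contig_arrays))
    return clusterer.families_


class KmerEnrichmentScorer(BaseEstimator):
    """Estimator wrapper for the k-mer route.

    fit(chip_reads, input_reads) counts canonical k-mers in both read sets,
    builds the enrichment table (``table_``), the MAD cutoff (``cutoff_``)
    and the enriched k-mer set (``enriched_kmers_``). ``extract`` then
    subsets reads containing enriched k-mers.
    """

    def __init__(self, k: int = 25, min_count: int = 100, n_mads: float = 25.0):
        self.k = k
        self.min_count = min_count
        self.n_mads = n_mads

    def fit(
        self,
        chip_reads: Sequence[SequenceRecord],
        input_reads: Sequence[SequenceRecord],
    ) -> "KmerEnrichmentScorer":
        chip_counts = count_kmers(chip_reads, self.k)
        input_counts = count_kmers(input_reads, self.k)
        self.chip_total_bp_ = float(sum(len(r.seq) for r in chip_reads))
        self.input_total_bp_ = float(sum(len(r.seq) for r in input_reads))
        self.table_ = enrichment_table(
            chip_counts,
            input_counts,
            min_count=self.min_count,
            chip_total_bp=self.chip_total_bp_,
            input_total_bp=self.input_total_bp_,
        )
        if self.table_:
            self.cutoff_ = mad_cutoff(
                [e.enrichment for e in self.table_], self.n_mads
            )
            self.enriched_kmers_ = {
                e.kmer for e in enriched_kmers(self.table_, self.cutoff_)
            }
        else:
            self.cutoff_ = None
            self.enriched_kmers_ = set()
        return self

    def extract(self, reads: Sequence[SequenceRecord]) -> list[SequenceRecord]:
        return extract_enriched_reads(reads, self.enriched_kmers_, self.k)


@dataclass
class KmerRouteResult:
    """Intermediates and families from the full assembly-free route."""

    scorer: KmerEnrichmentScorer
    enriched_reads: list[SequenceRecord]
    unitigs: list[SequenceRecord]
    contig_arrays: list[TandemRepeatArray]
    families: list[RepeatFamily]


def kmer_route(
    chip_reads: Sequence[SequenceRecord],
    input_reads: Sequence[SequenceRecord],
    k: int = 25,
    min_count: int = 100,
    n_mads: float = 25.0,
    similarity_threshold: float = 80.0,
    max_motifs: int = 2000,
) -> KmerRouteResult:
    """Full assembly-free route from read sets to repeat families."""
    scorer = KmerEnrichmentScorer(k=k, min_count=min_count, n_mads=n_mads).fit(
        chip_reads, input_reads
    )
    reads = scorer.extract(chip_reads)
    unitigs = build_unitigs(reads, k) if reads else []
    contig_arrays = annotate_tandem_arrays(unitigs)
    families = kmer_route_families(
        contig_arrays, similarity_threshold=similarity_threshold, max_motifs=max_motifs
    )
    return KmerRouteResult(scorer, reads, unitigs, contig_arrays, families)
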