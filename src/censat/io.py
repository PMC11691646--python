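"""Strict readers and writers for the external file formats the pipeline touches.

All in-memory coordinates are 0-based half-open. Formats that are 1-based
inclusive on disk (TRF ``.dat``, BLAST tabular) are converted at this boundary
and nowhere else. Readers reject invariant violations instead of silently
repairing them; the single documented exception is the TRF period/motif
reconciliation (a warning, keeping the motif).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

SEQUENCE_ALPHABET = frozenset("ACGTN")
MOTIF_ALPHABET = frozenset("ACGT")


class FormatError(ValueError):
    """A file violated the dialect this package reads or writes."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the uppercase alphabet {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated interval with a category label (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    category: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TandemRepeatArray:
    """One tandem-repeat array in the TRF sense (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    period: int
    copy_number: float
    motif: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid array interval [{self.start}, {self.end}) on {self.scaffold}"
            )
        if not self.motif:
            raise ValueError("array motif must be non-empty")
        bad = set(self.motif) - MOTIF_ALPHABET
        if bad:
            raise ValueError(f"motif contains invalid characters {sorted(bad)}")
        if self.period != len(self.motif):
            raise ValueError(
                f"period {self.period} != motif length {len(self.motif)}"
            )
        if self.copy_number <= 0:
            raise ValueError("copy_number must be positive")
        if self.array_length < self.period:
            raise ValueError("array shorter than one motif period")

    @property
    def array_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentHit:
    """One BLASTN tabular hit with the query length attached.

    Coordinates are converted to 0-based half-open with start < end on
    ingestion (subject hits on the minus strand are flipped).
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    query_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.query_length < 1:
            raise ValueError("query_length must be >= 1")

    @property
    def query_coverage(self) -> float:
        """Alignment coverage of the query, in percent."""
        return 100.0 * self.aln_length / self.query_length


@dataclass
class CoverageTrack:
    """Sorted, non-overlapping per-scaffold depth intervals plus a library size.

    ``library_size`` is the normalization constant (mapped-read count or an
    equivalent); it defaults to the sum of depth x length so small test
    tracks are self-contained.
    """

    intervals: list[tuple[str, int, int, float]]
    library_size: float

    @classmethod
    def build(
        cls,
        intervals: Iterable[tuple[str, int, int, float]],
        library_size: float | None = None,
    ) -> "CoverageTrack":
        rows = sorted(intervals, key=lambda r: (r[0], r[1]))
        prev_scaffold, prev_end = None, -1
        for scaffold, start, end, depth in rows:
            if start < 0 or start >= end:
                raise FormatError(
                    f"invalid interval [{start}, {end}) on {scaffold}"
                )
            if depth < 0:
                raise FormatError(f"negative depth {depth} on {scaffold}")
            if scaffold == prev_scaffold and start < prev_end:
                raise FormatError(
                    f"overlapping intervals on {scaffold} near position {start}"
                )
            prev_scaffold, prev_end = scaffold, end
        if library_size is None:
            library_size = float(
                sum(d * (e - s) for _, s, e, d in rows)
            )
        if library_size <= 0:
            raise ValueError(
                "library_size must be positive (supply it explicitly for "
                "empty or zero-depth tracks)"
            )
        return cls(intervals=rows, library_size=float(library_size))

    def by_scaffold(self) -> dict[str, list[tuple[int, int, float]]]:
        out: dict[str, list[tuple[int, int, float]]] = {}
        for scaffold, start, end, depth in self.intervals:
            out.setdefault(scaffold, []).append((start, end, depth))
        return out

    def total_mass(self) -> float:
        """Sum of depth x length over all intervals."""
        return sum(d * (e - s) for _, s, e, d in self.intervals)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; duplicate ids, empty sequences, and invalid
    characters are format errors naming the offending line.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    parts: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal header
        if header is None:
            return
        seq = "".join(parts)
        if not seq:
            raise FormatError(
                f"{path}: line {header_line}: record {header!r} has an empty sequence"
            )
        try:
            records.append(SequenceRecord(header, seq))
        except ValueError as exc:
            raise FormatError(f"{path}: line {header_line}: {exc}") from exc
        header = None
        parts.clear()

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FormatError(f"{path}: line {lineno}: empty FASTA header")
                if name in seen:
                    raise FormatError(
                        f"{path}: line {lineno}: duplicate record id {name!r}"
                    )
                seen.add(name)
                header = name
                header_line = lineno
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: line {lineno}: sequence before first header"
                    )
                chunk = line.upper()
                bad = set(chunk) - SEQUENCE_ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}: line {lineno}: invalid characters {sorted(bad)}"
                    )
                parts.append(chunk)
        flush(lineno + 1)
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ reads (quality scores are discarded)."""
    from Bio import SeqIO

    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate read id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    return records


def read_reads(path: str | Path) -> list[SequenceRecord]:
    """Read a read set from FASTA or FASTQ, dispatching on file extension."""
    suffix = Path(path).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return read_fastq(path)
    return read_fasta(path)


# ---------------------------------------------------------------------------
# bedGraph / BED
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, library_size: float | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into a sorted track."""
    intervals: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(fields)}"
                )
            try:
                scaffold, start, end, depth = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    float(fields[3]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            intervals.append((scaffold, start, end, depth))
    try:
        return CoverageTrack.build(intervals, library_size)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for scaffold, start, end, depth in track.intervals:
            fh.write(f"{scaffold}\t{start}\t{end}\t{depth:g}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED3+ file, returning (scaffold, start, end) tuples."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            out.append((fields[0], start, end))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for scaffold, start, end in sorted(intervals):
            fh.write(f"{scaffold}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Feature annotations (BED with category column, or GFF3)
# ---------------------------------------------------------------------------

def read_features(path: str | Path) -> list[FeatureAnnotation]:
    """Read feature annotations.

    ``.gff``/``.gff3`` files use the GFF3 type column as the category
    (coordinates converted from 1-based inclusive); anything else is read as
    BED with the category in column 4 and an optional strand in column 6.
    """
    suffix = Path(path).suffix.lower()
    features: list[FeatureAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if suffix in {".gff", ".gff3"}:
                    if len(fields) < 8:
                        raise FormatError("expected >=8 GFF3 columns")
                    scaffold, category = fields[0], fields[2]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6] if fields[6] in {"+", "-"} else "."
                else:
                    if len(fields) < 4:
                        raise FormatError("expected >=4 BED columns")
                    scaffold, category = fields[0], fields[3]
                    start, end = int(fields[1]), int(fields[2])
                    strand = (
                        fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
                    )
                features.append(FeatureAnnotation(scaffold, start, end, category, strand))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return features


def write_features(features: Sequence[FeatureAnnotation], path: str | Path) -> None:
    """Write features as BED6 with the category in the name column."""
    with open(path, "w") as fh:
        for f in sorted(features, key=lambda f: (f.scaffold, f.start)):
            fh.write(
                f"{f.scaffold}\t{f.start}\t{f.end}\t{f.category}\t0\t{f.strand}\n"
            )


# ---------------------------------------------------------------------------
# TRF .dat dialect
# ---------------------------------------------------------------------------

_TRF_MIN_FIELDS = 15


def read_trf_dat(path: str | Path) -> list[TandemRepeatArray]:
    """Read the Tandem Repeats Finder ``.dat`` dialect.

    ``Sequence:`` lines name the scaffold; data rows are space-separated with
    at least 15 fields (start end period copies consensus_size pct_match
    pct_indel score A C G T entropy motif sequence). Coordinates are converted
    from 1-based inclusive to 0-based half-open. A ``period != len(motif)``
    mismatch is reconciled (warning, motif wins); everything else is rejected.
    """
    arrays: list[TandemRepeatArray] = []
    scaffold: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                name = line[len("Sequence:") :].strip().split()
                if not name:
                    raise FormatError(f"{path}: line {lineno}: empty Sequence: header")
                scaffold = name[0]
                continue
            if scaffold is None or line.startswith("Parameters:"):
                # preamble before the first Sequence: block, or parameter echoes
                continue
            fields = line.split()
            if len(fields) < _TRF_MIN_FIELDS:
                raise FormatError(
                    f"{path}: line {lineno}: expected >={_TRF_MIN_FIELDS} fields, "
                    f"got {len(fields)}"
                )
            try:
                start = int(fields[0]) - 1
                end = int(fields[1])
                period = int(fields[2])
                copies = float(fields[3])
                motif = fields[13]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if period != len(motif):
                warnings.warn(
                    f"{path}: line {lineno}: period {period} != motif length "
                    f"{len(motif)}; keeping the motif",
                    stacklevel=2,
                )
                period = len(motif)
            try:
                arrays.append(
                    TandemRepeatArray(scaffold, start, end, period, copies, motif)
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return arrays


def _motif_entropy(motif: str) -> float:
    counts = Counter(motif)
    n = len(motif)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def write_trf_dat(arrays: Sequence[TandemRepeatArray], path: str | Path) -> None:
    """Write arrays in the ``.dat`` dialect read by :func:`read_trf_dat`."""
    by_scaffold: dict[str, list[TandemRepeatArray]] = {}
    for a in arrays:
        by_scaffold.setdefault(a.scaffold, []).append(a)
    with open(path, "w") as fh:
        fh.write("Tandem Repeats Finder output (censat dialect)\n\n")
        for scaffold in sorted(by_scaffold):
            fh.write(f"Sequence: {scaffold}\n\n")
            fh.write("Parameters: 2 7 7 80 10 50 2000\n\n")
            for a in sorted(by_scaffold[scaffold], key=lambda a: a.start):
                counts = Counter(a.motif)
                n = len(a.motif)
                comp = [round(100 * counts.get(b, 0) / n) for b in "ACGT"]
                fh.write(
                    f"{a.start + 1} {a.end} {a.period} {a.copy_number:.1f} "
                    f"{a.period} 95 0 {2 * a.array_length} "
                    f"{comp[0]} {comp[1]} {comp[2]} {comp[3]} "
                    f"{_motif_entropy(a.motif):.2f} {a.motif} {a.motif}\n"
                )


# ---------------------------------------------------------------------------
# BLAST tabular (12-column outfmt 6)
# ---------------------------------------------------------------------------

_BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(
    path: str | Path, query_lengths: Mapping[str, int]
) -> list[AlignmentHit]:
    """Read 12-column BLAST tabular output, attaching query lengths.

    A query id absent from ``query_lengths`` is an error; identities outside
    [0, 100] are format errors. Coordinates become 0-based half-open.
    """
    try:
        frame = pd.read_csv(
            path, sep="\t", header=None, names=_BLAST_COLUMNS, comment="#"
        )
    except pd.errors.EmptyDataError:
        return []
    hits: list[AlignmentHit] = []
    for row in frame.itertuples(index=False):
        qid = str(row.qseqid)
        if qid not in query_lengths:
            raise FormatError(
                f"{path}: query {qid!r} absent from the supplied query_lengths"
            )
        try:
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=str(row.sseqid),
                    pct_identity=float(row.pident),
                    aln_length=int(row.length),
                    q_start=min(int(row.qstart), int(row.qend)) - 1,
                    q_end=max(int(row.qstart), int(row.qend)),
                    s_start=min(int(row.sstart), int(row.send)) - 1,
                    s_end=max(int(row.sstart), int(row.send)),
                    evalue=float(row.evalue),
                    bitscore=float(row.bitscore),
                    query_length=int(query_lengths[qid]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return hits
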