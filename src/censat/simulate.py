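"""Synthetic genomes, annotations, coverage and reads with planted centromeres.

The generator emulates the data-generating situation the pipeline assumes: a
multi-scaffold genome where each (non-X) scaffold carries one centromere
region hosting tandem-repeat arrays from a small set of repeat families; one
family (the telomeric AACCT motif by default) is shared across several
scaffolds while another is scaffold-specific. ChIP coverage is fold-enriched
over input inside centromere regions (or chromosome-wide on an optional
X-mimicking scaffold), and read sets are sampled with probability
proportional to the ChIP coverage expectation. A :class:`TruthSet` records
everything planted so every downstream stage can be scored exactly.

Determinism: all outputs are byte-identical under a fixed config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    CoverageTrack,
    FeatureAnnotation,
    SequenceRecord,
    TandemRepeatArray,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_features,
    write_trf_dat,
)
from .io import AlignmentHit
from .composition import DEFAULT_CATEGORIES
from .motifs import motif_similarity, reverse_complement

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TELOMERE_MOTIF = "AACCT"

#: library size attached to simulated tracks; equal for ChIP and input so the
#: fold enrichment survives per-million normalization unchanged (the tracks
#: represent depth after equal-depth library normalization).
_TRACK_LIBRARY_SIZE = 1_000_000.0

# background feature mix for the 12 non-tandem-repeat categories
_FEATURE_WEIGHTS = {
    "exon": 0.10,
    "intron": 0.20,
    "five_prime_UTR": 0.02,
    "three_prime_UTR": 0.02,
    "DNA_transposon": 0.08,
    "LTR_retrotransposon": 0.08,
    "LINE": 0.05,
    "SINE": 0.03,
    "rolling_circle": 0.02,
    "low_complexity": 0.02,
    "unknown_repeat": 0.03,
    "intergenic": 0.35,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with desk-scale defaults."""

    seed: int = 0
    n_scaffolds: int = 5
    scaffold_length: int = 200_000
    n_families: int = 4
    motif_lengths: tuple[int, ...] = (5, 63, 150, 384)
    divergence: float = 0.05
    arrays_per_family: int = 4
    array_copy_number: int = 20
    min_array_bp: int = 1_000
    array_gap: int = 200
    centromere_length: int = 40_000
    centromere_fold_enrichment: float = 16.0
    background_depth: float = 30.0
    noise_model: str = "poisson"  # {"none", "poisson", "negative_binomial"}
    nb_dispersion: float = 10.0
    x_mode: bool = False
    x_terminal_boost: float = 1.5
    include_telomere_family: bool = True
    higher_order: bool = False
    indel_rate: float = 0.0
    read_length: int = 100
    n_reads_chip: int = 200_000
    n_reads_input: int = 200_000
    window_size: int = 10_000
    coverage_bin: int = 100

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1 or self.scaffold_length < 1:
            raise ValueError("need at least one scaffold of positive length")
        if self.n_families < 1 or self.arrays_per_family < 1:
            raise ValueError("need at least one family and one array per family")
        if not self.motif_lengths or any(l < 1 for l in self.motif_lengths):
            raise ValueError("motif_lengths must be positive")
        if not 0.0 <= self.divergence <= 0.2:
            raise ValueError("divergence must be in [0, 0.2]")
        if self.centromere_fold_enrichment < 1.0:
            raise ValueError("fold enrichment must be >= 1")
        if self.noise_model not in {"none", "poisson", "negative_binomial"}:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.centromere_length >= self.scaffold_length:
            raise ValueError("centromere longer than scaffold")
        if self.read_length > self.scaffold_length:
            raise ValueError("read_length exceeds scaffold_length")
        if self.x_mode and self.n_scaffolds < 2:
            raise ValueError("x_mode needs at least two scaffolds")


@dataclass(frozen=True)
class PlantedFamily:
    family_id: int
    generator_motif: str
    member_motifs: tuple[str, ...]


@dataclass
class TruthSet:
    """Ground truth of a simulated genome for recovery scoring."""

    planted_families: list[PlantedFamily]
    planted_arrays: list[TandemRepeatArray]
    array_families: list[int]  # parallel to planted_arrays
    centromere_regions: list[tuple[str, int, int]]
    feature_partition: list[FeatureAnnotation]
    scaffold_lengths: dict[str, int]
    x_scaffold: str | None = None

    def centromere_windows(self, window_size: int) -> set[tuple[str, int, int]]:
        """Windows overlapping a planted centromere region (non-X scaffolds)."""
        out: set[tuple[str, int, int]] = set()
        for scaffold, start, end in self.centromere_regions:
            length = self.scaffold_lengths[scaffold]
            w0 = start // window_size
            w1 = (end - 1) // window_size
            for w in range(w0, w1 + 1):
                out.add(
                    (scaffold, w * window_size, min((w + 1) * window_size, length))
                )
        return out

    def family_partition(self) -> dict[int, frozenset[int]]:
        """Array indices grouped by planted family id."""
        groups: dict[int, set[int]] = {}
        for idx, fid in enumerate(self.array_families):
            groups.setdefault(fid, set()).add(idx)
        return {fid: frozenset(ids) for fid, ids in groups.items()}


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, length)].tobytes().decode()


def _mutate(motif: str, rate: float, rng: np.random.Generator, indel_rate: float = 0.0) -> str:
    """Per-base substitutions at ``rate`` plus optional indels."""
    if rate <= 0 and indel_rate <= 0:
        return motif
    idx = {b: i for i, b in enumerate(_BASES)}
    out: list[str] = []
    subs = rng.random(len(motif)) < rate
    for i, base in enumerate(motif):
        if indel_rate > 0 and rng.random() < indel_rate / 2:
            continue  # deletion
        if subs[i]:
            base = _BASES[(idx[base] + int(rng.integers(1, 4))) % 4]
        out.append(base)
        if indel_rate > 0 and rng.random() < indel_rate / 2:
            out.append(_BASES[int(rng.integers(0, 4))])  # insertion
    if not out:
        out.append(motif[0])
    return "".join(out)


def _draw_generator_motifs(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Distinct generator motifs, rejection-sampled to be mutually dissimilar."""
    motifs: list[str] = []
    for i in range(config.n_families):
        length = config.motif_lengths[i % len(config.motif_lengths)]
        if config.include_telomere_family and length == len(_TELOMERE_MOTIF) and \
                _TELOMERE_MOTIF not in motifs:
            motifs.append(_TELOMERE_MOTIF)
            continue
        for _ in range(50):
            candidate = _random_seq(rng, length)
            if len(set(candidate)) < 2:
                continue
            if all(motif_similarity(candidate, m) < 70.0 for m in motifs):
                motifs.append(candidate)
                break
        else:
            raise RuntimeError("could not draw a dissimilar generator motif")
    return motifs


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _scaffold_names(config: SimulationConfig) -> list[str]:
    return [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]


def _centromere_region(config: SimulationConfig, length: int) -> tuple[int, int]:
    # window-aligned, centred: keeps truth windows identical to called windows
    start = ((length - config.centromere_length) // 2 // config.window_size) * \
        config.window_size
    return start, start + config.centromere_length


def generate_genome(config: SimulationConfig) -> tuple[list[SequenceRecord], TruthSet]:
    """Generate the genome and its :class:`TruthSet`.

    Each family's generator motif is diverged once per array (the member
    motif, which is what a tandem-repeat annotator's consensus would report)
    and again per copy within the array. One family is planted across several
    scaffolds, one is scaffold-specific; the rest are distributed round-robin.
    """
    rng = np.random.default_rng([config.seed, 0])
    names = _scaffold_names(config)
    x_scaffold = names[-1] if config.x_mode else None
    cen_scaffolds = [n for n in names if n != x_scaffold]
    scaffold_lengths = {n: config.scaffold_length for n in names}

    generators = _draw_generator_motifs(config, rng)
    shared_idx = (
        generators.index(_TELOMERE_MOTIF)
        if config.include_telomere_family and _TELOMERE_MOTIF in generators
        else 0
    )
    specific_idx = next(
        (i for i in range(config.n_families - 1, -1, -1) if i != shared_idx),
        shared_idx,
    )

    # effective copies: short motifs are repeated enough to span >= min_array_bp
    def copies_for(motif: str) -> int:
        return max(
            config.array_copy_number, -(-config.min_array_bp // len(motif))
        )

    # plan arrays: (family_idx, target scaffold or None for first-fit)
    plan: list[tuple[int, str | None]] = []
    rr = 0
    for fam in range(config.n_families):
        for a in range(config.arrays_per_family):
            if fam == shared_idx:
                target = cen_scaffolds[a % len(cen_scaffolds)]
            elif fam == specific_idx and config.n_families > 1:
                target = cen_scaffolds[-1]
            else:
                target = cen_scaffolds[rr % len(cen_scaffolds)]
                rr += 1
            plan.append((fam, target))

    # member motifs and array sequences
    member_motifs: dict[int, list[str]] = {f: [] for f in range(config.n_families)}
    array_seqs: list[tuple[int, str, str]] = []  # (family_idx, scaffold, sequence)
    truth_arrays_raw: list[tuple[int, str, str, str]] = []
    for fam, scaffold in plan:
        member = _mutate(
            generators[fam], config.divergence, rng, config.indel_rate
        )
        member_motifs[fam].append(member)
        n_copies = copies_for(member)
        seq = "".join(
            _mutate(member, config.divergence, rng, config.indel_rate)
            for _ in range(n_copies)
        )
        array_seqs.append((fam, scaffold, seq))
        truth_arrays_raw.append((fam, scaffold, member, seq))

    if config.higher_order and config.n_families >= 2:
        composite = generators[shared_idx] + generators[specific_idx]
        member_motifs[-1] = [composite]
        n_copies = copies_for(composite)
        seq = "".join(
            _mutate(composite, config.divergence, rng, config.indel_rate)
            for _ in range(n_copies)
        )
        truth_arrays_raw.append((-1, cen_scaffolds[0], composite, seq))

    # lay out arrays inside each scaffold's centromere region (first-fit by size)
    regions = {
        n: _centromere_region(config, scaffold_lengths[n]) for n in cen_scaffolds
    }
    cursors = {n: regions[n][0] for n in cen_scaffolds}
    placed: list[tuple[str, int, int, int, str]] = []  # scaffold, start, end, fam, member
    order = sorted(
        range(len(truth_arrays_raw)),
        key=lambda i: -len(truth_arrays_raw[i][3]),
    )
    positions: dict[int, tuple[str, int, int]] = {}
    for i in order:
        fam, scaffold, member, seq = truth_arrays_raw[i]
        start = cursors[scaffold]
        end = start + len(seq)
        if end > regions[scaffold][1]:
            raise ValueError(
                f"planted arrays do not fit in the centromere of {scaffold}; "
                "reduce copy number or enlarge centromere_length"
            )
        cursors[scaffold] = end + config.array_gap
        positions[i] = (scaffold, start, end)

    # build sequences
    seqs = {
        n: bytearray(_random_seq(rng, scaffold_lengths[n]).encode()) for n in names
    }
    planted_arrays: list[TandemRepeatArray] = []
    array_families: list[int] = []
    for i, (fam, scaffold, member, seq) in enumerate(truth_arrays_raw):
        scaffold, start, end = positions[i]
        seqs[scaffold][start:end] = seq.encode()
        planted_arrays.append(
            TandemRepeatArray(
                scaffold=scaffold,
                start=start,
                end=end,
                period=len(member),
                copy_number=round(len(seq) / len(member), 1),
                motif=member,
            )
        )
        array_families.append(fam + 1 if fam >= 0 else config.n_families + 1)

    records = [SequenceRecord(n, seqs[n].decode()) for n in names]

    # feature partition: tandem_repeat == planted arrays, rest chopped randomly
    partition = _feature_partition(
        rng, scaffold_lengths, planted_arrays, config
    )

    families = [
        PlantedFamily(
            family_id=f + 1,
            generator_motif=generators[f],
            member_motifs=tuple(member_motifs[f]),
        )
        for f in range(config.n_families)
    ]
    if config.higher_order and -1 in member_motifs:
        families.append(
            PlantedFamily(
                family_id=config.n_families + 1,
                generator_motif=member_motifs[-1][0],
                member_motifs=tuple(member_motifs[-1]),
            )
        )

    truth = TruthSet(
        planted_families=families,
        planted_arrays=planted_arrays,
        array_families=array_families,
        centromere_regions=[
            (n, regions[n][0], regions[n][1]) for n in cen_scaffolds
        ],
        feature_partition=partition,
        scaffold_lengths=scaffold_lengths,
        x_scaffold=x_scaffold,
    )
    return records, truth


def _feature_partition(
    rng: np.random.Generator,
    scaffold_lengths: dict[str, int],
    arrays: Sequence[TandemRepeatArray],
    config: SimulationConfig,
) -> list[FeatureAnnotation]:
    cats = [c for c in DEFAULT_CATEGORIES if c != "tandem_repeat"]
    weights = np.array([_FEATURE_WEIGHTS[c] for c in cats])
    weights = weights / weights.sum()
    partition: list[FeatureAnnotation] = []
    by_scaffold: dict[str, list[TandemRepeatArray]] = {s: [] for s in scaffold_lengths}
    for a in arrays:
        by_scaffold[a.scaffold].append(a)
    for scaffold, length in scaffold_lengths.items():
        cursor = 0
        bounds = sorted((a.start, a.end) for a in by_scaffold[scaffold])
        for start, end in bounds + [(length, length)]:
            # chop the gap [cursor, start) into background feature chunks
            while cursor < start:
                chunk = int(rng.integers(500, 5001))
                chunk_end = min(cursor + chunk, start)
                cat = cats[int(rng.choice(len(cats), p=weights))]
                partition.append(
                    FeatureAnnotation(scaffold, cursor, chunk_end, cat)
                )
                cursor = chunk_end
            if start < end:
                partition.append(
                    FeatureAnnotation(scaffold, start, end, "tandem_repeat")
                )
                cursor = end
    return partition


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------

def _expected_chip_segments(
    scaffold: str, length: int, truth: TruthSet, config: SimulationConfig
) -> list[tuple[int, int, float]]:
    bg = config.background_depth
    fold = config.centromere_fold_enrichment
    if truth.x_scaffold == scaffold:
        boost_end = min(config.window_size, length)
        return [
            (0, boost_end, bg * fold * config.x_terminal_boost),
            (boost_end, length, bg * fold),
        ]
    regions = [r for r in truth.centromere_regions if r[0] == scaffold]
    segments: list[tuple[int, int, float]] = []
    cursor = 0
    for _, start, end in sorted(regions, key=lambda r: r[1]):
        if cursor < start:
            segments.append((cursor, start, bg))
        segments.append((start, end, bg * fold))
        cursor = end
    if cursor < length:
        segments.append((cursor, length, bg))
    return segments


def _realize(
    segments: list[tuple[int, int, float]],
    scaffold: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[str, int, int, float]]:
    if config.noise_model == "none":
        return [(scaffold, s, e, d) for s, e, d in segments if e > s]
    out: list[tuple[str, int, int, float]] = []
    bin_size = config.coverage_bin
    for s, e, d in segments:
        starts = np.arange(s, e, bin_size)
        ends = np.minimum(starts + bin_size, e)
        n = len(starts)
        if config.noise_model == "poisson":
            depths = rng.poisson(d, size=n).astype(float)
        else:
            r = config.nb_dispersion
            p = r / (r + d)
            depths = rng.negative_binomial(r, p, size=n).astype(float)
        out.extend(
            (scaffold, int(bs), int(be), float(dd))
            for bs, be, dd in zip(starts, ends, depths)
        )
    return out


def simulate_coverage(
    genome: Sequence[SequenceRecord], truth: TruthSet, config: SimulationConfig
) -> tuple[CoverageTrack, CoverageTrack]:
    """ChIP and input coverage tracks with the configured fold enrichment.

    Input has constant expected depth everywhere; ChIP is fold-enriched
    inside centromere regions (chromosome-wide, with a stronger terminal
    window, on the X-mode scaffold). Both tracks carry the same library size
    so their per-million normalized ratio equals the depth ratio.
    """
    rng = np.random.default_rng([config.seed, 1])
    chip_rows: list[tuple[str, int, int, float]] = []
    input_rows: list[tuple[str, int, int, float]] = []
    for rec in genome:
        length = truth.scaffold_lengths[rec.id]
        chip_rows.extend(
            _realize(
                _expected_chip_segments(rec.id, length, truth, config),
                rec.id, config, rng,
            )
        )
        input_rows.extend(
            _realize([(0, length, config.background_depth)], rec.id, config, rng)
        )
    chip = CoverageTrack.build(chip_rows, library_size=_TRACK_LIBRARY_SIZE)
    control = CoverageTrack.build(input_rows, library_size=_TRACK_LIBRARY_SIZE)
    return chip, control


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: Sequence[SequenceRecord], truth: TruthSet, config: SimulationConfig
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Fixed-length read sets: input uniform, ChIP enrichment-weighted.

    ChIP read midpoints are sampled proportionally to the expected ChIP
    coverage; both sets are reverse-complemented with probability 0.5. Read
    ids encode origin as ``prefix_i|scaffold|start|strand`` for truth checks.
    """
    if config.read_length > min(truth.scaffold_lengths.values()):
        raise ValueError("read_length exceeds the shortest scaffold")
    rng = np.random.default_rng([config.seed, 2])
    seqs = {rec.id: rec.seq for rec in genome}

    def sample(n_reads: int, weighted: bool, prefix: str) -> list[SequenceRecord]:
        if n_reads == 0:
            return []
        bin_size = config.coverage_bin
        scaffolds: list[str] = []
        bin_starts: list[int] = []
        weights: list[float] = []
        for rec in genome:
            length = truth.scaffold_lengths[rec.id]
            segments = (
                _expected_chip_segments(rec.id, length, truth, config)
                if weighted
                else [(0, length, 1.0)]
            )
            for s, e, d in segments:
                starts = np.arange(s, e, bin_size)
                ends = np.minimum(starts + bin_size, e)
                scaffolds.extend([rec.id] * len(starts))
                bin_starts.extend(starts.tolist())
                weights.extend((d * (ends - starts)).tolist())
        w = np.asarray(weights, dtype=float)
        p = w / w.sum()
        picks = rng.choice(len(w), size=n_reads, p=p)
        offsets = rng.integers(0, bin_size, size=n_reads)
        flips = rng.random(n_reads) < 0.5
        reads: list[SequenceRecord] = []
        for i, (pick, off, flip) in enumerate(zip(picks, offsets, flips)):
            scaffold = scaffolds[pick]
            length = truth.scaffold_lengths[scaffold]
            mid = bin_starts[pick] + int(off)
            start = min(max(mid - config.read_length // 2, 0),
                        length - config.read_length)
            seq = seqs[scaffold][start : start + config.read_length]
            strand = "+"
            if flip:
                seq = reverse_complement(seq)
                strand = "-"
            reads.append(
                SequenceRecord(f"{prefix}_{i}|{scaffold}|{start}|{strand}", seq)
            )
        return reads

    chip_reads = sample(config.n_reads_chip, True, "chip")
    input_reads = sample(config.n_reads_input, False, "input")
    return chip_reads, input_reads


# ---------------------------------------------------------------------------
# truth serialization and synthetic alignment hits
# ---------------------------------------------------------------------------

def write_truth(truth: TruthSet, outdir: str | Path) -> dict[str, Path]:
    """Serialize the truth set: TRF .dat, BED, features BED, family TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "arrays": outdir / "planted_arrays.dat",
        "centromeres": outdir / "centromere_regions.bed",
        "features": outdir / "feature_partition.bed",
        "families": outdir / "planted_families.tsv",
        "array_families": outdir / "array_families.tsv",
        "scaffolds": outdir / "scaffold_lengths.tsv",
    }
    order = sorted(
        range(len(truth.planted_arrays)),
        key=lambda i: (truth.planted_arrays[i].scaffold, truth.planted_arrays[i].start),
    )
    write_trf_dat([truth.planted_arrays[i] for i in order], paths["arrays"])
    write_bed(truth.centromere_regions, paths["centromeres"])
    write_features(truth.feature_partition, paths["features"])
    with open(paths["families"], "w") as fh:
        fh.write("family_id\tgenerator_motif\tmember_index\tmember_motif\n")
        for fam in truth.planted_families:
            for i, member in enumerate(fam.member_motifs):
                fh.write(f"{fam.family_id}\t{fam.generator_motif}\t{i}\t{member}\n")
    with open(paths["array_families"], "w") as fh:
        fh.write("scaffold\tstart\tend\tfamily_id\n")
        for i in order:
            a = truth.planted_arrays[i]
            fh.write(
                f"{a.scaffold}\t{a.start}\t{a.end}\t{truth.array_families[i]}\n"
            )
    with open(paths["scaffolds"], "w") as fh:
        fh.write("scaffold\tlength\n")
        for scaffold, length in truth.scaffold_lengths.items():
            fh.write(f"{scaffold}\t{length}\n")
    return paths


def synthetic_blast_hits(
    truth: TruthSet, identity: float = 95.0
) -> tuple[list[AlignmentHit], dict[str, int], dict[str, int]]:
    """Synthetic stand-in for a BLASTN search of family representatives.

    One full-coverage hit per planted array, spanning the array and carrying
    the given identity. Returns (hits, query_lengths, family_of_query) ready
    for :func:`censat.representation.representation_by_hits`. Synthetic:
    used where running an aligner is out of scope.
    """
    hits: list[AlignmentHit] = []
    query_lengths: dict[str, int] = {}
    family_of_query: dict[str, int] = {}
    gen_by_id = {f.family_id: f.generator_motif for f in truth.planted_families}
    for arr, fid in zip(truth.planted_arrays, truth.array_families):
        qid = f"family_{fid}"
        qlen = len(gen_by_id.get(fid, arr.motif))
        query_lengths[qid] = qlen
        family_of_query[qid] = fid
        hits.append(
            AlignmentHit(
                query_id=qid,
                subject_id=arr.scaffold,
                pct_identity=identity,
                aln_length=qlen,
                q_start=0,
                q_end=qlen,
                s_start=arr.start,
                s_end=arr.end,
                evalue=1e-20,
                bitscore=2.0 * qlen,
                query_length=qlen,
            )
        )
    return hits, query_lengths, family_of_query


def write_simulation(
    config: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Run the full generator and serialize genome, coverage, reads and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(config)
    chip, control = simulate_coverage(genome, truth, config)
    chip_reads, input_reads = simulate_reads(genome, truth, config)
    paths = {
        "genome": outdir / "genome.fasta",
        "chip_bedgraph": outdir / "chip.bedgraph",
        "input_bedgraph": outdir / "input.bedgraph",
        "chip_reads": outdir / "chip_reads.fasta",
        "input_reads": outdir / "input_reads.fasta",
    }
    write_fasta(genome, paths["genome"])
    write_bedgraph(chip, paths["chip_bedgraph"])
    write_bedgraph(control, paths["input_bedgraph"])
    write_fasta(chip_reads, paths["chip_reads"])
    write_fasta(input_reads, paths["input_reads"])
    paths["library_sizes"] = outdir / "library_sizes.tsv"
    with open(paths["library_sizes"], "w") as fh:
        fh.write("track\tlibrary_size\n")
        fh.write(f"chip\t{chip.library_size:g}\n")
        fh.write(f"input\t{control.library_size:g}\n")
    paths.update(write_truth(truth, outdir / "truth"))
    return paths
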