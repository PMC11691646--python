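# Methods

This note documents the models, parameter choices and numerical conventions
behind `censat`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open. Formats that are 1-based
inclusive on disk (the Tandem Repeats Finder `.dat` dialect, BLAST tabular)
are converted at the I/O boundary and nowhere else. Readers reject invariant
violations (overlapping coverage intervals, duplicate FASTA ids, identities
outside [0, 100]) rather than repairing them; the single documented exception
is a TRF row whose period disagrees with its motif length, which is
reconciled in favour of the motif with a warning. `N` bases are preserved in
genome sequences, but motifs containing `N` are rejected because the
canonicalization and distance algebra is defined over {A,C,G,T}.

A coverage track's `library_size` is the normalization constant (mapped-read
count or equivalent). When not supplied it defaults to the track's total
depth x length mass, which keeps small test files self-contained — but note
that for a strongly enriched ChIP track this default absorbs part of the
enrichment signal, so real analyses should pass the mapped-read counts
explicitly (the CLI exposes `--chip-library-size` / `--input-library-size`,
and the simulator writes a `library_sizes.tsv`).

## Windowed enrichment

Mean coverage is computed in nonoverlapping 10-kb windows (the last window of
a scaffold may be short and is retained — dropping it would silently truncate
telocentric centromeres), divided by the library size and rescaled by 1e6.
Per-million scaling is one concrete choice of "common scaling"; any constant
common to both libraries leaves the log2 ratio unchanged. The enrichment
statistic is `log2((chip + p) / (input + p))` with pseudocount `p = 0.01`
normalized units, which bounds ratios for zero-input windows without
discarding them. Whether means are computed before or after library
normalization is immaterial to the ratio; normalization-then-averaging is
used. Both calling thresholds are inclusive: `>= 2` (4-fold) defines
centromere windows, `>= 4` (16-fold) defines the strongly enriched windows
used for feature-composition sums.

One consequence of the pseudocount worth knowing: at exactly 16-fold
enrichment the noise-free ratio is log2((16b+p)/(b+p)), a hair *below* 4, so
composition analyses exercised at the 16x feature threshold use simulations
with 32-fold enrichment to sit clear of the boundary.

Sex-linkage calling uses per-scaffold male:female normalized coverage: in an
X0 system males carry one X, so X-linked scaffolds are expected near ratio
0.5 (band [0.35, 0.65]) and autosomes near 1.0 (band [0.85, 1.15]); anything
else, including zero female coverage, is labelled ambiguous.

## Feature composition

The default taxonomy has 13 categories (exon, intron, 5'/3' UTR, tandem
repeat, DNA transposon, LTR retrotransposon, LINE, SINE, rolling-circle,
low-complexity, unknown repeat, intergenic). Overlaps are resolved by a
precedence order defaulting to repeat classes > genic classes > intergenic,
which preserves the repeat signal the analysis targets; unannotated bases are
intergenic, so the partition tiles each scaffold exactly. The goodness-of-fit
test treats summed base pairs as counts: chi2 = sum (O-E)^2/E with expected
counts from the background proportions of the same scope (scope-matched
backgrounds; genome-wide backgrounds are obtainable by passing a single
scope). df is always |categories| - 1 = 12. Because adjacent bases are
strongly autocorrelated, these chi-square values are inflated and should be
read descriptively, not as calibrated p-values.

## Motif canonicalization and similarity

A tandem-repeat monomer is a cyclic, strand-less object. Its canonical form
is the lexicographic minimum (A<C<G<T) over all rotations of the motif and of
its reverse complement, computed with Booth's least-rotation algorithm and
verified against brute-force enumeration of all 2L candidates. Similarity
between motifs a, b: both are canonicalized, the shorter is tandem-duplicated
and truncated to the longer length L ("adjusted by tandem duplication" —
truncation, not rounding up), and

```
similarity = 100 * (L - d) / L,
d = min over strand in {+, -} of min over rotations r of Levenshtein(r(x), strand(y))
```

with edit distances computed by edlib and the rotation scan applied to the
lexicographically smaller operand so that similarity is exactly symmetric.
Canonicalizing inside the similarity makes it invariant under rotation and
strand flip of either argument. The denominator is the longer length, which
keeps similarity <= 100 and matches the 80%-identity alignment analogy. Both
orientations are tried even though canonicalization fixes a strand, because
canonical forms of near-identical motifs can land on opposite strands.

## Family clustering

Identical canonical motifs are merged (abundances aggregated) before the
quadratic all-pairs comparison, which is guarded by a configurable motif-count
cap. Edges require similarity >= 80 (inclusive). "Network clustering" is
implemented as connected components — the minimal, parameter-free reading;
community detection is a deliberate extension point, not a default. Families
are numbered by descending total bp (ties: array count, then smallest
canonical string), and each family's representative maximizes, in order:
total supporting bp, number of arrays, network degree, with the canonical
string as the final deterministic tie-break — the same priorities used to
select probe candidates. Composite (higher-order) families are *not*
auto-detected or removed; that judgement is left to the analyst.

Arrays enter clustering when they overlap a called centromere window AND
their footprint-weighted local log2 ratio (window means weighted by overlap
length) itself reaches the centromere threshold.

## k-mer route

Canonical k-mers use strand-min only (reads are unstranded; no rotation).
The min-count filter applies to raw counts in both data sets; normalization
is per total base pairs of the respective read set (sum of read lengths, not
window counts), so enrichment is invariant under joint rescaling. The outlier
cutoff is `median + 25 * MAD` with the *raw* MAD (no 1.4826 consistency
constant) and strict `>` semantics — a constant enrichment distribution
yields an empty enriched set. Only enrichment is called (one-sided): depletion
does not define centromeres here.

The default `min_count = 100` reflects production sequencing depth. The
filter's job is to exclude unreliably counted k-mers, so it scales with
coverage: the bundled desk-scale simulations (about 20x per library) use
`min_count = 5`.

The unitig builder produces maximal non-branching paths of the bidirected de
Bruijn graph over canonical k-mers, with deterministic seed order and
output ordering (descending length, then sequence, strand-canonicalized), so
results are invariant under read-order permutation. It is plumbing, not an
assembler: no error correction, tip clipping or coverage heuristics. A
minimal tandem detector (smallest period whose self-match fraction is >=
0.85 over >= 3 copies, consensus by per-phase majority vote with alphabetical
tie-break, periods < 3 and sequences < 25 bp ignored) annotates unitigs when
no external tandem-repeat annotation is available; it is deliberately
conservative, favouring precision over recall.

At the simulated within-array divergence (5% per copy), nearly every motif
position carries a variant k-mer in some copy, so the de Bruijn graph bubbles
at almost every position and unitigs of long-monomer families stay near k in
length. The practical consequence is that the k-mer route recovers the
short-monomer (telomeric) family reliably and long-monomer families rarely —
a proper subset of the assembly-route families, which is also the qualitative
relationship expected between the two routes on real data.

## Representation matrices

Method 1 sums annotated array lengths per (scaffold, family), clipping
arrays at centromere-window edges (an array straddling a window boundary
contributes only its inside portion). Method 2 filters alignment hits at
>= 80% identity AND >= 80% query coverage (both inclusive), merges
overlapping subject spans of the same family before summing (span, not hit
count, is the quantity of interest), and clips to the same windows. Cells are
therefore bounded by the scaffold's total flagged-window span, and both
matrices are invariant under input permutation and hit duplication.

## Synthetic data

The generator's defaults define the study conditions used throughout the
tests: 5 scaffolds x 200 kb; 4 repeat families with monomer lengths 5, 63,
150 and 384 bp (the 5-mer defaults to the telomeric `AACCT`, planted on
several scaffolds as the shared family; one long-monomer family is private to
a single scaffold; the rest are distributed round-robin); per-base
substitution divergence 0.05 applied once per array (the "member" motif an
annotator's consensus would report) and again per copy; 40-kb window-aligned
centromere regions with 16-fold ChIP enrichment over a 30x background;
Poisson per-100-bp-bin coverage noise (negative-binomial and noise-free
available); 200,000 reads of 100 bp per library (~20x). Short monomers get
their copy number raised so every array spans at least 1 kb, matching the
kilobase scale of real satellite arrays. Generator motifs are
rejection-sampled to pairwise similarity < 70 so family identity is
well-defined. An optional X-mode scaffold receives chromosome-wide ChIP
enrichment with a 1.5x boost in its first window, emulating a sex chromosome
with longitudinal CenH3 binding and a terminal constriction; an optional
higher-order mode plants one composite array concatenating two family
motifs. Simulated ChIP and input tracks carry equal library sizes, i.e. they
represent depth after equal-depth normalization, so the planted fold survives
per-million scaling exactly.

ChIP reads are sampled with probability proportional to the expected
coverage at the read midpoint (bin resolution 100 bp) and reverse
complemented with probability 0.5. The simulation omits sequencing errors,
quality scores, PCR duplicates, mappability structure and indel divergence
(available but off by default, keeping expected within-family similarity
analytically ~100 x (1 - 2d)). Passing recovery tests therefore demonstrates
the correctness of the algorithms under the stated statistical structure, not
robustness to alignment artefacts or assembly error in real data.

Centromere regions are aligned to the 10-kb window grid so that, in the
noise-free limit, called windows equal truth windows as sets — a sharp
end-to-end correctness check that would otherwise be blurred by partial
windows.

## Problem sizes and determinism

The bundled test suite and the acceptance script run the full pipeline on
ten 1-Mb genomes (family recovery), one read-level simulation of 2 x 200k
reads (k-mer route), 10,000 random motifs (canonicalization oracle) and
~17,000 string pairs (edit-distance oracle); everything completes in a few
minutes on one CPU. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; fixed seeds give byte-identical outputs,
including FASTA, bedGraph and `.dat` files.

## Known limitations

- Quadratic all-pairs motif comparison: genome-scale catalogs need the
  documented cap or pre-merging; no locality-sensitive shortcut is provided.
- The per-base feature-partition painter holds one int16 per base per
  scaffold; fine to tens of megabases, not for gigabase genomes.
- In-memory k-mer counting; no disk-backed database.
- The chi-square p-values inherit the base-pair autocorrelation caveat above.
- BAM/CRAM ingestion is out of scope; coverage enters as bedGraph and
  alignment hits as 12-column tabular files.
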