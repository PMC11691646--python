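"""Rotation- and strand-invariant motif algebra for tandem-repeat monomers.

A tandem-repeat monomer is a cyclic string: the annotated motif can start at
any phase of the array and on either strand. Motifs are therefore identified
by their canonical rotation — the lexicographically smallest string among all
rotations of the motif and of its reverse complement — and compared with a
rotation-aware Levenshtein distance after tandem-duplicating the shorter
motif to the length of the longer one.
"""

from __future__ import annotations

import edlib

from .io import MOTIF_ALPHABET

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T} (N is complemented to N elsewhere)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_motif(motif: str) -> None:
    if not motif:
        raise ValueError("motif must be non-empty")
    bad = set(motif) - MOTIF_ALPHABET
    if bad:
        raise ValueError(f"motif contains invalid characters {sorted(bad)}")


def least_rotation(s: str) -> str:
    """Lexicographically smallest rotation of ``s`` (Booth's algorithm)."""
    n = len(s)
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + n]


def rotations(s: str):
    """Yield all rotations of ``s``."""
    for i in range(len(s)):
        yield s[i:] + s[:i]


def canonical_rotation(motif: str) -> str:
    """Canonical form of a motif: minimal rotation over both strands.

    The result is the lexicographic minimum (A<C<G<T) over all rotations of
    the motif and all rotations of its reverse complement, making it
    invariant under rotation and strand flips.
    """
    _validate_motif(motif)
    return min(least_rotation(motif), least_rotation(reverse_complement(motif)))


def expand_to_length(motif: str, length: int) -> str:
    """Tandem-duplicate ``motif`` and truncate to exactly ``length`` bases."""
    _validate_motif(motif)
    if length < len(motif):
        raise ValueError(
            f"target length {length} shorter than motif ({len(motif)} bp)"
        )
    reps = -(-length // len(motif))
    return (motif * reps)[:length]


def levenshtein(a: str, b: str) -> int:
    """Plain Levenshtein distance (edlib NW alignment)."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def rotation_min_levenshtein(a: str, b: str) -> int:
    """Minimum Levenshtein distance between ``b`` and any rotation of ``a``.

    Zero iff ``a`` is a rotation of ``b`` (for equal-length inputs). Callers
    comparing motifs of unequal length expand the shorter one first.
    """
    if not a or not b:
        raise ValueError("inputs must be non-empty")
    best = max(len(a), len(b))
    for rot in rotations(a):
        d = edlib.align(rot, b, mode="NW", task="distance")["editDistance"]
        if d < best:
            best = d
            if best == 0:
                break
    return best


def motif_similarity(a: str, b: str) -> float:
    """Percent similarity between two motifs, rotation- and strand-invariant.

    Both motifs are canonicalized, the shorter is tandem-duplicated to the
    length L of the longer, and similarity is
    ``100 * (L - d) / L`` where ``d`` is the minimum rotation-aware
    Levenshtein distance over the forward and reverse-complement orientation.
    Symmetric by construction; 100 iff the motifs are cyclic/strand
    equivalent after expansion.
    """
    ca, cb = canonical_rotation(a), canonical_rotation(b)
    length = max(len(ca), len(cb))
    ea = expand_to_length(ca, length)
    eb = expand_to_length(cb, length)
    # rotate the lexicographically smaller operand so sim(a,b) == sim(b,a)
    x, y = (ea, eb) if ea <= eb else (eb, ea)
    d = rotation_min_levenshtein(x, y)
    if d > 0:
        d = min(d, rotation_min_levenshtein(reverse_complement(x), y))
    return 100.0 * (length - d) / length
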