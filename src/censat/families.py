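"""Assembly-based centromere repeat families.

Tandem-repeat arrays overlapping called centromere windows (and locally
enriched themselves) are canonicalized into a catalog of unique motifs,
compared all-against-all with a rotation-aware Levenshtein similarity, linked
at >= 80% similarity, and partitioned into families as the connected
components of the resulting network. Each family gets a representative motif
chosen to maximize abundance, occurrence count and network connectivity —
the rule used to pick FISH probe candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .io import TandemRepeatArray
from .motifs import canonical_rotation, motif_similarity
from .windows import GenomeWindow, ThresholdConfig, log2_ratio


@dataclass
class CanonicalMotif:
    """Strand- and rotation-invariant motif plus provenance and abundance."""

    canonical: str
    members: list[str] = field(default_factory=list)
    total_bp: int = 0
    n_arrays: int = 0

    @property
    def length(self) -> int:
        return len(self.canonical)


@dataclass
class RepeatFamily:
    """A connected component of the similarity network."""

    family_id: int
    members: list[CanonicalMotif]
    representative: CanonicalMotif
    total_bp: int
    n_arrays: int


def filter_centromeric_arrays(
    arrays: Sequence[TandemRepeatArray],
    windows: Sequence[GenomeWindow],
    thresholds: ThresholdConfig | None = None,
) -> list[TandemRepeatArray]:
    """Keep arrays in called centromere windows that are locally enriched.

    An array is kept when it overlaps at least one centromere window and its
    footprint-weighted log2(ChIP/input), computed from the windows it
    overlaps, is itself >= the centromere threshold.
    """
    thresholds = thresholds or ThresholdConfig()
    by_scaffold: dict[str, list[GenomeWindow]] = {}
    for w in windows:
        by_scaffold.setdefault(w.scaffold, []).append(w)
    for wins in by_scaffold.values():
        wins.sort(key=lambda w: w.start)

    kept: list[TandemRepeatArray] = []
    for arr in arrays:
        wins = by_scaffold.get(arr.scaffold, ())
        touches_centromere = False
        chip_mass = input_mass = span = 0.0
        for w in wins:
            overlap = min(arr.end, w.end) - max(arr.start, w.start)
            if overlap <= 0:
                continue
            if w.is_centromere:
                touches_centromere = True
            chip_mass += w.mean_chip * overlap
            input_mass += w.mean_input * overlap
            span += overlap
        if not touches_centromere or span == 0:
            continue
        local = log2_ratio(chip_mass / span, input_mass / span, thresholds.pseudocount)
        if local >= thresholds.centromere_log2:
            kept.append(arr)
    return kept


def build_catalog(arrays: Sequence[TandemRepeatArray]) -> list[CanonicalMotif]:
    """Merge arrays into a catalog of unique canonical motifs.

    Identical canonical forms are merged before the quadratic all-pairs step,
    aggregating supporting base pairs and array counts.
    """
    catalog: dict[str, CanonicalMotif] = {}
    for arr in arrays:
        canon = canonical_rotation(arr.motif)
        entry = catalog.setdefault(canon, CanonicalMotif(canonical=canon))
        entry.members.append(arr.motif)
        entry.total_bp += arr.array_length
        entry.n_arrays += 1
    return [catalog[c] for c in sorted(catalog)]


def build_family_network(
    catalog: Sequence[CanonicalMotif],
    threshold: float = 80.0,
    max_motifs: int = 2000,
) -> nx.Graph:
    """All-pairs similarity network with edges at similarity >= threshold.

    The all-pairs comparison is quadratic in the catalog size; catalogs above
    ``max_motifs`` are rejected with a suggestion to subsample.
    """
    if len(catalog) > max_motifs:
        raise ValueError(
            f"catalog of {len(catalog)} motifs exceeds max_motifs={max_motifs}; "
            "subsample or raise the cap"
        )
    graph = nx.Graph()
    for motif in catalog:
        graph.add_node(motif.canonical, motif=motif)
    items = sorted(catalog, key=lambda m: m.canonical)
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            sim = motif_similarity(items[i].canonical, items[j].canonical)
            if sim >= threshold:
                graph.add_edge(items[i].canonical, items[j].canonical, similarity=sim)
    return graph


def select_representative(
    members: Sequence[CanonicalMotif], network: nx.Graph | None = None
) -> CanonicalMotif:
    """Pick the family representative: most bp, then most arrays, then the
    best-connected node, with the canonical string as the deterministic
    tie-break."""
    if not members:
        raise ValueError("family has no members")

    def degree(m: CanonicalMotif) -> int:
        if network is None or m.canonical not in network:
            return 0
        return network.degree(m.canonical)

    return sorted(
        members, key=lambda m: (-m.total_bp, -m.n_arrays, -degree(m), m.canonical)
    )[0]


def cluster_families(network: nx.Graph) -> list[RepeatFamily]:
    """Connected components as families, numbered by descending total bp."""
    components: list[list[CanonicalMotif]] = []
    for comp in nx.connected_components(network):
        components.append([network.nodes[c]["motif"] for c in comp])
    components.sort(
        key=lambda ms: (
            -sum(m.total_bp for m in ms),
            -sum(m.n_arrays for m in ms),
            min(m.canonical for m in ms),
        )
    )
    families = []
    for fid, members in enumerate(components, start=1):
        members = sorted(members, key=lambda m: m.canonical)
        families.append(
            RepeatFamily(
                family_id=fid,
                members=members,
                representative=select_representative(members, network),
                total_bp=sum(m.total_bp for m in members),
                n_arrays=sum(m.n_arrays for m in members),
            )
        )
    return families


class RepeatFamilyClusterer(ClusterMixin, BaseEstimator):
    """Cluster tandem-repeat arrays (or raw motifs) into repeat families.

    fit(X) accepts a sequence of :class:`TandemRepeatArray` or of raw motif
    strings. Fitted attributes: ``catalog_`` (unique canonical motifs),
    ``network_`` (similarity graph), ``families_`` (ordered by abundance),
    ``labels_`` (family id per input element) and ``n_families_``.
    """

    def __init__(self, similarity_threshold: float = 80.0, max_motifs: int = 2000):
        self.similarity_threshold = similarity_threshold
        self.max_motifs = max_motifs

    def fit(self, X: Sequence[TandemRepeatArray] | Sequence[str], y=None):
        if len(X) == 0:
            raise ValueError("cannot cluster an empty motif set")
        if isinstance(X[0], str):
            arrays = [
                TandemRepeatArray("query", 0, len(m), len(m), 1.0, m) for m in X
            ]
        else:
            arrays = list(X)
        self.catalog_ = build_catalog(arrays)
        self.network_ = build_family_network(
            self.catalog_, self.similarity_threshold, self.max_motifs
        )
        self.families_ = cluster_families(self.network_)
        self.n_families_ = len(self.families_)
        family_of_canon = {
            m.canonical: fam.family_id
            for fam in self.families_
            for m in fam.members
        }
        self.labels_ = np.array(
            [family_of_canon[canonical_rotation(a.motif)] for a in arrays]
        )
        return self

    def family_of(self, motif: str) -> int | None:
        """Family id of a motif, or None if it is not in the fitted catalog."""
        return {
            m.canonical: fam.family_id
            for fam in self.families_
            for m in fam.members
        }.get(canonical_rotation(motif))


def assembly_route(
    arrays: Sequence[TandemRepeatArray],
    windows: Sequence[GenomeWindow],
    thresholds: ThresholdConfig | None = None,
    similarity_threshold: float = 80.0,
    max_motifs: int = 2000,
) -> tuple[RepeatFamilyClusterer, list[TandemRepeatArray]]:
    """Full assembly-based route: filter arrays, then cluster into families.

    Returns the fitted clusterer and the retained (centromeric) arrays, whose
    order matches ``clusterer.labels_``.
    """
    kept = filter_centromeric_arrays(arrays, windows, thresholds)
    clusterer = RepeatFamilyClusterer(
        similarity_threshold=similarity_threshold, max_motifs=max_motifs
    )
    if kept:
        clusterer.fit(kept)
    else:
        clusterer.catalog_ = []
        clusterer.network_ = nx.Graph()
        clusterer.families_ = []
        clusterer.n_families_ = 0
        clusterer.labels_ = np.array([], dtype=int)
    return clusterer, kept
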