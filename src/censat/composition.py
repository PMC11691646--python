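"""Genomic-feature composition of CenH3-enriched regions.

The genome is partitioned into a fixed taxonomy of feature categories (13 by
default), overlaps resolved by a precedence order; the base-pair composition
of strongly enriched windows (log2 ratio >= 4, i.e. 16-fold) is then compared
to the background composition of the reference span with a chi-square
goodness-of-fit test. Base pairs are used as counts, mirroring the summing of
feature portion lengths; because neighbouring bases are autocorrelated the
resulting chi-square values are inflated and should be read as descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import FeatureAnnotation
from .windows import GenomeWindow, ThresholdConfig

#: The default 13-category feature taxonomy.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "exon",
    "intron",
    "five_prime_UTR",
    "three_prime_UTR",
    "tandem_repeat",
    "DNA_transposon",
    "LTR_retrotransposon",
    "LINE",
    "SINE",
    "rolling_circle",
    "low_complexity",
    "unknown_repeat",
    "intergenic",
)

#: Default overlap precedence: repeat classes > genic classes > intergenic.
DEFAULT_PRECEDENCE: tuple[str, ...] = (
    "tandem_repeat",
    "DNA_transposon",
    "LTR_retrotransposon",
    "LINE",
    "SINE",
    "rolling_circle",
    "low_complexity",
    "unknown_repeat",
    "exon",
    "five_prime_UTR",
    "three_prime_UTR",
    "intron",
    "intergenic",
)


@dataclass(frozen=True)
class FeatureTaxonomy:
    """Ordered category set plus the precedence used to resolve overlaps."""

    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("category names must be unique")
        if "intergenic" not in self.categories:
            raise ValueError("taxonomy must include 'intergenic'")
        if set(self.precedence) != set(self.categories):
            raise ValueError("precedence must order exactly the categories")
        if self.precedence[-1] != "intergenic":
            raise ValueError("'intergenic' must be last in precedence")

    def __len__(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class CompositionResult:
    """Observed vs background composition with the chi-square test."""

    categories: tuple[str, ...]
    observed_bp: dict[str, int]
    background_bp: dict[str, int]
    chi2: float
    df: int
    p_value: float
    std_residuals: dict[str, float]


def flatten_features(
    annotations: Iterable[FeatureAnnotation],
    taxonomy: FeatureTaxonomy,
    scaffold_lengths: Mapping[str, int],
) -> list[FeatureAnnotation]:
    """Resolve overlaps into a disjoint partition covering every base.

    Each base is assigned the highest-precedence category covering it;
    unannotated bases become ``intergenic``. Implemented as a per-base paint
    (adequate for the multi-megabase scales this package targets; a sweep-line
    would be the extension point for full genomes).
    """
    code = {cat: i for i, cat in enumerate(taxonomy.categories)}
    intergenic = code["intergenic"]
    by_scaffold: dict[str, list[FeatureAnnotation]] = {s: [] for s in scaffold_lengths}
    for ann in annotations:
        if ann.category not in code:
            raise ValueError(f"category {ann.category!r} outside the taxonomy")
        if ann.scaffold not in scaffold_lengths:
            raise ValueError(f"unknown scaffold {ann.scaffold!r}")
        if ann.end > scaffold_lengths[ann.scaffold]:
            raise ValueError(
                f"feature [{ann.start}, {ann.end}) exceeds {ann.scaffold} length"
            )
        by_scaffold[ann.scaffold].append(ann)

    partition: list[FeatureAnnotation] = []
    for scaffold, length in scaffold_lengths.items():
        paint = np.full(length, intergenic, dtype=np.int16)
        # paint lowest precedence first so higher precedence overwrites
        for cat in reversed(taxonomy.precedence):
            if cat == "intergenic":
                continue
            for ann in by_scaffold[scaffold]:
                if ann.category == cat:
                    paint[ann.start : ann.end] = code[cat]
        # run-length encode
        breaks = np.flatnonzero(np.diff(paint)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [length]))
        for s, e in zip(starts, ends):
            partition.append(
                FeatureAnnotation(
                    scaffold, int(s), int(e), taxonomy.categories[paint[s]]
                )
            )
    return partition


def category_lengths(
    partition: Iterable[FeatureAnnotation], taxonomy: FeatureTaxonomy
) -> dict[str, int]:
    """Total bp per category over a partition (zero-filled)."""
    out = {cat: 0 for cat in taxonomy.categories}
    for ann in partition:
        out[ann.category] += ann.length
    return out


def enriched_feature_lengths(
    partition: Sequence[FeatureAnnotation],
    windows: Sequence[GenomeWindow],
    thresholds: ThresholdConfig | None = None,
    taxonomy: FeatureTaxonomy | None = None,
) -> dict[str, int]:
    """Per-category bp overlapping windows with log2 ratio >= feature_log2."""
    thresholds = thresholds or ThresholdConfig()
    taxonomy = taxonomy or FeatureTaxonomy()
    enriched: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        if w.log2_ratio >= thresholds.feature_log2:
            enriched.setdefault(w.scaffold, []).append((w.start, w.end))
    for ivals in enriched.values():
        ivals.sort()
    out = {cat: 0 for cat in taxonomy.categories}
    for ann in partition:
        for ws, we in enriched.get(ann.scaffold, ()):
            if ws >= ann.end:
                break
            overlap = min(ann.end, we) - max(ann.start, ws)
            if overlap > 0:
                out[ann.category] += overlap
    return out


def chi_square_gof(
    observed_bp: Mapping[str, int], background_bp: Mapping[str, int]
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of observed bp against background proportions.

    Expected counts are the background proportions scaled to the observed
    total; df is the number of categories minus one. A category observed but
    absent from the background has an undefined expectation and is an error;
    categories absent from both contribute nothing.
    """
    cats = list(observed_bp)
    if set(cats) != set(background_bp):
        raise ValueError("observed and background must share the same categories")
    obs = np.array([observed_bp[c] for c in cats], dtype=float)
    bg = np.array([background_bp[c] for c in cats], dtype=float)
    if bg.sum() <= 0:
        raise ValueError("background span must be positive")
    if np.any((bg == 0) & (obs > 0)):
        offenders = [c for c in cats if background_bp[c] == 0 and observed_bp[c] > 0]
        raise ValueError(
            f"categories observed but absent from background: {offenders}"
        )
    expected = obs.sum() * bg / bg.sum()
    mask = expected > 0
    chi2 = float(((obs[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    df = len(cats) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def _composition_result(
    observed: Mapping[str, int],
    background: Mapping[str, int],
    taxonomy: FeatureTaxonomy,
) -> CompositionResult:
    chi2, df, p = chi_square_gof(observed, background)
    obs = np.array([observed[c] for c in taxonomy.categories], dtype=float)
    bg = np.array([background[c] for c in taxonomy.categories], dtype=float)
    expected = obs.sum() * bg / bg.sum()
    resid = {
        cat: float((o - e) / np.sqrt(e)) if e > 0 else 0.0
        for cat, o, e in zip(taxonomy.categories, obs, expected)
    }
    return CompositionResult(
        categories=taxonomy.categories,
        observed_bp={c: int(observed[c]) for c in taxonomy.categories},
        background_bp={c: int(background[c]) for c in taxonomy.categories},
        chi2=chi2,
        df=df,
        p_value=p,
        std_residuals=resid,
    )


def composition_report(
    windows: Sequence[GenomeWindow],
    partition: Sequence[FeatureAnnotation],
    scaffold_scope: Mapping[str, str],
    taxonomy: FeatureTaxonomy | None = None,
    thresholds: ThresholdConfig | None = None,
) -> dict[str, CompositionResult]:
    """Composition tests genome-wide and per scope (e.g. autosomes vs X).

    ``scaffold_scope`` maps each scaffold to a scope label (``autosomes``,
    ``X``, ...). Backgrounds are scope-matched: each scope's expectation comes
    from the feature composition of its own scaffolds. Results are returned
    for ``genome`` plus every scope label present.
    """
    taxonomy = taxonomy or FeatureTaxonomy()
    thresholds = thresholds or ThresholdConfig()
    scopes: dict[str, set[str]] = {"genome": set(scaffold_scope)}
    for scaffold, scope in scaffold_scope.items():
        scopes.setdefault(scope, set()).add(scaffold)
    results: dict[str, CompositionResult] = {}
    for scope, scaffolds in scopes.items():
        if not scaffolds:
            raise ValueError(f"scope {scope!r} contains no scaffolds")
        part = [a for a in partition if a.scaffold in scaffolds]
        wins = [w for w in windows if w.scaffold in scaffolds]
        observed = enriched_feature_lengths(part, wins, thresholds, taxonomy)
        background = category_lengths(part, taxonomy)
        results[scope] = _composition_result(observed, background, taxonomy)
    return results
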