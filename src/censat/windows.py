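"""Windowed ChIP/input enrichment and centromere-window calling.

Mean ChIP and input coverage are computed in nonoverlapping fixed-width
windows (10 kb by default) across all scaffolds, normalized per million units
of library size, and summarized as log2(ChIP/input) with a small pseudocount.
Windows at or above the enrichment threshold (log2 ratio >= 2 by default) are
called centromere windows; a stricter threshold (>= 4, i.e. 16-fold) is used
downstream for feature-composition sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import CoverageTrack


@dataclass(frozen=True)
class ThresholdConfig:
    """Window size, enrichment thresholds, and the zero-guard pseudocount."""

    window_size: int = 10_000
    centromere_log2: float = 2.0
    feature_log2: float = 4.0
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (self.feature_log2 >= self.centromere_log2 >= 0):
            raise ValueError("need feature_log2 >= centromere_log2 >= 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass(frozen=True)
class GenomeWindow:
    """A fixed-width genomic window with normalized coverages and log2 ratio."""

    scaffold: str
    start: int
    end: int
    mean_chip: float
    mean_input: float
    log2_ratio: float
    is_centromere: bool


def log2_ratio(mean_chip: float, mean_input: float, pseudocount: float) -> float:
    """log2((chip + pseudocount) / (input + pseudocount)); 0 when both are 0."""
    if mean_chip < 0 or mean_input < 0:
        raise ValueError("coverage means must be >= 0")
    num, den = mean_chip + pseudocount, mean_input + pseudocount
    if num == 0 and den == 0:
        return 0.0
    return math.log2(num / den)


def tile_scaffold(length: int, window_size: int) -> list[tuple[int, int]]:
    """Nonoverlapping windows covering [0, length); the last may be short."""
    return [(s, min(s + window_size, length)) for s in range(0, length, window_size)]


def window_means(
    track: CoverageTrack,
    window_size: int,
    scaffold_lengths: Mapping[str, int],
) -> dict[str, np.ndarray]:
    """Per-window mean depth, normalized per million units of library size.

    Bases absent from the track count as depth 0; the mean over a window is
    the depth-length sum divided by the window width, then scaled by
    ``1e6 / library_size``.
    """
    scale = 1e6 / track.library_size
    out: dict[str, np.ndarray] = {}
    for scaffold, length in scaffold_lengths.items():
        n = -(-length // window_size)
        out[scaffold] = np.zeros(n)
    for scaffold, ivals in track.by_scaffold().items():
        if scaffold not in scaffold_lengths:
            raise ValueError(f"track scaffold {scaffold!r} not in scaffold_lengths")
        length = scaffold_lengths[scaffold]
        sums = out[scaffold]
        for start, end, depth in ivals:
            if end > length:
                raise ValueError(
                    f"interval [{start}, {end}) exceeds {scaffold} length {length}"
                )
            if depth == 0.0:
                continue
            w0, w1 = start // window_size, (end - 1) // window_size
            if w0 == w1:
                sums[w0] += depth * (end - start)
            else:
                sums[w0] += depth * ((w0 + 1) * window_size - start)
                if w1 > w0 + 1:
                    sums[w0 + 1 : w1] += depth * window_size
                sums[w1] += depth * (end - w1 * window_size)
    for scaffold, length in scaffold_lengths.items():
        widths = np.array(
            [e - s for s, e in tile_scaffold(length, window_size)], dtype=float
        )
        out[scaffold] = out[scaffold] / widths * scale
    return out


def compute_windows(
    chip: CoverageTrack,
    control: CoverageTrack,
    scaffold_lengths: Mapping[str, int],
    thresholds: ThresholdConfig | None = None,
) -> list[GenomeWindow]:
    """Tile every scaffold and attach normalized means and log2 ratios."""
    thresholds = thresholds or ThresholdConfig()
    chip_means = window_means(chip, thresholds.window_size, scaffold_lengths)
    input_means = window_means(control, thresholds.window_size, scaffold_lengths)
    windows: list[GenomeWindow] = []
    for scaffold in scaffold_lengths:
        tiles = tile_scaffold(scaffold_lengths[scaffold], thresholds.window_size)
        for i, (start, end) in enumerate(tiles):
            mc = float(chip_means[scaffold][i])
            mi = float(input_means[scaffold][i])
            ratio = log2_ratio(mc, mi, thresholds.pseudocount)
            windows.append(
                GenomeWindow(
                    scaffold, start, end, mc, mi, ratio,
                    is_centromere=ratio >= thresholds.centromere_log2,
                )
            )
    return windows


def call_centromere_windows(
    windows: Iterable[GenomeWindow], thresholds: ThresholdConfig | None = None
) -> list[GenomeWindow]:
    """Re-flag windows: ``is_centromere`` iff log2 ratio >= threshold (inclusive)."""
    thresholds = thresholds or ThresholdConfig()
    return [
        GenomeWindow(
            w.scaffold, w.start, w.end, w.mean_chip, w.mean_input, w.log2_ratio,
            is_centromere=w.log2_ratio >= thresholds.centromere_log2,
        )
        for w in windows
    ]


def windows_to_frame(windows: Sequence[GenomeWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (w.scaffold, w.start, w.end, w.mean_chip, w.mean_input,
             w.log2_ratio, w.is_centromere)
            for w in windows
        ],
        columns=[
            "scaffold", "start", "end", "mean_chip", "mean_input",
            "log2_ratio", "is_centromere",
        ],
    )


def classify_sex_linked(
    cov_male: Mapping[str, float],
    cov_female: Mapping[str, float],
    x_band: tuple[float, float] = (0.35, 0.65),
    autosome_band: tuple[float, float] = (0.85, 1.15),
) -> dict[str, str]:
    """Label scaffolds by the male:female normalized coverage ratio.

    In an XX/X0 system males carry one X, so X-linked scaffolds show about
    half the female coverage in males (ratio ~0.5) while autosomes sit near
    1. Scaffolds between the bands, or with zero female coverage, are
    ``ambiguous``.
    """
    labels: dict[str, str] = {}
    for scaffold in cov_male:
        if scaffold not in cov_female:
            raise ValueError(f"scaffold {scaffold!r} missing from female coverage")
        f = cov_female[scaffold]
        if f <= 0:
            labels[scaffold] = "ambiguous"
            continue
        ratio = cov_male[scaffold] / f
        if x_band[0] <= ratio <= x_band[1]:
            labels[scaffold] = "X-linked"
        elif autosome_band[0] <= ratio <= autosome_band[1]:
            labels[scaffold] = "autosomal"
        else:
            labels[scaffold] = "ambiguous"
    return labels


class CentromereWindowCaller(BaseEstimator):
    """Estimator wrapper around windowed enrichment and centromere calling.

    Parameters mirror :class:`ThresholdConfig`. After :meth:`fit`, the fitted
    attributes hold the tiled windows (``windows_``), the called subset
    (``centromere_windows_``), and a tidy frame (``frame_``).
    """

    def __init__(
        self,
        window_size: int = 10_000,
        centromere_log2: float = 2.0,
        feature_log2: float = 4.0,
        pseudocount: float = 0.01,
    ):
        self.window_size = window_size
        self.centromere_log2 = centromere_log2
        self.feature_log2 = feature_log2
        self.pseudocount = pseudocount

    def _thresholds(self) -> ThresholdConfig:
        return ThresholdConfig(
            window_size=self.window_size,
            centromere_log2=self.centromere_log2,
            feature_log2=self.feature_log2,
            pseudocount=self.pseudocount,
        )

    def fit(
        self,
        chip: CoverageTrack,
        control: CoverageTrack,
        scaffold_lengths: Mapping[str, int] | None = None,
    ) -> "CentromereWindowCaller":
        if not isinstance(chip, CoverageTrack) or not isinstance(control, CoverageTrack):
            raise TypeError("fit expects two CoverageTrack inputs")
        if scaffold_lengths is None:
            # fall back to the span covered by either track
            scaffold_lengths = {}
            for track in (chip, control):
                for scaffold, ivals in track.by_scaffold().items():
                    end = max(e for _, e, _ in ivals)
                    scaffold_lengths[scaffold] = max(
                        scaffold_lengths.get(scaffold, 0), end
                    )
        self.scaffold_lengths_ = dict(scaffold_lengths)
        self.windows_ = compute_windows(
            chip, control, self.scaffold_lengths_, self._thresholds()
        )
        self.centromere_windows_ = [w for w in self.windows_ if w.is_centromere]
        self.frame_ = windows_to_frame(self.windows_)
        return self
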