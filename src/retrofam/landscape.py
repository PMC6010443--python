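"""Chromosomal window densities and gene-proximity extraction.

Chromosomes are split into contiguous fixed-size windows (default 2 Mb); a
repeat element or gene is assigned to exactly one window by its start
coordinate, so an element straddling a boundary is counted once. The last
partial window is kept as its own bin. Tracks can be correlated (Spearman by
default) and written as bedGraph, the one place the package uses 0-based
half-open coordinates. Gene neighborhoods collect genes whose interval comes
within a symmetric flank (default 20 kb) of any member hit of a family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .model import GeneFeature, RepeatHit, SpeciesAnnotation

WINDOW_SIZE = 2_000_000
GENE_FLANK = 20_000

Feature = Union[RepeatHit, GeneFeature]


def assign_window(start: int, window_size: int = WINDOW_SIZE) -> int:
    """0-based window index of a 1-based start: floor((start-1)/window_size)."""
    if start < 1:
        raise ValueError(f"start must be >= 1, got {start}")
    if window_size < 1:
        raise ValueError("window_size must be positive")
    return (start - 1) // window_size


@dataclass(slots=True)
class WindowTrack:
    """Per-chromosome window count vectors for one feature set."""

    species: str
    feature_label: str
    window_size: int
    vectors: dict[str, np.ndarray]

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.vectors[c] for c in sorted(self.vectors)])

    def total(self) -> float:
        return float(sum(v.sum() for v in self.vectors.values()))


def density_track(
    features: Sequence[Feature],
    annotation: SpeciesAnnotation,
    label: str,
    window_size: int = WINDOW_SIZE,
    mode: str = "count",
) -> WindowTrack:
    """Window density track over all chromosomes of one species.

    ``mode='count'`` counts features per start window; ``mode='bp'`` adds
    each feature's full length to its start window instead. Features on
    chromosomes absent from the annotation raise.
    """
    if mode not in ("count", "bp"):
        raise ValueError(f"mode must be 'count' or 'bp', got {mode!r}")
    vectors = {
        name: np.zeros(math.ceil(length / window_size), dtype=np.int64)
        for name, length, _ in annotation.chromosomes
    }
    for feat in features:
        vec = vectors.get(feat.chromosome)
        if vec is None:
            raise ValueError(
                f"feature on unknown chromosome {feat.chromosome!r} "
                f"for {annotation.species}"
            )
        vec[assign_window(feat.start, window_size)] += (
            1 if mode == "count" else feat.length()
        )
    return WindowTrack(
        species=annotation.species,
        feature_label=label,
        window_size=window_size,
        vectors=vectors,
    )


def track_correlation(a: WindowTrack, b: WindowTrack, method: str = "spearman") -> float:
    """Correlation of two tracks over the concatenated window grid."""
    if a.species != b.species or a.window_size != b.window_size:
        raise ValueError("tracks are on different species or window grids")
    if sorted(a.vectors) != sorted(b.vectors) or any(
        len(a.vectors[c]) != len(b.vectors[c]) for c in a.vectors
    ):
        raise ValueError("tracks are on different chromosome grids")
    x = a.concatenated().astype(float)
    y = b.concatenated().astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")  # correlation undefined for a constant track
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def genes_near_family(
    family_hits: Sequence[RepeatHit],
    genes: Sequence[GeneFeature],
    flank: int = GENE_FLANK,
) -> set[str]:
    """Gene IDs whose interval intersects any hit extended by ``flank``.

    Distance is interval-to-interval gap, strand-blind; a gene overlapping a
    hit is at distance zero. Monotone in ``flank``.
    """
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chromosome, IntervalTree()).addi(
            g.start, g.end + 1, g.gene_id
        )
    found: set[str] = set()
    for h in family_hits:
        tree = trees.get(h.chromosome)
        if tree is None:
            continue
        lo = max(1, h.start - flank)
        for iv in tree.overlap(lo, h.end + flank + 1):
            found.add(iv.data)
    return found


def gene_neighborhood_gaps(
    family_hits: Sequence[RepeatHit],
    genes: Sequence[GeneFeature],
    flank: int = GENE_FLANK,
) -> dict[str, int]:
    """Minimum hit-to-gene gap (bp, 0 when overlapping) per neighboring gene."""
    gaps: dict[str, int] = {}
    by_chrom: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for h in family_hits:
        for g in by_chrom.get(h.chromosome, []):
            gap = max(0, g.start - h.end, h.start - g.end)
            if gap <= flank:
                if g.gene_id not in gaps or gap < gaps[g.gene_id]:
                    gaps[g.gene_id] = gap
    return gaps


def write_bedgraph(track: WindowTrack, annotation: SpeciesAnnotation, path: str | Path) -> None:
    """bedGraph output (0-based half-open); last window truncated to length."""
    lengths = {name: length for name, length, _ in annotation.chromosomes}
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{track.feature_label}" '
            f'description="{track.species}"\n'
        )
        for chrom in sorted(track.vectors):
            vec = track.vectors[chrom]
            for i, count in enumerate(vec):
                start0 = i * track.window_size
                end0 = min((i + 1) * track.window_size, lengths[chrom])
                fh.write(f"{chrom}\t{start0}\t{end0}\t{int(count)}\n")
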