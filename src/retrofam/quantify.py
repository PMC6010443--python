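"""Per-family, per-species quantification.

Covers overlap resolution between competing annotations (keep the longer
hit), copy-number and occupied-length summaries, genome fraction, and the
three-way copy-number classification (LOW 10-200, MID 201-800, HIGH >800
copies) used throughout the comparative analysis.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from intervaltree import IntervalTree

from .model import CopyClassSummary, FamilyRecord, FamilySummary, RepeatHit

COPY_CLASS_EDGES = (10, 200, 800)


def resolve_overlaps(
    hits: Sequence[RepeatHit], max_overlap_fraction: float = 0.0
) -> list[RepeatHit]:
    """Resolve competing annotations at one locus in favour of longer hits.

    Per chromosome, hits are considered longest-first (ties: smaller start,
    then smaller hit_id); a hit is retained iff its overlap with every
    already-retained hit is at most ``max_overlap_fraction`` of its own
    length. With the default 0.0, any shared base discards the shorter hit.
    Runs across families jointly, since RepeatMasker reports competing
    annotations of different families for one locus. Output is sorted by
    (chromosome, start).
    """
    by_chrom: dict[str, list[RepeatHit]] = defaultdict(list)
    for h in hits:
        by_chrom[h.chromosome].append(h)
    retained: list[RepeatHit] = []
    for chrom in sorted(by_chrom):
        tree = IntervalTree()
        for h in sorted(
            by_chrom[chrom], key=lambda h: (-h.length(), h.start, h.hit_id)
        ):
            budget = max_overlap_fraction * h.length()
            ok = True
            for iv in tree.overlap(h.start, h.end + 1):
                overlap = min(h.end + 1, iv.end) - max(h.start, iv.begin)
                if overlap > budget:
                    ok = False
                    break
            if ok:
                tree.addi(h.start, h.end + 1)
                retained.append(h)
    retained.sort(key=lambda h: (h.chromosome, h.start, h.end))
    return retained


def summarize_family(family: FamilyRecord, species: str) -> FamilySummary:
    """Copy number, total occupied bp and mean element length in one species."""
    members = family.members.get(species, [])
    copy_number = len(members)
    total_bp = sum(h.length() for h in members)
    mean_bp = total_bp / copy_number if copy_number else 0.0
    return FamilySummary(
        family_id=family.family_id,
        species=species,
        copy_number=copy_number,
        total_bp=total_bp,
        mean_bp=mean_bp,
    )


def genome_fraction(total_bp: float, genome_size: float) -> float:
    """Percent of the genome occupied, reported to two decimals."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return round(100.0 * total_bp / genome_size, 2)


def copy_class_of(copy_number: int, edges: Sequence[int] = COPY_CLASS_EDGES) -> str:
    """LOW for [edges[0], edges[1]], MID for (edges[1], edges[2]], HIGH above."""
    lo, mid, high = edges
    if copy_number < lo:
        raise ValueError(
            f"copy_number {copy_number} below the family floor {lo}; "
            "family filtering should have removed it"
        )
    if copy_number <= mid:
        return "LOW"
    if copy_number <= high:
        return "MID"
    return "HIGH"


def bin_by_copy_class(
    summaries: Sequence[FamilySummary], edges: Sequence[int] = COPY_CLASS_EDGES
) -> list[CopyClassSummary]:
    """Aggregate family summaries into the LOW/MID/HIGH copy-number classes.

    Per class: number of families, summed occupied bp, and the overall mean
    element length (summed bp over summed copies). Classes partition the
    input; all three are always reported, empty ones with zero counts.
    """
    acc: dict[str, list[float]] = {c: [0, 0, 0] for c in ("LOW", "MID", "HIGH")}
    for s in summaries:
        cls = copy_class_of(s.copy_number, edges)
        acc[cls][0] += 1
        acc[cls][1] += s.total_bp
        acc[cls][2] += s.copy_number
    out = []
    for cls in ("LOW", "MID", "HIGH"):
        n_fam, total_bp, total_copies = acc[cls]
        out.append(
            CopyClassSummary(
                copy_class=cls,
                family_count=int(n_fam),
                total_bp=int(total_bp),
                mean_element_bp=(total_bp / total_copies) if total_copies else 0.0,
            )
        )
    return out
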