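"""Consensus-library construction and family definition.

The family concept follows the standard 80%-identity convention for LTR
retrotransposons: library consensus sequences are clustered greedily at a
configurable identity threshold (default 0.8), deduplicated against a
reference library at the same threshold, and a *family* is then the set of
genomic copies annotated by one surviving consensus, subject to two filters:
elements must be longer than ``min_element_length`` (default 100 nt, strict)
and the family must retain at least ``min_copies`` members pooled across
species (default 10).

Identity semantics are CD-HIT-like: a global alignment with free end gaps
(match +1, mismatch -1, gap -2), both strands compared, and the number of
identically aligned bases divided by the length of the *shorter* sequence.
Among score-co-optimal alignments the one with the most identities is used,
which makes the statistic symmetric and reproducible.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Sequence

from Bio import Align
from Bio.Seq import Seq

from .model import ConsensusEntry, FamilyRecord, RepeatHit

# Tiny match bonus: breaks score ties in favour of alignments with more
# identical pairs without ever overturning a strict score ordering for
# sequences shorter than ~1e6 bases.
_MATCH_EPS = 1e-6

FULL_LENGTH_FRACTION = 0.5


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1 + _MATCH_EPS
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # end gaps are free so a short sequence can slide along a long one
    aligner.open_end_gap_score = 0
    aligner.extend_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identically aligned bases over the shorter sequence.

    Both orientations of ``b`` are tried and the better one is kept, so
    ``pairwise_identity(s, revcomp(s)) == 1.0``. Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    best = 0
    for other in (b, str(Seq(b).reverse_complement())):
        alignment = _ALIGNER.align(a, other)[0]
        identities = alignment.counts().identities
        if identities > best:
            best = identities
    return min(1.0, best / min(len(a), len(b)))


def _entry_order(entries: Sequence[ConsensusEntry]) -> list[ConsensusEntry]:
    return sorted(entries, key=lambda e: (-len(e.sequence), e.family_id))


def greedy_cluster(
    seqs: Sequence[ConsensusEntry], threshold: float = 0.8
) -> list[list[ConsensusEntry]]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are processed longest-first (ties broken by label); each joins
    the first cluster whose representative — its longest member, i.e. the
    founder — shows :func:`pairwise_identity` >= ``threshold``, otherwise it
    founds a new cluster. Clusters partition the input.
    """
    if not seqs:
        raise ValueError("greedy_cluster requires a non-empty input")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    clusters: list[list[ConsensusEntry]] = []
    for entry in _entry_order(seqs):
        for cluster in clusters:
            representative = cluster[0]
            if pairwise_identity(entry.sequence, representative.sequence) >= threshold:
                cluster.append(entry)
                break
        else:
            clusters.append([entry])
    return clusters


def build_consensus(cluster: Sequence[ConsensusEntry]) -> str:
    """Majority-vote consensus of a cluster in the representative's frame.

    Every member is aligned to the representative (the longest member, ties
    by label); per representative column the majority base over all aligned
    member bases (gaps abstain) wins, ties resolving to the representative's
    base. Columns where the representative is gapped are dropped, so the
    result has exactly the representative's length.
    """
    if not cluster:
        raise ValueError("build_consensus requires a non-empty cluster")
    ordered = _entry_order(cluster)
    representative = ordered[0]
    rep_seq = representative.sequence
    votes: list[Counter] = [Counter({base: 1}) for base in rep_seq]
    for member in ordered[1:]:
        alignment = _ALIGNER.align(rep_seq, member.sequence)[0]
        rep_row = alignment[0]
        mem_row = alignment[1]
        pos = 0
        for rep_char, mem_char in zip(rep_row, mem_row):
            if rep_char == "-":
                continue
            if mem_char != "-":
                votes[pos][mem_char] += 1
            pos += 1
    out = []
    for base, counter in zip(rep_seq, votes):
        top = counter.most_common()
        best_count = top[0][1]
        winners = {b for b, c in top if c == best_count}
        out.append(base if base in winners else top[0][0])
    return "".join(out)


def deduplicate_library(
    novel: Sequence[ConsensusEntry],
    reference: Sequence[ConsensusEntry],
    threshold: float = 0.8,
) -> list[ConsensusEntry]:
    """Drop novel consensi redundant with a reference library.

    Returns the reference entries plus every novel entry whose identity to
    *all* reference entries stays below ``threshold``.
    """
    kept = list(reference)
    for entry in novel:
        if all(
            pairwise_identity(entry.sequence, ref.sequence) < threshold
            for ref in reference
        ):
            kept.append(entry)
    return kept


def define_families(
    hits: Sequence[RepeatHit],
    library: Sequence[ConsensusEntry],
    min_copies: int = 10,
    min_element_length: int = 100,
) -> list[FamilyRecord]:
    """Group annotation hits into families with the standard filters.

    Hits with length() <= ``min_element_length`` are discarded first (the
    filter is strict: a 100-bp hit does not survive the default). Surviving
    hits are grouped by ``family_id`` across all species; groups with fewer
    than ``min_copies`` pooled members are dropped. Member lists are ordered
    by (species, chromosome, start) and families by family_id, so the result
    is independent of input order.
    """
    lib = {e.family_id: e for e in library}
    unknown = sorted({h.family_id for h in hits} - set(lib))
    if unknown:
        raise ValueError(
            f"hits reference {len(unknown)} unknown family_id(s): "
            + ", ".join(unknown[:10])
        )
    grouped: dict[str, list[RepeatHit]] = defaultdict(list)
    for h in hits:
        if h.length() > min_element_length:
            grouped[h.family_id].append(h)
    families: list[FamilyRecord] = []
    for family_id in sorted(grouped):
        members = grouped[family_id]
        if len(members) < min_copies:
            continue
        per_species: dict[str, list[RepeatHit]] = defaultdict(list)
        for h in members:
            per_species[h.species].append(h)
        for sp in per_species:
            per_species[sp].sort(key=lambda h: (h.chromosome, h.start, h.end))
        entry = lib[family_id]
        families.append(
            FamilyRecord(
                family_id=family_id,
                superfamily=entry.superfamily,
                consensus_length=len(entry.sequence),
                members={sp: per_species[sp] for sp in sorted(per_species)},
            )
        )
    return families


def classify_element_structure(
    hit: RepeatHit, consensus_length: int, full_fraction: float = FULL_LENGTH_FRACTION
) -> str:
    """Call a copy 'full' or 'remnant' by its length relative to the consensus.

    A copy covering at least ``full_fraction`` of the consensus length
    (default one half) is 'full'; shorter copies are 'remnant'. This is a
    coverage proxy for truncation by illegitimate recombination, not a
    structural LTR-boundary call.
    """
    if consensus_length <= 0:
        raise ValueError("consensus_length must be positive")
    return "remnant" if hit.length() / consensus_length < full_fraction else "full"
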