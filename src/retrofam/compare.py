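"""Cross-species family presence/absence algebra and subgenome distribution.

A family is *present* in a species when it retains at least
``presence_threshold`` surviving copies there (default 10, mirroring the
per-genome family filter). The presence matrix feeds the Venn partition —
for four species, the 15 nonempty subsets — and arbitrary present-in /
absent-in selections. For allotetraploids, per-family copy counts are split
between A- and D-labelled chromosomes to quantify subgenome insertion bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .model import FamilyRecord, SpeciesAnnotation, SubgenomePreference

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class PresenceMatrix:
    """Boolean family x species presence matrix (every row has >= 1 True)."""

    families: list[str]
    species: list[str]
    cells: list[list[bool]]
    dropped: int = 0  # families whose row was all-False

    def row(self, family_id: str) -> list[bool]:
        return self.cells[self.families.index(family_id)]

    def present_set(self, family_idx: int) -> frozenset[str]:
        return frozenset(
            sp for sp, flag in zip(self.species, self.cells[family_idx]) if flag
        )


@dataclass(slots=True)
class VennPartition:
    """Family counts for every nonempty subset of species."""

    species: list[str]
    region_counts: dict[frozenset[str], int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.region_counts.values())

    def count(self, subset: Iterable[str]) -> int:
        return self.region_counts[frozenset(subset)]


def presence_matrix(
    families: Sequence[FamilyRecord],
    species: Sequence[str],
    presence_threshold: int = 10,
) -> PresenceMatrix:
    """Build the presence matrix from per-species surviving copy counts.

    Families present (>= threshold copies) in none of the listed species are
    dropped and counted in ``dropped``. A family carrying members for a
    species not in ``species`` raises.
    """
    species = list(species)
    known = set(species)
    rows: list[list[bool]] = []
    names: list[str] = []
    dropped = 0
    for fam in families:
        extra = sorted(set(fam.members) - known)
        if extra:
            raise ValueError(
                f"family {fam.family_id} has members in unknown species {extra}"
            )
        row = [fam.copies_in(sp) >= presence_threshold for sp in species]
        if any(row):
            names.append(fam.family_id)
            rows.append(row)
        else:
            dropped += 1
    if dropped:
        logger.warning(
            "presence_matrix: dropped %d families below the presence "
            "threshold in every species",
            dropped,
        )
    return PresenceMatrix(families=names, species=species, cells=rows, dropped=dropped)


def venn_partition(m: PresenceMatrix) -> VennPartition:
    """Assign each family to its exact presence subset and count per region."""
    if not (2 <= len(m.species) <= 4):
        raise ValueError("venn_partition supports 2-4 species")
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(m.species) + 1):
        for combo in combinations(m.species, r):
            counts[frozenset(combo)] = 0
    for idx in range(len(m.families)):
        counts[m.present_set(idx)] += 1
    return VennPartition(species=list(m.species), region_counts=counts)


def select_families(
    m: PresenceMatrix,
    present_in: Iterable[str] = (),
    absent_in: Iterable[str] = (),
) -> set[str]:
    """Families present in all of ``present_in`` and none of ``absent_in``.

    Species named in neither set are unconstrained, so the result is in
    general a union of Venn regions.
    """
    present_in = set(present_in)
    absent_in = set(absent_in)
    if present_in & absent_in:
        raise ValueError(
            f"present_in and absent_in overlap: {sorted(present_in & absent_in)}"
        )
    unknown = (present_in | absent_in) - set(m.species)
    if unknown:
        raise ValueError(f"unknown species: {sorted(unknown)}")
    out: set[str] = set()
    for idx, family_id in enumerate(m.families):
        have = m.present_set(idx)
        if present_in <= have and not (absent_in & have):
            out.add(family_id)
    return out


def subgenome_distribution(
    family: FamilyRecord, annotation: SpeciesAnnotation
) -> SubgenomePreference:
    """Split one family's copies between A- and D-subgenome chromosomes.

    Copies on unlabelled scaffolds are excluded from both counts and
    reported as ``unplaced``. Requires a tetraploid annotation.
    """
    if annotation.ploidy != "tetraploid":
        raise ValueError(
            f"{annotation.species} is not annotated as tetraploid"
        )
    subg_of = {name: subg for name, _, subg in annotation.chromosomes}
    copies_a = copies_d = unplaced = 0
    for hit in family.members.get(annotation.species, []):
        subg = subg_of.get(hit.chromosome)
        if subg is None:
            raise ValueError(
                f"hit on unknown chromosome {hit.chromosome!r} "
                f"for species {annotation.species}"
            )
        if subg == "A":
            copies_a += 1
        elif subg == "D":
            copies_d += 1
        else:
            unplaced += 1
    return SubgenomePreference(
        family_id=family.family_id,
        copies_A=copies_a,
        copies_D=copies_d,
        unplaced=unplaced,
    )


def aggregate_subgenome(
    prefs: Iterable[SubgenomePreference],
) -> tuple[int, int]:
    """Total (A, D) copy counts over a set of families."""
    total_a = total_d = 0
    for p in prefs:
        total_a += p.copies_A
        total_d += p.copies_D
    return total_a, total_d
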