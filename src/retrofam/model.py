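"""Shared domain types for LTR-retrotransposon family analysis.

All genomic coordinates are 1-based inclusive, matching both the
RepeatMasker ``.out`` dialect and GFF3, so no conversion happens between
the two source formats. The only 0-based half-open coordinates in the
package appear in bedGraph track output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SUPERFAMILIES = ("Gypsy", "Copia", "Other", "Unknown")

#: Copy-number class labels, in ascending copy-number order.
COPY_CLASSES = ("LOW", "MID", "HIGH")


def classify_superfamily(class_family: str) -> str:
    """Map a RepeatMasker class/family string to a superfamily label.

    ``LTR/Gypsy*`` -> Gypsy, ``LTR/Copia*`` -> Copia, any other ``LTR/*``
    -> Other, everything else -> Unknown.
    """
    if class_family.startswith("LTR/Gypsy"):
        return "Gypsy"
    if class_family.startswith("LTR/Copia"):
        return "Copia"
    if class_family.startswith("LTR/"):
        return "Other"
    return "Unknown"


def superfamily_to_class(superfamily: str) -> str:
    """Inverse of :func:`classify_superfamily` (canonical spelling)."""
    if superfamily == "Gypsy":
        return "LTR/Gypsy"
    if superfamily == "Copia":
        return "LTR/Copia"
    if superfamily == "Other":
        return "LTR/Other"
    return "Unknown"


@dataclass(frozen=True, slots=True)
class RepeatHit:
    """One annotated repeat interval (one RepeatMasker ``.out`` row).

    ``strand`` is '-' exactly when the ``.out`` row carried the
    complement flag 'C'. ``hit_id`` is the RepeatMasker ID column and is
    not globally unique (RepeatMasker reuses IDs across files).
    """

    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    family_id: str
    superfamily: str = "Unknown"
    sw_score: int = 0
    pct_div: float = 0.0
    hit_id: int = 0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """Element-vs-consensus pairwise alignment from a ``.align`` file."""

    hit_id: int
    family_id: str
    aligned_element: str
    aligned_consensus: str

    def __post_init__(self) -> None:
        if len(self.aligned_element) != len(self.aligned_consensus):
            raise ValueError(
                f"alignment rows differ in length for hit {self.hit_id} "
                f"({len(self.aligned_element)} vs {len(self.aligned_consensus)})"
            )
        if len(self.aligned_element) == 0:
            raise ValueError(f"empty alignment for hit {self.hit_id}")


@dataclass(frozen=True, slots=True)
class GeneFeature:
    """A gene interval from a GFF3 annotation."""

    chromosome: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(slots=True)
class SpeciesAnnotation:
    """Chromosome-level description of one species' assembly.

    ``chromosomes`` holds (name, length bp, subgenome) triples where
    subgenome is 'A', 'D' or 'none'. ``genome_size`` defaults to the sum
    of chromosome lengths but may exceed it when unplaced scaffolds are
    omitted from the manifest.
    """

    species: str
    chromosomes: list[tuple[str, int, str]]
    genome_size: int = 0
    ploidy: str = ""

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.species}: duplicate chromosome names")
        if not self.genome_size:
            self.genome_size = sum(c[1] for c in self.chromosomes)
        if self.genome_size <= 0:
            raise ValueError(f"{self.species}: genome_size must be > 0")
        if not self.ploidy:
            subg = {c[2] for c in self.chromosomes}
            self.ploidy = "tetraploid" if {"A", "D"} <= subg else "diploid"
        if self.ploidy not in ("diploid", "tetraploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")

    def chromosome_length(self, name: str) -> int:
        for cname, length, _ in self.chromosomes:
            if cname == name:
                return length
        raise KeyError(f"{self.species}: unknown chromosome {name!r}")

    def subgenome_of(self, name: str) -> str:
        for cname, _, subg in self.chromosomes:
            if cname == name:
                return subg
        raise KeyError(f"{self.species}: unknown chromosome {name!r}")

    def chromosome_names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]


@dataclass(frozen=True, slots=True)
class ConsensusEntry:
    """One consensus sequence of the repeat library."""

    family_id: str
    superfamily: str
    sequence: str
    source: str = "de_novo"  # or "reference"

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"{self.family_id}: empty consensus sequence")


@dataclass(slots=True)
class FamilyRecord:
    """A named consensus plus its member hits across species.

    A family is the set of genomic copies annotated by the same library
    consensus; construction enforces the >100 nt element filter and the
    pooled >=10-copy rule (see :mod:`retrofam.families`).
    """

    family_id: str
    superfamily: str
    consensus_length: int
    members: dict[str, list[RepeatHit]] = field(default_factory=dict)

    def copies_in(self, species: str) -> int:
        return len(self.members.get(species, []))

    def total_copies(self) -> int:
        return sum(len(v) for v in self.members.values())

    def all_members(self) -> list[RepeatHit]:
        out: list[RepeatHit] = []
        for sp in sorted(self.members):
            out.extend(self.members[sp])
        return out


@dataclass(frozen=True, slots=True)
class FamilySummary:
    """Per-family, per-species copy number and occupied length."""

    family_id: str
    species: str
    copy_number: int
    total_bp: int
    mean_bp: float


@dataclass(frozen=True, slots=True)
class CopyClassSummary:
    """Aggregate over all families of one copy-number class."""

    copy_class: str  # LOW / MID / HIGH
    family_count: int
    total_bp: int
    mean_element_bp: float


@dataclass(frozen=True, slots=True)
class SubgenomePreference:
    """A/D-subgenome copy counts of one family in a tetraploid."""

    family_id: str
    copies_A: int
    copies_D: int
    unplaced: int = 0

    @property
    def preference_A(self) -> float | None:
        """Fraction of placed copies on A chromosomes; None if no placed copy."""
        total = self.copies_A + self.copies_D
        if total == 0:
            return None
        return self.copies_A / total
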