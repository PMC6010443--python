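"""Readers and writers for the external file formats.

Handles RepeatMasker ``.out`` hit tables (read/write), RepeatMasker-style
``.align`` pairwise-alignment files (read/write), GFF3 gene annotations,
repeat-library FASTA with ``name#LTR/Gypsy`` headers, genome FASTA, and the
4-column chromosome manifest TSV (species, chromosome, length, subgenome).

Parsing is strict: rows with the wrong column count raise :class:`ParseError`
naming the offending line, and alignment blocks whose two rows reconstruct to
different lengths raise naming the block. Rows are never reordered.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignmentRecord,
    ConsensusEntry,
    GeneFeature,
    RepeatHit,
    SpeciesAnnotation,
    classify_superfamily,
    superfamily_to_class,
)


class ParseError(ValueError):
    """Raised on malformed input files; message carries file position."""


_OUT_HEADER = (
    "   SW   perc perc perc  query       position in query         matching"
    "        repeat             position in repeat\n"
    "score   div. del. ins.  sequence    begin  end      (left)    repeat"
    "          class/family       begin  end  (left)    ID\n"
    "\n"
)

# Sequence characters accepted verbatim; anything else becomes 'N'.
_SEQ_CLEAN = re.compile(r"[^ACGTN-]")


def _clean_seq(s: str) -> str:
    return _SEQ_CLEAN.sub("N", s.upper())


# ---------------------------------------------------------------------------
# RepeatMasker .out


def read_repeatmasker_out(path: str | Path, species: str) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` hit table into :class:`RepeatHit` rows.

    Expects the modern layout: three header lines, then whitespace-delimited
    rows of 15 columns (16 with the trailing ``*`` overlap marker):
    score, %div, %del, %ins, query, qbegin, qend, (left), C/+, repeat,
    class/family, rbegin, rend, (left), ID. Orientation 'C' maps to
    strand '-'. Rows are returned in file order.
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3:
                continue  # fixed 3-line header
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            if len(fields) not in (15, 16):
                raise ParseError(
                    f"{path}: line {lineno}: expected 15 or 16 columns, "
                    f"got {len(fields)}"
                )
            try:
                sw_score = int(fields[0])
                pct_div = float(fields[1])
                qbegin = int(fields[5])
                qend = int(fields[6])
                hit_id = int(fields[14])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if qbegin > qend:
                raise ParseError(
                    f"{path}: line {lineno}: query begin {qbegin} > end {qend}"
                )
            orientation = fields[8]
            if orientation not in ("+", "C"):
                raise ParseError(
                    f"{path}: line {lineno}: orientation must be '+' or 'C', "
                    f"got {orientation!r}"
                )
            hits.append(
                RepeatHit(
                    species=species,
                    chromosome=fields[4],
                    start=qbegin,
                    end=qend,
                    strand="-" if orientation == "C" else "+",
                    family_id=fields[9],
                    superfamily=classify_superfamily(fields[10]),
                    sw_score=sw_score,
                    pct_div=pct_div,
                    hit_id=hit_id,
                )
            )
    return hits


def write_repeatmasker_out(hits: Iterable[RepeatHit], path: str | Path) -> None:
    """Serialize hits back to the ``.out`` layout (round-trips all typed fields)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for h in hits:
            orientation = "C" if h.strand == "-" else "+"
            fh.write(
                f"{h.sw_score:>5d} {h.pct_div:5.1f}  0.0  0.0  "
                f"{h.chromosome:<12s} {h.start:>9d} {h.end:>9d} (0)  "
                f"{orientation}  {h.family_id:<16s} "
                f"{superfamily_to_class(h.superfamily):<16s} "
                f"1 {h.length():d} (0) {h.hit_id:d}\n"
            )


# ---------------------------------------------------------------------------
# RepeatMasker .align
#
# Dialect written by this package (and accepted by the reader): one block per
# hit, a header line starting in column 0 with the score, e.g.
#
#   312 12.50 0.00 0.00 chrA01 1200 1699 (0) + RLGy_0001 1 500 (0) 7
#
# followed by interleaved, two-space-indented sequence lines alternating
# query (element) and consensus:
#
#     chrA01          1200 ACGT...TTGA 1259
#     RLGy_0001          1 ACGT...TTGA   60
#
# Segments are concatenated per block; Kimura values RepeatMasker appends to
# its own .align files are ignored here — divergence is always recomputed.

_ALIGN_HEADER_RE = re.compile(r"^\d")


def read_repeatmasker_align(path: str | Path) -> list[AlignmentRecord]:
    """Parse a ``.align`` file into :class:`AlignmentRecord` objects.

    Sequence lines are uppercased; any character outside ``ACGTN-`` becomes
    'N'. Blocks whose query and consensus rows reconstruct to different
    lengths raise :class:`ParseError` identifying the block.
    """
    records: list[AlignmentRecord] = []
    cur: dict | None = None
    seq_line_idx = 0

    def flush(block_start: int) -> None:
        nonlocal cur
        if cur is None:
            return
        q = "".join(cur["query"])
        c = "".join(cur["cons"])
        if not q or not c:
            raise ParseError(
                f"{path}: block at line {block_start}: missing sequence lines"
            )
        if len(q) != len(c):
            raise ParseError(
                f"{path}: block at line {block_start} (hit {cur['hit_id']}): "
                f"row lengths differ ({len(q)} vs {len(c)})"
            )
        records.append(
            AlignmentRecord(
                hit_id=cur["hit_id"],
                family_id=cur["family_id"],
                aligned_element=q,
                aligned_consensus=c,
            )
        )
        cur = None

    block_start = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _ALIGN_HEADER_RE.match(line):
                flush(block_start)
                fields = line.split()
                if len(fields) < 14:
                    raise ParseError(
                        f"{path}: line {lineno}: malformed block header"
                    )
                try:
                    hit_id = int(fields[13])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-integer hit ID"
                    ) from None
                cur = {
                    "hit_id": hit_id,
                    "family_id": fields[9],
                    "query": [],
                    "cons": [],
                }
                seq_line_idx = 0
                block_start = lineno
            elif line.startswith("  ") and cur is not None:
                fields = line.split()
                if len(fields) != 4:
                    continue  # matrix/annotation lines are ignored
                seq = _clean_seq(fields[2])
                if seq_line_idx % 2 == 0:
                    cur["query"].append(seq)
                else:
                    cur["cons"].append(seq)
                seq_line_idx += 1
    flush(block_start)
    return records


def write_repeatmasker_align(
    records: Iterable[AlignmentRecord],
    path: str | Path,
    *,
    chromosome_of: dict[int, str] | None = None,
    wrap: int = 60,
) -> None:
    """Write alignment records in the block dialect read back by this module."""
    chromosome_of = chromosome_of or {}
    with open(path, "w") as fh:
        for rec in records:
            chrom = chromosome_of.get(rec.hit_id, "query")
            n = len(rec.aligned_element)
            fh.write(
                f"100 0.00 0.00 0.00 {chrom} 1 {n} (0) + "
                f"{rec.family_id} 1 {n} (0) {rec.hit_id}\n\n"
            )
            for off in range(0, n, wrap):
                q = rec.aligned_element[off : off + wrap]
                c = rec.aligned_consensus[off : off + wrap]
                fh.write(f"  {chrom:<20s} {off + 1:>8d} {q} {off + len(q)}\n")
                fh.write(
                    f"  {rec.family_id:<20s} {off + 1:>8d} {c} {off + len(c)}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_genes(path: str | Path) -> list[GeneFeature]:
    """Extract ``gene`` features from a GFF3 file.

    Coordinates stay 1-based inclusive as written. A missing ``ID``
    attribute falls back to ``chrom:start-end``.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
        )
    except Exception as exc:  # malformed columns surface as one error type
        raise ParseError(f"{path}: not parseable as GFF3: {exc}") from exc
    genes: list[GeneFeature] = []
    for feat in db.features_of_type("gene", order_by=None):
        gene_id = feat.attributes.get("ID", [None])[0]
        if not gene_id:
            gene_id = f"{feat.seqid}:{feat.start}-{feat.end}"
        strand = feat.strand if feat.strand in ("+", "-") else "."
        genes.append(
            GeneFeature(
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=strand,
                gene_id=gene_id,
            )
        )
    return genes


def write_gff3_genes(genes: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tretrofam\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_library_fasta(path: str | Path, source: str = "de_novo") -> list[ConsensusEntry]:
    """Read a repeat library FASTA; superfamily is encoded after '#' in headers
    (``RLGy_0001#LTR/Gypsy``); headers without '#' map to Unknown."""
    entries: list[ConsensusEntry] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, classfam = rec.id.partition("#")
        entries.append(
            ConsensusEntry(
                family_id=name,
                superfamily=classify_superfamily(classfam) if classfam else "Unknown",
                sequence=_clean_seq(str(rec.seq)),
                source=source,
            )
        )
    return entries


def write_library_fasta(entries: Iterable[ConsensusEntry], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(e.sequence),
            id=f"{e.family_id}#{superfamily_to_class(e.superfamily)}",
            description="",
        )
        for e in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a chromosome -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(chromosomes: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Chromosome manifest


def read_manifest(path: str | Path) -> dict[str, SpeciesAnnotation]:
    """Read the 4-column manifest TSV (species, chromosome, length, subgenome)."""
    per_species: dict[str, list[tuple[str, int, str]]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].startswith("#") or row[0] == "species":
                continue
            if len(row) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(row)}"
                )
            species, chrom, length, subg = row
            if subg not in ("A", "D", "none"):
                raise ParseError(
                    f"{path}: line {lineno}: subgenome must be A, D or none"
                )
            per_species.setdefault(species, []).append((chrom, int(length), subg))
    return {
        sp: SpeciesAnnotation(species=sp, chromosomes=chroms)
        for sp, chroms in per_species.items()
    }


def write_manifest(annotations: Iterable[SpeciesAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tchromosome\tlength\tsubgenome\n")
        for ann in annotations:
            for chrom, length, subg in ann.chromosomes:
                fh.write(f"{ann.species}\t{chrom}\t{length}\t{subg}\n")
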