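"""Synthetic multi-species genomes with known LTR-retrotransposon content.

The simulator emulates the statistical structure the comparative analysis
assumes, so every pipeline stage can run — and be checked against ground
truth — without any real assembly:

* several species share one consensus library; per-family copy numbers are
  configured per species and may span orders of magnitude;
* per-copy divergence from the consensus is drawn from a configurable age
  distribution — by default the mixture 0.8*N(28, 6) + 0.2*N(2, 1) in K
  percent units, truncated to [0, 55], i.e. an old main peak near K = 28
  plus a small recent burst below K = 3;
* about three quarters of copies (``remnant_prob`` = 0.75) are truncated
  "remnant" fragments covering 10-50% of the consensus;
* in tetraploids, insertions fall on A- vs D-subgenome chromosomes with a
  configurable bias.

Divergence is introduced by an inverse Kimura-2-parameter model: for a
target K and transition/transversion ratio kappa, the per-site transition
and transversion probabilities (P = kappa*Q) solving K(P, Q) = target are
applied site-wise, so the expected estimated K equals the target.
Alignments are emitted gap-free (substitution-only), which keeps K recovery
exactly testable; elements are planted non-overlapping so copy numbers
round-trip exactly through the pipeline.

All randomness flows from one integer seed through per-purpose
``numpy`` generators in documented draw order, so a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from intervaltree import IntervalTree
from scipy.optimize import brentq

from . import rm_io
from .model import (
    AlignmentRecord,
    ConsensusEntry,
    GeneFeature,
    RepeatHit,
    SpeciesAnnotation,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def _to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Configuration


@dataclass(slots=True)
class AgeComponent:
    weight: float
    mean: float
    sd: float


#: Default element-age mixture (K percent units): old main peak at 28 plus
#: a small recent burst, truncated to [0, 55].
DEFAULT_AGE_COMPONENTS = (
    AgeComponent(weight=0.8, mean=28.0, sd=6.0),
    AgeComponent(weight=0.2, mean=2.0, sd=1.0),
)
DEFAULT_AGE_TRUNCATION = (0.0, 55.0)


@dataclass(slots=True)
class AgeMixture:
    components: tuple[AgeComponent, ...] = DEFAULT_AGE_COMPONENTS
    truncation: tuple[float, float] = DEFAULT_AGE_TRUNCATION

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.components)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"mixture weights sum to {total}, expected 1")

    def draw(self, rng: np.random.Generator) -> float:
        weights = [c.weight for c in self.components]
        lo, hi = self.truncation
        for _ in range(1000):
            comp = self.components[rng.choice(len(self.components), p=weights)]
            k = rng.normal(comp.mean, comp.sd)
            if lo <= k <= hi:
                return float(k)
        return float(min(max(lo, k), hi))


@dataclass(slots=True)
class ChromosomePlan:
    name: str
    length: int
    subgenome: str = "none"


@dataclass(slots=True)
class SpeciesPlan:
    name: str
    chromosomes: list[ChromosomePlan]

    @property
    def ploidy(self) -> str:
        subg = {c.subgenome for c in self.chromosomes}
        return "tetraploid" if {"A", "D"} <= subg else "diploid"


@dataclass(slots=True)
class FamilyPlan:
    family_id: str
    consensus_length: int
    copies: dict[str, int]
    superfamily: str = "Gypsy"
    age: AgeMixture = field(default_factory=AgeMixture)
    remnant_prob: float = 0.75
    min_remnant_fraction: float = 0.1
    subgenome_bias: float = 0.5  # P(insert on an A chromosome) in tetraploids


@dataclass(slots=True)
class GenePlan:
    per_chromosome: int = 20
    mean_length: int = 3000
    sd_length: int = 800


@dataclass(slots=True)
class SimulationConfig:
    seed: int
    species: list[SpeciesPlan]
    families: list[FamilyPlan]
    genes: GenePlan = field(default_factory=GenePlan)
    kappa: float = 2.0  # transition/transversion ratio P/Q

    def species_plan(self, name: str) -> SpeciesPlan:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(f"unknown species {name!r}")

    # -- (de)serialisation ---------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        species = [
            SpeciesPlan(
                name=sp["name"],
                chromosomes=[
                    ChromosomePlan(
                        name=c["name"],
                        length=int(c["length"]),
                        subgenome=c.get("subgenome", "none"),
                    )
                    for c in sp["chromosomes"]
                ],
            )
            for sp in data["species"]
        ]
        families = []
        for fam in data["families"]:
            age_spec = fam.get("age")
            if age_spec is None:
                age = AgeMixture()
            else:
                age = AgeMixture(
                    components=tuple(
                        AgeComponent(c["weight"], c["mean"], c["sd"])
                        for c in age_spec["components"]
                    ),
                    truncation=tuple(
                        age_spec.get("truncation", DEFAULT_AGE_TRUNCATION)
                    ),
                )
            families.append(
                FamilyPlan(
                    family_id=fam["family_id"],
                    consensus_length=int(fam["consensus_length"]),
                    copies={k: int(v) for k, v in fam["copies"].items()},
                    superfamily=fam.get("superfamily", "Gypsy"),
                    age=age,
                    remnant_prob=float(fam.get("remnant_prob", 0.75)),
                    min_remnant_fraction=float(fam.get("min_remnant_fraction", 0.1)),
                    subgenome_bias=float(fam.get("subgenome_bias", 0.5)),
                )
            )
        genes_spec = data.get("genes", {})
        return cls(
            seed=int(data["seed"]),
            species=species,
            families=families,
            genes=GenePlan(
                per_chromosome=int(genes_spec.get("per_chromosome", 20)),
                mean_length=int(genes_spec.get("mean_length", 3000)),
                sd_length=int(genes_spec.get("sd_length", 800)),
            ),
            kappa=float(data.get("kappa", 2.0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Core generative operations


def solve_k2p_rates(target_k: float, kappa: float) -> tuple[float, float]:
    """Per-site (P, Q) with P = kappa*Q such that K2P(P, Q) = target_k.

    ``target_k`` is in percent units. Raises for negative targets,
    non-positive kappa, or targets outside the non-saturated domain.
    """
    if target_k < 0:
        raise ValueError("target K must be nonnegative")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if target_k == 0:
        return 0.0, 0.0

    def k_of_q(q: float) -> float:
        w1 = 1.0 - 2.0 * kappa * q - q
        w2 = 1.0 - 2.0 * q
        return -50.0 * math.log(w1 * math.sqrt(w2))

    q_max = min(1.0 / (2.0 * kappa + 1.0), 0.5) - 1e-9
    hi = q_max
    if k_of_q(hi) < target_k:
        raise ValueError(f"target K={target_k} infeasible for kappa={kappa}")
    q = float(brentq(lambda x: k_of_q(x) - target_k, 1e-15, hi, xtol=1e-15))
    return kappa * q, q


def mutate_k2p(
    seq: str, target_k: float, kappa: float, rng: np.random.Generator
) -> str:
    """Substitute bases so the expected estimated K equals ``target_k``.

    Each site independently receives a transition with probability P and a
    transversion (either partner, equiprobable) with probability Q, where
    (P, Q) solve the K2P closed form for the target. Non-ACGT characters
    are left untouched.
    """
    p, q = solve_k2p_rates(target_k, kappa)
    codes = _to_codes(seq).copy()
    valid = codes >= 0
    u = rng.random(len(codes))
    transition = valid & (u < p)
    transversion = valid & (u >= p) & (u < p + q)
    # A<->G and C<->T are XOR 2 in the ACGT=0123 encoding
    codes[transition] ^= 2
    tv_bits = rng.integers(0, 2, size=len(codes)) * 2 + 1  # 1 or 3
    codes[transversion] ^= tv_bits[transversion].astype(np.int8)
    out = _to_codes(seq).copy()
    out[valid] = codes[valid]
    chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    chars[valid] = _BASES[out[valid]]
    return chars.tobytes().decode("ascii")


def fragment_element(
    consensus: str,
    remnant_prob: float,
    min_fraction: float,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Return (element sequence, 0-based consensus offset).

    With probability ``remnant_prob``, a uniformly placed contiguous slice
    covering U(min_fraction, 0.5) of the consensus; otherwise the full
    consensus at offset 0.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must be in (0, 1]")
    n = len(consensus)
    if rng.random() < remnant_prob:
        frac = rng.uniform(min_fraction, 0.5)
        length = max(1, int(round(frac * n)))
        offset = int(rng.integers(0, n - length + 1))
        return consensus[offset : offset + length], offset
    return consensus, 0


def random_consensus(length: int, rng: np.random.Generator) -> str:
    return _to_str(rng.integers(0, 4, size=length).astype(np.int8))


def consensus_library(cfg: SimulationConfig) -> list[ConsensusEntry]:
    """The shared consensus library, deterministic in the config seed."""
    rng = np.random.default_rng([cfg.seed, 900_001])
    return [
        ConsensusEntry(
            family_id=fam.family_id,
            superfamily=fam.superfamily,
            sequence=random_consensus(fam.consensus_length, rng),
        )
        for fam in cfg.families
    ]


# ---------------------------------------------------------------------------
# Whole-species simulation


@dataclass(slots=True)
class GroundTruthRow:
    species: str
    hit_id: int
    family_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    subgenome: str
    true_k: float
    remnant: bool
    consensus_offset: int


@dataclass(slots=True)
class SimulatedSpecies:
    annotation: SpeciesAnnotation
    chromosomes: dict[str, str]
    hits: list[RepeatHit]
    alignments: list[AlignmentRecord]
    genes: list[GeneFeature]
    ground_truth: list[GroundTruthRow]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        sp = self.annotation.species
        rm_io.write_genome_fasta(self.chromosomes, outdir / f"{sp}.fa")
        rm_io.write_repeatmasker_out(self.hits, outdir / f"{sp}.out")
        rm_io.write_repeatmasker_align(
            self.alignments,
            outdir / f"{sp}.align",
            chromosome_of={h.hit_id: h.chromosome for h in self.hits},
        )
        rm_io.write_gff3_genes(self.genes, outdir / f"{sp}.gff3")


@dataclass(slots=True)
class SimulatedDataset:
    config: SimulationConfig
    library: list[ConsensusEntry]
    species: dict[str, SimulatedSpecies]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rm_io.write_library_fasta(self.library, outdir / "library.fa")
        rm_io.write_manifest(
            [s.annotation for s in self.species.values()], outdir / "manifest.tsv"
        )
        with open(outdir / "ground_truth.tsv", "w") as fh:
            fh.write(
                "species\thit_id\tfamily_id\tchromosome\tstart\tend\tstrand\t"
                "subgenome\ttrue_k\tremnant\tconsensus_offset\n"
            )
            for sim in self.species.values():
                for row in sim.ground_truth:
                    fh.write(
                        f"{row.species}\t{row.hit_id}\t{row.family_id}\t"
                        f"{row.chromosome}\t{row.start}\t{row.end}\t{row.strand}\t"
                        f"{row.subgenome}\t{row.true_k:.4f}\t"
                        f"{int(row.remnant)}\t{row.consensus_offset}\n"
                    )
        for sim in self.species.values():
            sim.write(outdir)


def _choose_chromosome(
    chroms: Sequence[ChromosomePlan], rng: np.random.Generator
) -> ChromosomePlan:
    lengths = np.array([c.length for c in chroms], dtype=float)
    return chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]


def _place(
    occupied: IntervalTree,
    chrom_length: int,
    elem_length: int,
    rng: np.random.Generator,
    tries: int = 500,
) -> int | None:
    """Uniform non-overlapping 0-based start by rejection sampling."""
    if elem_length > chrom_length:
        return None
    for _ in range(tries):
        start0 = int(rng.integers(0, chrom_length - elem_length + 1))
        if not occupied.overlap(start0, start0 + elem_length):
            return start0
    return None


def simulate_species(
    cfg: SimulationConfig,
    species: str,
    library: list[ConsensusEntry] | None = None,
) -> SimulatedSpecies:
    """Simulate one species' genome, annotation and alignments.

    Draw order per copy is fixed (subgenome, chromosome, age, fragmentation,
    mutation, strand, placement) so output is deterministic in the config
    seed. Raises when requested copies cannot be placed without overlap —
    enlarge the chromosomes in that case.
    """
    plan = cfg.species_plan(species)
    sp_index = [s.name for s in cfg.species].index(species)
    rng = np.random.default_rng([cfg.seed, 1 + sp_index])
    library = library if library is not None else consensus_library(cfg)
    consensi = {e.family_id: e for e in library}

    annotation = SpeciesAnnotation(
        species=species,
        chromosomes=[(c.name, c.length, c.subgenome) for c in plan.chromosomes],
    )
    arrays = {
        c.name: rng.integers(0, 4, size=c.length).astype(np.int8)
        for c in plan.chromosomes
    }
    occupied = {c.name: IntervalTree() for c in plan.chromosomes}
    a_chroms = [c for c in plan.chromosomes if c.subgenome == "A"]
    d_chroms = [c for c in plan.chromosomes if c.subgenome == "D"]
    tetraploid = plan.ploidy == "tetraploid"

    hits: list[RepeatHit] = []
    alignments: list[AlignmentRecord] = []
    truth: list[GroundTruthRow] = []
    hit_id = 0
    for fam in cfg.families:
        n_copies = fam.copies.get(species, 0)
        consensus = consensi[fam.family_id].sequence
        for _ in range(n_copies):
            if tetraploid and a_chroms and d_chroms:
                pool = a_chroms if rng.random() < fam.subgenome_bias else d_chroms
            else:
                pool = plan.chromosomes
            chrom = _choose_chromosome(pool, rng)
            target_k = fam.age.draw(rng)
            element, offset = fragment_element(
                consensus, fam.remnant_prob, fam.min_remnant_fraction, rng
            )
            mutated = mutate_k2p(element, target_k, cfg.kappa, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            start0 = _place(occupied[chrom.name], chrom.length, len(mutated), rng)
            if start0 is None:
                raise ValueError(
                    f"{species}/{chrom.name}: could not place a "
                    f"{len(mutated)} bp copy of {fam.family_id} without "
                    "overlap; increase chromosome lengths or reduce copies"
                )
            codes = _to_codes(mutated)
            if strand == "-":
                genomic = _COMPLEMENT[codes][::-1]
            else:
                genomic = codes
            arrays[chrom.name][start0 : start0 + len(mutated)] = genomic
            occupied[chrom.name].addi(start0, start0 + len(mutated))
            hit_id += 1
            cons_slice = consensus[offset : offset + len(mutated)]
            mismatches = int(
                (_to_codes(mutated) != _to_codes(cons_slice)).sum()
            )
            pct_div = 100.0 * mismatches / len(mutated)
            hits.append(
                RepeatHit(
                    species=species,
                    chromosome=chrom.name,
                    start=start0 + 1,
                    end=start0 + len(mutated),
                    strand=strand,
                    family_id=fam.family_id,
                    superfamily=fam.superfamily,
                    sw_score=max(1, len(mutated) - 2 * mismatches),
                    pct_div=round(pct_div, 1),
                    hit_id=hit_id,
                )
            )
            alignments.append(
                AlignmentRecord(
                    hit_id=hit_id,
                    family_id=fam.family_id,
                    aligned_element=mutated,
                    aligned_consensus=cons_slice,
                )
            )
            truth.append(
                GroundTruthRow(
                    species=species,
                    hit_id=hit_id,
                    family_id=fam.family_id,
                    chromosome=chrom.name,
                    start=start0 + 1,
                    end=start0 + len(mutated),
                    strand=strand,
                    subgenome=chrom.subgenome,
                    true_k=target_k,
                    remnant=len(mutated) < len(consensus),
                    consensus_offset=offset,
                )
            )

    genes: list[GeneFeature] = []
    gene_no = 0
    for chrom in plan.chromosomes:
        for _ in range(cfg.genes.per_chromosome):
            length = max(
                200, int(round(rng.normal(cfg.genes.mean_length, cfg.genes.sd_length)))
            )
            start0 = _place(occupied[chrom.name], chrom.length, length, rng)
            if start0 is None:
                continue  # crowded chromosome: emit fewer genes
            occupied[chrom.name].addi(start0, start0 + length)
            gene_no += 1
            genes.append(
                GeneFeature(
                    chromosome=chrom.name,
                    start=start0 + 1,
                    end=start0 + length,
                    strand="+" if rng.random() < 0.5 else "-",
                    gene_id=f"{species}_g{gene_no:05d}",
                )
            )

    return SimulatedSpecies(
        annotation=annotation,
        chromosomes={name: _to_str(arr) for name, arr in arrays.items()},
        hits=hits,
        alignments=alignments,
        genes=genes,
        ground_truth=truth,
    )


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Simulate every configured species against the shared library."""
    library = consensus_library(cfg)
    species = {
        sp.name: simulate_species(cfg, sp.name, library) for sp in cfg.species
    }
    return SimulatedDataset(config=cfg, library=library, species=species)


# ---------------------------------------------------------------------------
# Packaged validation scenario


def demo_config(seed: int = 1) -> SimulationConfig:
    """The packaged four-species validation scenario.

    Two diploids and two tetraploids share a 21-family library covering the
    structure the comparative analysis cares about: families shared by all
    four species across the three copy-number classes (LOW 10-200, MID
    201-800, HIGH >800), species-specific families, families absent from
    exactly one species, a tetraploid-only family, one strongly A-biased
    high-copy family (bias 0.95) and one D-biased family. Most families
    age by the pure old peak N(28, 6); the species-specific families carry
    the default recent-burst mixture, mirroring how young amplifications
    are confined to particular genomes. Consensus length 2 kb with remnant
    slices of at least 12% keeps every emitted copy above the 100-nt
    element filter, so configured copy numbers survive the pipeline
    exactly.
    """
    old = AgeMixture(components=(AgeComponent(1.0, 28.0, 6.0),))
    bursty = AgeMixture()  # default 0.8*N(28,6) + 0.2*N(2,1)
    diploid = lambda name, prefix: SpeciesPlan(
        name,
        [ChromosomePlan(f"{prefix}{i}", 3_600_000) for i in (1, 2, 3)],
    )
    tetraploid = lambda name: SpeciesPlan(
        name,
        [ChromosomePlan(f"A{i}", 3_000_000, "A") for i in (1, 2, 3)]
        + [ChromosomePlan(f"D{i}", 3_000_000, "D") for i in (1, 2, 3)],
    )
    every = lambda n: {"dipA": n, "dipD": n, "tetX": n, "tetY": n}

    def fam(fid, copies, superfamily="Gypsy", age=old, bias=0.5, **kw):
        return FamilyPlan(
            family_id=fid,
            consensus_length=2000,
            copies=copies,
            superfamily=superfamily,
            age=age,
            min_remnant_fraction=0.12,
            subgenome_bias=bias,
            **kw,
        )

    families = [
        fam("RLGy_core01", every(1400)),                      # HIGH everywhere
        fam("RLCo_core02", every(450), "Copia"),              # MID everywhere
    ]
    families += [fam(f"RLGy_low{i:02d}", every(80)) for i in range(3, 9)]
    families += [fam(f"RLCo_mid{i:02d}", every(250), "Copia") for i in range(9, 13)]
    families += [
        fam(
            "RLGy_abias",
            {"dipA": 400, "tetX": 1100, "tetY": 400},
            bias=0.95,
        ),
        fam(
            "RLCo_dbias",
            {"dipD": 300, "tetX": 300, "tetY": 300},
            "Copia",
            bias=0.05,
        ),
        fam("RLGy_tetonly", {"tetX": 200, "tetY": 200}),
        fam("RLGy_specx", {"tetX": 300}, age=bursty),
        fam("RLGy_speca", {"dipA": 150}, age=bursty),
        fam("RLCo_specd", {"dipD": 150}, "Copia"),
        fam("RLCo_specy", {"tetY": 150}, "Copia"),
        fam("RLGy_noty", {"dipA": 90, "dipD": 90, "tetX": 90}),
        fam("RLGy_notd", {"dipA": 90, "tetX": 90, "tetY": 90}),
    ]
    return SimulationConfig(
        seed=seed,
        species=[
            diploid("dipA", "a"),
            diploid("dipD", "d"),
            tetraploid("tetX"),
            tetraploid("tetY"),
        ],
        families=families,
    )


# ---------------------------------------------------------------------------
# Deliberately messy fixtures


def random_hit_set(
    rng: np.random.Generator,
    n_hits: int,
    n_chromosomes: int = 3,
    chrom_length: int = 100_000,
    species: str = "sp1",
    n_families: int = 5,
) -> list[RepeatHit]:
    """Random, deliberately overlapping hits for overlap-resolution tests.

    Unlike :func:`simulate_species` output (non-overlapping by
    construction), these intervals collide freely, exercising the
    longer-hit-wins rule.
    """
    hits = []
    for i in range(n_hits):
        chrom = f"chr{int(rng.integers(1, n_chromosomes + 1))}"
        length = int(rng.integers(100, 5000))
        start = int(rng.integers(1, max(2, chrom_length - length)))
        hits.append(
            RepeatHit(
                species=species,
                chromosome=chrom,
                start=start,
                end=start + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                family_id=f"FAM_{int(rng.integers(0, n_families)):03d}",
                superfamily="Gypsy",
                sw_score=length,
                pct_div=float(rng.uniform(0, 40)),
                hit_id=i + 1,
            )
        )
    return hits
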