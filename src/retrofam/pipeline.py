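"""End-to-end orchestration: families -> quantify -> compare -> divergence
-> landscape, with TSV report output.

Every stage is a pure function of (inputs, config), so rerunning a
configuration reproduces the bundle byte for byte. The summary tables echo
the shape of the standard comparative reports: a per-species genome-occupancy
table (LTR bp, genome bp, percent) and family-sharing percentages over the
Venn partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import compare, divergence, families, landscape, quantify, rm_io
from .model import FamilyRecord

logger = logging.getLogger(__name__)

STAGES = ("families", "quantify", "compare", "kimura", "landscape")


@dataclass(slots=True)
class SpeciesInputs:
    name: str
    out: Path
    align: Path
    gff3: Path


@dataclass(slots=True)
class RunConfig:
    """Validated inputs and thresholds for one pipeline run."""

    species: list[SpeciesInputs]
    manifest: Path
    library: Path
    outdir: Path
    identity_threshold: float = 0.8
    min_copies: int = 10
    min_element_length: int = 100
    presence_threshold: int = 10
    flank: int = landscape.GENE_FLANK
    window_size: int = landscape.WINDOW_SIZE
    copy_class_edges: tuple[int, int, int] = quantify.COPY_CLASS_EDGES
    top_families: int = 5
    seed: int = 0

    def validate(self) -> None:
        for value, name in (
            (self.min_copies, "min_copies"),
            (self.min_element_length, "min_element_length"),
            (self.presence_threshold, "presence_threshold"),
            (self.flank, "flank"),
            (self.window_size, "window_size"),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity_threshold must be in (0, 1]")
        missing = [
            str(p)
            for p in [self.manifest, self.library]
            + [p for sp in self.species for p in (sp.out, sp.align, sp.gff3)]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError("missing input files: " + ", ".join(missing))

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path | None = None) -> "RunConfig":
        import yaml

        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh)
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        thresholds = data.get("thresholds", {})
        return cls(
            species=[
                SpeciesInputs(
                    name=sp["name"],
                    out=resolve(sp["out"]),
                    align=resolve(sp["align"]),
                    gff3=resolve(sp["gff3"]),
                )
                for sp in data["species"]
            ],
            manifest=resolve(data["manifest"]),
            library=resolve(data["library"]),
            outdir=Path(outdir) if outdir else resolve(data.get("outdir", "results")),
            identity_threshold=float(thresholds.get("identity", 0.8)),
            min_copies=int(thresholds.get("min_copies", 10)),
            min_element_length=int(thresholds.get("min_element_length", 100)),
            presence_threshold=int(thresholds.get("presence_threshold", 10)),
            flank=int(thresholds.get("flank", landscape.GENE_FLANK)),
            window_size=int(thresholds.get("window", landscape.WINDOW_SIZE)),
            copy_class_edges=tuple(
                thresholds.get("copy_class_edges", quantify.COPY_CLASS_EDGES)
            ),
            top_families=int(data.get("top_families", 5)),
            seed=int(data.get("seed", 0)),
        )


def report_sharing_percentages(v: compare.VennPartition) -> pd.DataFrame:
    """Venn region counts as percentages of all families.

    ``percent`` is printed at one decimal; ``percent_int`` at integer
    precision. ``kind`` highlights the whole-set and singleton regions.
    """
    total = v.total()
    if total == 0:
        raise ValueError("empty Venn partition")
    rows = []
    order = {sp: i for i, sp in enumerate(v.species)}
    for subset in sorted(
        v.region_counts, key=lambda s: (len(s), sorted(order[x] for x in s))
    ):
        count = v.region_counts[subset]
        if len(subset) == len(v.species):
            kind = "all"
        elif len(subset) == 1:
            kind = "specific"
        else:
            kind = "partial"
        rows.append(
            {
                "subset": "+".join(sorted(subset, key=order.get)),
                "n_species": len(subset),
                "count": count,
                "percent": round(100.0 * count / total, 1),
                "percent_int": round(100.0 * count / total),
                "kind": kind,
            }
        )
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(cfg: RunConfig, stages: set[str] | None = None) -> dict:
    """Execute the pipeline and write the report bundle to ``cfg.outdir``.

    ``stages`` restricts which report groups are written (family
    construction always runs, as everything depends on it). Returns the
    in-memory bundle keyed by table name.
    """
    stages = set(STAGES) if stages is None else set(stages)
    unknown = stages - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    cfg.validate()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    stage = "families"
    annotations = rm_io.read_manifest(cfg.manifest)
    library = rm_io.read_library_fasta(cfg.library)
    all_resolved = []
    for sp in cfg.species:
        raw = rm_io.read_repeatmasker_out(sp.out, sp.name)
        resolved = quantify.resolve_overlaps(raw)
        logger.info(
            "[families] %s: %d hits read, %d after overlap resolution",
            sp.name, len(raw), len(resolved),
        )
        all_resolved.extend(resolved)
    fam_records = families.define_families(
        all_resolved, library, cfg.min_copies, cfg.min_element_length
    )
    logger.info("[families] %d families defined", len(fam_records))
    species_names = [sp.name for sp in cfg.species]
    fam_rows = []
    for fam in fam_records:
        for sp in species_names:
            s = quantify.summarize_family(fam, sp)
            if s.copy_number:
                fam_rows.append(
                    {
                        "family_id": fam.family_id,
                        "superfamily": fam.superfamily,
                        "species": sp,
                        "copies": s.copy_number,
                        "total_bp": s.total_bp,
                        "mean_bp": round(s.mean_bp),
                    }
                )
    bundle["families"] = pd.DataFrame(fam_rows)
    _write(bundle["families"], cfg.outdir / "families.tsv")

    if "quantify" in stages:
        stage = "quantify"
        class_rows = []
        for sp in species_names:
            present = [
                quantify.summarize_family(fam, sp)
                for fam in fam_records
                if fam.copies_in(sp) >= cfg.copy_class_edges[0]
            ]
            for cls in quantify.bin_by_copy_class(present, cfg.copy_class_edges):
                class_rows.append(
                    {
                        "species": sp,
                        "copy_class": cls.copy_class,
                        "family_count": cls.family_count,
                        "total_bp": cls.total_bp,
                        "mean_element_bp": round(cls.mean_element_bp),
                    }
                )
        bundle["copy_class"] = pd.DataFrame(class_rows)
        _write(bundle["copy_class"], cfg.outdir / "copy_class.tsv")

        frac_rows = []
        for sp in species_names:
            ltr_bp = sum(
                h.length() for fam in fam_records for h in fam.members.get(sp, [])
            )
            genome_bp = annotations[sp].genome_size
            frac_rows.append(
                {
                    "species": sp,
                    "ltr_bp": ltr_bp,
                    "genome_bp": genome_bp,
                    "percent_of_genome": quantify.genome_fraction(ltr_bp, genome_bp),
                }
            )
        bundle["genome_fraction"] = pd.DataFrame(frac_rows)
        _write(bundle["genome_fraction"], cfg.outdir / "genome_fraction.tsv")
        logger.info("[quantify] wrote copy-class and genome-fraction tables")

    matrix = compare.presence_matrix(
        fam_records, species_names, cfg.presence_threshold
    )
    if "compare" in stages:
        stage = "compare"
        if 2 <= len(species_names) <= 4:
            venn = compare.venn_partition(matrix)
            sharing = report_sharing_percentages(venn)
            bundle["venn"] = pd.DataFrame(
                [
                    {
                        "subset": "+".join(
                            sorted(s, key=species_names.index)
                        ),
                        "count": c,
                    }
                    for s, c in sorted(
                        venn.region_counts.items(),
                        key=lambda kv: (len(kv[0]), sorted(species_names.index(x) for x in kv[0])),
                    )
                ]
            )
            bundle["sharing"] = sharing
            _write(bundle["venn"], cfg.outdir / "venn.tsv")
            _write(sharing, cfg.outdir / "sharing.tsv")
            logger.info("[compare] %d Venn regions over %d families",
                        len(venn.region_counts), venn.total())
        else:
            logger.warning(
                "[compare] Venn partition needs 2-4 species (got %d); "
                "skipping venn/sharing tables", len(species_names),
            )

        subg_rows = []
        for sp in species_names:
            if annotations[sp].ploidy != "tetraploid":
                continue
            for fam in fam_records:
                if not fam.copies_in(sp):
                    continue
                pref = compare.subgenome_distribution(fam, annotations[sp])
                subg_rows.append(
                    {
                        "species": sp,
                        "family_id": fam.family_id,
                        "copies_A": pref.copies_A,
                        "copies_D": pref.copies_D,
                        "unplaced": pref.unplaced,
                        "preference_A": (
                            round(pref.preference_A, 4)
                            if pref.preference_A is not None
                            else ""
                        ),
                    }
                )
        bundle["subgenome"] = pd.DataFrame(subg_rows)
        _write(bundle["subgenome"], cfg.outdir / "subgenome.tsv")

    if "kimura" in stages:
        stage = "kimura"
        surviving = {
            (sp, h.hit_id)
            for fam in fam_records
            for sp in fam.members
            for h in fam.members[sp]
        }
        copy_class = {}
        for fam in fam_records:
            for sp in species_names:
                n = fam.copies_in(sp)
                if n >= cfg.copy_class_edges[0]:
                    copy_class[(sp, fam.family_id)] = quantify.copy_class_of(
                        n, cfg.copy_class_edges
                    )
        records_by_species = {}
        for sp in cfg.species:
            recs = rm_io.read_repeatmasker_align(sp.align)
            records_by_species[sp.name] = [
                r for r in recs if (sp.name, r.hit_id) in surviving
            ]
        profile = divergence.kimura_profile(
            records_by_species, copy_class, strict=False
        )
        bundle["kimura_profile"] = pd.DataFrame(
            profile.to_rows(), columns=["species", "copy_class", "k_bin", "count"]
        )
        _write(bundle["kimura_profile"], cfg.outdir / "kimura_profile.tsv")
        logger.info(
            "[kimura] %d elements scored, %d saturated, %d without class",
            profile.total_scored(),
            sum(profile.saturated.values()),
            profile.skipped_no_class,
        )
        bundle["kimura_profile_obj"] = profile

    if "landscape" in stages:
        stage = "landscape"
        top = sorted(
            fam_records, key=lambda f: (-f.total_copies(), f.family_id)
        )[: cfg.top_families]
        corr_rows = []
        neigh_rows = []
        for sp in cfg.species:
            ann = annotations[sp.name]
            genes = rm_io.read_gff3_genes(sp.gff3)
            sp_hits = [
                h for fam in fam_records for h in fam.members.get(sp.name, [])
            ]
            gene_track = landscape.density_track(
                genes, ann, "genes", cfg.window_size
            )
            all_track = landscape.density_track(
                sp_hits, ann, "all_LTR", cfg.window_size
            )
            landscape.write_bedgraph(
                gene_track, ann, cfg.outdir / f"{sp.name}.genes.bedgraph"
            )
            landscape.write_bedgraph(
                all_track, ann, cfg.outdir / f"{sp.name}.all_LTR.bedgraph"
            )
            for fam in top:
                fam_hits = fam.members.get(sp.name, [])
                if not fam_hits:
                    continue
                track = landscape.density_track(
                    fam_hits, ann, fam.family_id, cfg.window_size
                )
                landscape.write_bedgraph(
                    track, ann,
                    cfg.outdir / f"{sp.name}.{fam.family_id}.bedgraph",
                )
                corr_rows.append(
                    {
                        "species": sp.name,
                        "family_id": fam.family_id,
                        "spearman_vs_genes": round(
                            landscape.track_correlation(track, gene_track), 4
                        ),
                    }
                )
                for gene_id, gap in sorted(
                    landscape.gene_neighborhood_gaps(
                        fam_hits, genes, cfg.flank
                    ).items()
                ):
                    neigh_rows.append(
                        {
                            "species": sp.name,
                            "family_id": fam.family_id,
                            "gene_id": gene_id,
                            "min_gap_bp": gap,
                        }
                    )
        bundle["track_correlation"] = pd.DataFrame(corr_rows)
        bundle["gene_neighborhoods"] = pd.DataFrame(neigh_rows)
        _write(bundle["track_correlation"], cfg.outdir / "track_correlation.tsv")
        _write(bundle["gene_neighborhoods"], cfg.outdir / "gene_neighborhoods.tsv")
        logger.info("[landscape] wrote tracks for %d families", len(top))

    del stage
    bundle["family_records"] = fam_records
    bundle["presence_matrix"] = matrix
    return bundle
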