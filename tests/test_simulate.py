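"""Inverse-K2P mutation, fragmentation, whole-species simulation contracts."""

import numpy as np
import pytest

from oracles import kimura_closed_form
from retrofam.divergence import kimura_k2p
from retrofam.families import define_families
from retrofam.model import AlignmentRecord
from retrofam.rm_io import (
    read_repeatmasker_align,
    read_repeatmasker_out,
)
from retrofam.simulate import (
    AgeComponent,
    AgeMixture,
    ChromosomePlan,
    FamilyPlan,
    SimulationConfig,
    SpeciesPlan,
    fragment_element,
    mutate_k2p,
    random_consensus,
    simulate,
    simulate_species,
    solve_k2p_rates,
)


class TestSolveRates:
    def test_zero_target(self):
        assert solve_k2p_rates(0.0, 2.0) == (0.0, 0.0)

    @pytest.mark.parametrize("k,kappa", [(5.0, 2.0), (17.02, 2.0), (28.0, 1.0), (45.0, 3.0)])
    def test_rates_satisfy_closed_form(self, k, kappa):
        p, q = solve_k2p_rates(k, kappa)
        assert p == pytest.approx(kappa * q)
        assert kimura_closed_form(p, q) == pytest.approx(k, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            solve_k2p_rates(-1.0, 2.0)
        with pytest.raises(ValueError):
            solve_k2p_rates(10.0, 0.0)


class TestMutate:
    def test_target_zero_leaves_sequence_unchanged(self, rng):
        s = random_consensus(500, rng)
        assert mutate_k2p(s, 0.0, 2.0, rng) == s

    def test_long_sequence_estimate_near_target(self, rng):
        s = random_consensus(100_000, rng)
        m = mutate_k2p(s, 17.02, 2.0, rng)
        assert kimura_k2p(AlignmentRecord(1, "f", m, s)) == pytest.approx(17.02, abs=0.5)

    def test_non_acgt_untouched(self, rng):
        m = mutate_k2p("N" * 50, 30.0, 2.0, rng)
        assert m == "N" * 50


class TestFragment:
    def test_never_remnant(self, rng):
        cons = random_consensus(1000, rng)
        for _ in range(20):
            sub, off = fragment_element(cons, 0.0, 0.1, rng)
            assert sub == cons and off == 0

    def test_always_remnant_respects_bounds(self, rng):
        cons = random_consensus(1000, rng)
        for _ in range(200):
            sub, off = fragment_element(cons, 1.0, 0.1, rng)
            assert 100 <= len(sub) <= 500
            assert cons[off : off + len(sub)] == sub

    def test_remnant_rate_within_binomial_interval(self, rng):
        cons = random_consensus(400, rng)
        remnants = sum(
            len(fragment_element(cons, 0.75, 0.1, rng)[0]) < 400 for _ in range(1000)
        )
        assert abs(remnants / 1000 - 0.75) < 0.04

    def test_min_fraction_validated(self, rng):
        with pytest.raises(ValueError):
            fragment_element("ACGT", 0.5, 0.0, rng)


def micro_config(seed=5, **family_kw):
    kw = dict(
        family_id="RLGy_x", consensus_length=1500, copies={"sp": 10},
        age=AgeMixture(components=(AgeComponent(1.0, 0.0, 0.0),), truncation=(0, 0)),
        remnant_prob=0.0,
    )
    kw.update(family_kw)
    return SimulationConfig(
        seed=seed,
        species=[SpeciesPlan("sp", [ChromosomePlan("c1", 200_000)])],
        families=[FamilyPlan(**kw)],
    )


class TestSimulateSpecies:
    def test_closed_micro_loop_recovers_family_and_zero_divergence(self):
        from retrofam.simulate import consensus_library

        cfg = micro_config()
        sim = simulate_species(cfg, "sp")
        (fam,) = define_families(sim.hits, consensus_library(cfg))
        assert fam.total_copies() == 10
        assert all(kimura_k2p(r) == 0.0 for r in sim.alignments)

    def test_elements_match_genome_sequence(self):
        """Planted plus-strand copies read back identically from the FASTA."""
        cfg = micro_config()
        sim = simulate_species(cfg, "sp")
        chrom = sim.chromosomes["c1"]
        for h, rec in zip(sim.hits, sim.alignments):
            genomic = chrom[h.start - 1 : h.end]
            if h.strand == "+":
                assert genomic == rec.aligned_element

    def test_subgenome_bias_recovered(self):
        cfg = SimulationConfig(
            seed=9,
            species=[SpeciesPlan("tet", [
                ChromosomePlan("A1", 600_000, "A"),
                ChromosomePlan("D1", 600_000, "D"),
            ])],
            families=[FamilyPlan(
                "RLGy_b", 1200, {"tet": 200}, subgenome_bias=0.95,
                min_remnant_fraction=0.15,
            )],
        )
        sim = simulate_species(cfg, "tet")
        frac_a = np.mean([r.subgenome == "A" for r in sim.ground_truth])
        assert abs(frac_a - 0.95) < 0.03

    def test_overcrowded_chromosome_errors(self):
        cfg = micro_config(copies={"sp": 1000})
        with pytest.raises(ValueError, match="chromosome"):
            simulate_species(cfg, "sp")


class TestDatasetContracts:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg = micro_config()
        out1, out2 = tmp_path / "a", tmp_path / "b"
        simulate(cfg).write(out1)
        simulate(cfg).write(out2)
        for p1 in sorted(out1.iterdir()):
            assert p1.read_bytes() == (out2 / p1.name).read_bytes()

    def test_emitted_files_reparse_cleanly(self, small_dataset):
        _, dataset, outdir = small_dataset
        for name, sim in dataset.species.items():
            hits = read_repeatmasker_out(outdir / f"{name}.out", name)
            assert hits == sim.hits
            records = read_repeatmasker_align(outdir / f"{name}.align")
            assert records == sim.alignments

    def test_ground_truth_matches_out_rows(self, small_dataset):
        _, dataset, _ = small_dataset
        for sim in dataset.species.values():
            assert len(sim.ground_truth) == len(sim.hits)
            for row, h in zip(sim.ground_truth, sim.hits):
                assert (row.chromosome, row.start, row.end, row.strand) == (
                    h.chromosome, h.start, h.end, h.strand,
                )

    def test_yaml_round_trip(self, tmp_path):
        cfg_yaml = tmp_path / "sim.yaml"
        cfg_yaml.write_text(
            "seed: 3\n"
            "species:\n"
            "  - name: sp\n"
            "    chromosomes:\n"
            "      - {name: c1, length: 150000}\n"
            "families:\n"
            "  - family_id: RLGy_y\n"
            "    consensus_length: 1200\n"
            "    copies: {sp: 12}\n"
            "    age:\n"
            "      components: [{weight: 1.0, mean: 10, sd: 2}]\n"
            "      truncation: [0, 40]\n"
        )
        cfg = SimulationConfig.from_yaml(cfg_yaml)
        assert cfg.seed == 3
        assert cfg.families[0].age.components[0].mean == 10
        sim = simulate_species(cfg, "sp")
        assert len(sim.hits) == 12
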