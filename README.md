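# retrofam

Comparative analysis of **LTR-retrotransposon families** across related
plant genomes — built around the questions raised by allopolyploid cotton
(*Gossypium*), where two tetraploid species carry A- and D-subgenomes
inherited from diploid progenitors, but applicable to any set of
RepeatMasker-annotated assemblies.

LTR retrotransposons are the dominant DNA component of most plant genomes.
Analysing them at the *family* level — a family being the set of genomic
copies annotated by one library consensus — reveals structure that
superfamily-level totals hide: which families are shared between species,
which are species-specific, how copies distribute between subgenomes of an
allotetraploid, and when each family was transpositionally active.

## What the package computes

Given RepeatMasker `.out` hit tables, `.align` element-vs-consensus
alignments, a consensus library FASTA, gene GFF3s and a chromosome
manifest, `retrofam`:

* **builds families** — greedy clustering of consensi at ≥ 80 % identity
  (CD-HIT-style: identity over the shorter sequence, both strands, free
  end gaps), reference-library deduplication, then family definition with
  the standard filters: elements > 100 nt, ≥ 10 copies;
* **quantifies** — per-species copy number, occupied bp and mean element
  length after longer-hit-wins overlap resolution; percent of genome;
  LOW (10–200) / MID (201–800) / HIGH (> 800) copy-number classes;
* **compares** — presence/absence matrix (≥ 10 copies per species), the
  full Venn partition (15 regions for four species), arbitrary
  present-in/absent-in family selections, and A- vs D-subgenome copy
  counts per family in tetraploids;
* **dates** — Kimura 2-parameter divergence of every element from its
  consensus, `K = −½·ln((1−2P−Q)·√(1−2Q))` (reported ×100), binned into
  unit bins over 0–60 and stratified by species and copy class; pairwise
  K2P matrices from an input MSA and Saitou–Nei neighbor-joining trees
  (exact on additive matrices);
* **maps** — 2-Mb window density tracks (start-point assignment) for
  families and genes as bedGraph, Spearman track correlations, and genes
  within ± 20 kb of a family's copies;
* **simulates** — synthetic multi-species genomes with a shared library,
  configurable per-species copy numbers, an element-age mixture (default
  0.8·N(28, 6) + 0.2·N(2, 1) in K units), ~75 % truncated remnant copies
  and subgenome insertion bias, with full ground truth, so the whole
  pipeline is testable end to end without any real assembly.

## Worked example

Simulate a toy two-species dataset and analyse it:

```bash
retrofam simulate --config sim.yaml --outdir data
# simulated 2 species, 1 families, 25 elements -> data
retrofam run --config data/run.yaml --outdir results
# wrote 12 tables to results
```

with `sim.yaml` planting one Gypsy family (1.5-kb consensus, 15 copies in
`spA`, 10 in `spB`, half of them remnants):

```yaml
seed: 11
species:
  - name: spA
    chromosomes: [{name: c1, length: 400000}]
  - name: spB
    chromosomes: [{name: c1, length: 400000}]
families:
  - family_id: RLGy_demo
    consensus_length: 1500
    copies: {spA: 15, spB: 10}
    remnant_prob: 0.5
    min_remnant_fraction: 0.15
```

`results/families.tsv` recovers the configured copy numbers exactly, and
the occupied-length columns show the effect of remnant truncation (mean
element ≈ 1.0 kb and 0.76 kb against a 1.5-kb consensus):

```
family_id   superfamily  species  copies  total_bp  mean_bp
RLGy_demo   Gypsy        spA      15      15584     1039
RLGy_demo   Gypsy        spB      10      7584      758
```

`results/genome_fraction.tsv` gives per-species genome occupancy
(15 584 bp of a 400-kb genome = 3.90 %), and `results/sharing.tsv` the
Venn partition with percentages — here the single family is shared:

```
subset   n_species  count  percent  percent_int  kind
spA      1          0      0.0      0            specific
spB      1          0      0.0      0            specific
spA+spB  2          1      100.0    100          all
```

The same tables, plus copy-class summaries, per-family subgenome counts,
the Kimura landscape (`kimura_profile.tsv`) and bedGraph density tracks,
are produced for any number of species. Everything is also available as a
library — see `retrofam.families`, `retrofam.quantify`,
`retrofam.compare`, `retrofam.divergence`, `retrofam.landscape`,
`retrofam.simulate`.

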