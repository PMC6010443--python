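# Methods

## Family model

A *family* is the set of genomic copies annotated by one consensus
sequence of the repeat library. Families are materialised from
RepeatMasker-style hit tables in three steps:

1. **Overlap resolution** (per species, across families jointly): hits are
   considered longest-first; a hit survives only if it overlaps every
   already-retained hit by at most `max_overlap_fraction` of its own
   length (default 0 — any shared base discards the shorter hit). Ties in
   length resolve to the smaller start, then the smaller hit ID. This
   models RepeatMasker reporting competing annotations of different
   families at one locus.
2. **Element filter**: only hits longer than 100 nt count (strictly — a
   100-bp hit is dropped).
3. **Family filter**: a family needs at least 10 surviving copies pooled
   across species. *Presence* of a family in one species additionally
   requires ≥ 10 copies in that species (configurable down to 1); the
   presence matrix drives the Venn partition and family selections.

### Identity and clustering

Library construction clusters consensus sequences at ≥ 80 % identity.
Identity is CD-HIT-like: a global alignment with free end gaps (match +1,
mismatch −1, gap −2), both strands compared, and the count of identically
aligned bases divided by the length of the shorter sequence. A tiny match
bonus (10⁻⁶) breaks ties between score-co-optimal alignments in favour of
the one with most identities; this makes the statistic symmetric and
deterministic without affecting any strict score ordering for sequences
below ~10⁶ bp. Clustering is greedy and incremental: sequences are
processed longest-first (ties by label), each joining the first cluster
whose founder matches at ≥ 80 %, so the result is order-independent given
the input set. Cluster consensi are majority votes in the representative's
coordinate frame (ties to the representative's base) rather than a full
progressive MSA — deterministic, linear-cost, and adequate for
highly-similar cluster members.

### Full-length vs remnant calls

A copy is called *remnant* when it covers less than half of its consensus
length. This is a coverage proxy for truncation by illegitimate/unequal
recombination, not a structural LTR-boundary call; the 0.5 threshold is a
package choice (configurable), so remnant percentages should be read as
relative comparisons, not absolute structural statistics.

## Divergence model

Element age is proxied by the Kimura 2-parameter distance between a copy
and its consensus, computed from the `.align` pairwise alignments:

    K = −½ · ln((1 − 2P − Q) · √(1 − 2Q))

with P and Q the transition and transversion proportions over columns
where both rows are a plain A/C/G/T base (gap and N columns excluded;
pairwise deletion likewise for MSA distance matrices). K is reported ×100
to match the conventional 0–60 landscape axis. Alignments where the
logarithm's argument is non-positive are *saturated*; they are excluded
from landscapes and counted separately rather than clamped into the last
bin, which would fabricate a terminal spike. No CpG-adjusted variant is
applied.

Landscapes use unit bins [k, k+1) with the final bin absorbing K ≥ 60,
stratified by species and copy-number class (LOW 10–200, MID 201–800,
HIGH > 800 per species). **Peak location** is read as the argmax of the
histogram after a centred moving average (width 7 in the validation
checks): the age distribution is broad relative to a unit bin — and when
the underlying density peaks exactly on a bin edge the two adjacent bins
are tied in expectation — so the raw argmax wanders among near-tied bins
while the smoothed argmax is stable.

Neighbor joining is the standard Saitou–Nei agglomeration on the Q
criterion with the usual branch-length formulas, resolving the last three
nodes by the three-point formulas into an unrooted trifurcation. It is
exact on additive matrices (verified against random tree metrics to
1e-6). Negative branch lengths are clamped to zero by default
(toggleable).

## Window densities and gene proximity

Chromosomes split into contiguous fixed-size windows (default 2 Mb); each
feature counts once, in the window containing its start — an element
straddling a boundary is not split — and the final partial window is kept
as its own bin. Track correlation defaults to Spearman over the
concatenated per-chromosome vectors; this quantifies what density figures
are usually only eyeballed for, and is labelled as such in the output.
Gene neighborhoods are symmetric (± 20 kb default), measured
interval-to-interval (a gene overlapping a copy is at distance 0), strand
ignored.

An open choice: window densities could count elements or sum occupied bp;
counts are the default, with `mode="bp"` attributing each feature's full
length to its start window.

## Synthetic-genome generator

The simulator emulates the statistical structure of multi-species repeat
annotations so that every pipeline stage has a ground-truthed input:

* **Shared library**: uniform-random consensi, one per configured family,
  identical across species.
* **Copy numbers** are configured per family per species and are
  recovered exactly by the pipeline because insertions are planted
  non-overlapping and every fragment is kept above the 100-nt filter.
* **Ages**: per-copy target K drawn from a truncated normal mixture. The
  default is 0.8·N(28, 6) + 0.2·N(2, 1) on [0, 55] — a broad old peak at
  K = 28 plus a small recent burst below K = 3.
* **Divergence** is introduced by the inverse K2P model: for target K and
  transition/transversion ratio κ (default 2), the per-site rates with
  P = κQ solving the closed form are applied independently per site, so
  the expected estimated K equals the target. Alignments are emitted
  gap-free (substitution-only): indel evolution is deliberately excluded
  so K recovery is exactly testable.
* **Fragmentation**: with probability `remnant_prob` (default 0.75) a
  copy is a uniformly placed slice covering U(`min_fraction`, 0.5) of the
  consensus.
* **Subgenome bias**: in tetraploids each insertion picks an A-labelled
  chromosome with probability `subgenome_bias`, then a chromosome within
  the set proportionally to length.
* **Genes** are planted after elements, avoiding them, so gene-proximity
  statistics are well defined.

All randomness flows from one integer seed through per-purpose generators
in documented draw order; a fixed seed gives byte-identical output files.

What the simulator does **not** model — and hence what passing tests do
not show about real data: realistic base composition and repeat nesting,
indels and alignment ambiguity, solo-LTR formation, annotation errors and
fragmented assemblies, and real overlap conflicts (a separate fixture
generator produces deliberately overlapping hit sets to exercise overlap
resolution). Closed-loop recovery demonstrates internal consistency of
the estimators, not annotation accuracy on real genomes.

### Packaged validation scenario

`demo_config(seed)` defines the four-species scenario used by the
validation suite and `scripts/acceptance.py`: two diploids (3 × 3.6-Mb
chromosomes) and two tetraploids (3 A + 3 D chromosomes of 3 Mb), 21
families of 2-kb consensi (~17 800 elements in total — large enough that
the divergence-peak readout is stable, small enough to simulate and
analyse in well under a minute). The design covers all three copy-number
classes shared by all species, species-specific families, families absent
from exactly one species, a tetraploid-only family, one high-copy family
with A-subgenome bias 0.95 (1 100 copies in one tetraploid, so the
recovered preference has binomial standard error ≈ 0.007) and one
D-biased family. Recent-burst age mixtures are confined to two
species-specific families, matching the observation that young
amplifications are genome-particular; the remaining families age by the
pure old peak N(28, 6).

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive throughout (the `.out`/GFF3
  convention); only bedGraph output is 0-based half-open.
* Genome fractions print at two decimals; sharing percentages at one
  decimal plus an integer column.
* Constant window tracks give a correlation of NaN rather than an error.
* Saturated MSA pairs abort distance-matrix construction (NJ needs a
  complete matrix) naming the pair.
* `mutate_k2p` solves for Q by bisection on (0, min(1/(2κ+1), ½)); K = 0
  returns the sequence unchanged; non-ACGT characters are never mutated.
* Families whose per-species copy number falls below the presence floor
  contribute no landscape class for that species; their alignment records
  are counted as skipped rather than guessed into a class.

## Known limitations

* The 80 %-identity rule is applied without a coverage requirement
  (Wicker-style 80/80/80 is not enforced); a coverage knob would tighten
  family boundaries for highly fragmented libraries.
* Remnant calls are coverage-based (see above).
* The NJ implementation targets the small trees of per-family phylogenies
  (≤ a few hundred taxa); it is O(n³) and unsuitable for whole-library
  trees.
* MSAs are consumed, never computed.
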