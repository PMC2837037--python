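# Methods

## The mapping model

A BAC library of a target species is end sequenced and the end reads are
aligned to the assembled genome of a related reference species. Because
paired end reads come from the two extremities of one insert, a clone
whose ends align to the same chromosome, inward-facing on opposite
strands, at a separation compatible with the insert-size distribution,
almost certainly derives from a single orthologous locus. Overlapping
consistent clones define BAC-contigs; the remaining signal classes carry
information of their own (one-end clones mark repeat-rich or diverged
regions, same-chromosome inconsistent pairs mark candidate
rearrangements, two-chromosome pairs are discarded as chimera- or
repeat-driven).

### Hit acceptance

A read is placed only when its best local alignment has e-value ≤ 10⁻⁵
and the second-best alignment's e-value is at least 10⁵-fold larger.
Reported e-values of exactly zero are floored at 1e-180 before the ratio
test so it stays defined; tied best e-values are rejected as ambiguous
(the ratio cannot hold). Hits may arrive in several stringency rounds
(decreasing aligner word size); a read accepted at a stricter round is
never re-evaluated. Reads without an acceptable direct hit can be
rescued through an assembled WGS contig that contains them: the contig's
accepted hit is composed with the read's offset and orientation inside
the contig (`anchored` round). When both a direct acceptance and an
anchored lift exist, the direct hit wins — one fewer composed error
source. Every read ends in exactly one state: accepted, above_cutoff,
ambiguous, no_hits, or lift_failure.

### Consistency policy

The implied insert of a pair is the outermost reference span (it includes
both read lengths, the conventional reference-projected "insert size").
Default distance bounds are [0.3, 2.5] × (library mean insert /
inflation guess), with inflation guess 1.0 on a first pass — wide enough
to hold the whole insert-size distribution even after a ~1.5-fold genome
compression, tight enough to flag Mbp-scale separations. The orientation
rule is purely inward-facing opposite strands; which vector end produced
the forward read is irrelevant and not assumed.

### Tiling

Contig membership requires a shared base (half-open interval overlap);
abutting clones do not join. The minimal tiling path is the greedy
interval cover: seed with the clone at the contig's left edge (ties →
larger right end, then lexicographic id), then repeatedly add, among
clones overlapping the covered prefix, the one reaching farthest right.
For covering a connected union of intervals by an overlap chain this
greedy choice is optimal; the test suite verifies cardinality equality
against an exhaustive oracle on a thousand random instances (≤ 12
intervals) and that removing any path clone breaks coverage. N50 here is
referenced to the *chromosome* length, not the covered length: the size
(and count) of descending-size contigs at which half the reference is
covered. A gene counts as covered only when fully contained in one
contig span — partially covered genes are not counted, the conservative
reading of "genes covered".

### Genome size from insert-size modes

Teleost genomes accumulate indels mostly in intergenic and intronic
sequence while gene synteny is conserved, so the sizes of orthologous
loci scale roughly uniformly. The reference-projected insert sizes of
consistent clones are then the library insert sizes divided by the
genome-size ratio, and the ratio of the two distribution *modes*
estimates that ratio directly; multiplying by the reference genome size
gives the target genome size. Modes are taken from fixed-width
histograms (default bin 5 kbp, centers anchored on the sample minimum,
ties toward the smaller bin); the same binning is applied to both
distributions so quantization partially cancels in the ratio.
Reporting rounds fold-coverage to one decimal and genome size to the
nearest 10 Mbp.

### Rearrangement detection and second-reference confirmation

A clone spanning an intra-chromosomal breakpoint has its two ends near
the edges of two different BAC-contigs (consistent coverage cannot cross
the breakpoint, so contigs end there). Candidates are therefore
inconsistent same-chromosome clones with both ends within an edge
tolerance of contig boundaries; the default tolerance is one
reference-projected clone length (library mean / inflation estimate),
since a spanning clone's end cannot lie farther from the break. All
other inconsistent clones are rejected as not-at-edge.

Chimeric clones produce identical signatures, so candidates are
cross-checked on a second reference genome through an ortholog table:
each contig edge takes the position of its nearest flanking ortholog
gene (within a 500 kbp flank window; edges without one are unevaluable),
and a candidate is confirmed when its two projected edges land on the
same second-reference chromosome within an adjacency threshold (default
1 Mbp) with no other projected edge between them. A genuine
rearrangement relative to the reference looks un-rearranged on an
outgroup sharing the target's arrangement; a chimeric junction projects
to two unrelated loci. Candidates sharing an ordered edge pair are
grouped into one breakpoint with a supporting-clone count.

## The simulator

The generator works at the coordinate level (no nucleotides): the output
is the set of tables a real campaign would produce after alignment, plus
ground truth. Per chromosome it composes two layers:

1. **Inflation** — intergenic gaps stretch by a constant factor while
   genes keep their length, so the target chromosome is
   `inflation_factor` × the reference length and ortholog order is
   preserved; this mirrors the indel-accumulation picture above.
2. **Rearrangement** — segment inversions and transpositions permute
   reference blocks; every junction between non-co-linear blocks is a
   recorded breakpoint (the pair of joined reference coordinates). The
   segment map is a bijection, verified by round-trip property tests.

Clones draw truncated-normal insert lengths (lower bound 2 × read
length), place uniformly on the target, and emit inward-facing end reads
from the insert extremities. Chimeric clones take their two ends from
independent placements. Each mappable end yields one hit with a fixed
highly significant e-value (1e-50); with probability
`ambiguous_hit_rate` an end also gets a decoy hit whose e-value either
keeps the uniqueness ratio satisfied (1e-40: primary still accepted) or
violates it (1e-48: the read becomes ambiguous), exercising both filter
branches. Unmappable ends emit nothing. Reads crossing a block junction
are attributed to the block holding their first base, as a local aligner
would place them.

The second-reference (ortholog) coordinates follow the *target's* gene
order: the outgroup is modeled as sharing the planted arrangement, which
is exactly the situation in which edge-adjacency confirms true
breakpoints and rejects chimeras. A configurable number of extra
adjacent-gene shuffles can be planted to degrade that assumption.

### Detectability constraint on planted rearrangements

Rearranged segment lengths are drawn uniformly in
[2 × insert mean, chromosome/5] — spannable by clones, never dominant.
Cut points keep at least one maximal clone length (mean + 4 sd) of
separation so no clone straddles two junctions. Transpositions
additionally enforce a minimum displacement and segment length of
2.5 × insert mean: a junction whose reference-coordinate jump is smaller
than the consistency distance window is undetectable *in principle* —
spanning pairs remain within bounds, classify as consistent and bridge
the contig gap — so planting such events would only measure a floor set
by geometry, not by the method. Inversions flip orientation and are
detectable at any displacement.

### Default parameters (the simulated study conditions)

| parameter | default | why |
|---|---|---|
| insert_mean / insert_sd | 164,000 / 16,400 bp | published library mean; 10% CV typical of BAC libraries |
| end_read_length | 670 bp | published average read length |
| inflation_factor | 1.3 | the observed target/reference genome-size ratio |
| n_chromosomes | 21 | reference karyotype |
| chromosome_length_range | 3.0–4.5 Mbp | ~1/13 linear scale; smallest size that hosts two detectable rearrangements per chromosome |
| n_rearrangements_per_chromosome | 2 (70% inversion / 30% transposition) | order of the observed ~10 candidates per chromosome at full scale, scaled down |
| n_clones | 6,000 | ≈ 9.6× physical coverage on the scaled genome, matching the real campaign |
| chimera_rate | 0.02 | typical BAC-library chimera burden (no published figure) |
| unmappable_end_rate / ambiguous_hit_rate | 0.15 / 0.10 | reproduce the rough published proportions of one-end and weakly/ambiguously matching clones |
| histogram bin width | 5 kbp | resolves the two insert-size modes with several bins between them |
| evalue_cutoff / ratio_threshold | 1e-5 / 1e5 | the published filter thresholds |
| edge_tolerance | insert_mean / inflation | one projected clone length |
| adjacency_threshold / flank_window | 1 Mbp / 500 kbp | order of contig-edge resolution on the second reference |

One seed drives everything; sub-streams for the reference, target,
library and ortholog steps are derived from it at fixed offsets, so each
stage is independently reproducible.

### What the simulator does not emulate

No nucleotide sequences, hence no real alignment noise: e-values are
synthetic constants, hit coordinates are exact up to junction clipping,
and repeats are reduced to a uniform decoy-hit rate. Insert sizes are a
single truncated normal (real libraries are mixtures with heavier
tails). Inflation is uniform over gaps, not clustered. There are no
inter-chromosomal rearrangements, no assembly gaps or errors in the
reference, and the second reference shares the target's arrangement
exactly unless shuffles are planted. Passing tests therefore demonstrate
the *logic* of the pipeline — filtering, classification, covering,
estimation and confirmation behave as claimed under known truth — not
robustness to aligner-level artifacts of real data.

## Numerical and procedural choices

* Coordinates are 0-based half-open internally; BLAST tabular input is
  1-based inclusive with minus strand encoded by reversed subject
  coordinates, converted at parse time; GFF3 output is 1-based inclusive.
* Tie-breaks everywhere are deterministic (larger right end, then
  lexicographic id for tiling; smaller bin for histogram modes; first
  occurrence for nearest edges/genes via argmin).
* The genome-wide report row is always recomputed from per-chromosome
  rows: counts summed, largest maximized, percentages re-derived from
  summed numerators and denominators — never averages of percentages.
  The packaged published per-chromosome summary is aggregated the same
  way (its own printed genome-wide gene-coverage figure differs from
  what its rows imply by 0.16 percentage points; the recomputed value is
  reported).
* Degenerate inputs: zero clones/genes give empty, well-formed tables;
  an empty hit schedule accepts nothing; an empty ortholog table makes
  all candidates unevaluable rather than guessed; a zero improvement
  baseline reports "undefined", not infinity.
* Simulation experiment sizes in tests and the acceptance script (a
  ~100 Mbp target at ~10× clone coverage, 3–10 replicate seeds per
  claim) were chosen as the smallest configurations at which the
  estimators' sampling noise is clearly inside the tolerances being
  asserted (mode-ratio recovery to ±0.05, breakpoint sensitivity ≥ 90%).

## Known limitations

* The mode-ratio size estimator is quantized by the histogram bin; with
  ~3,000 consistent clones its seed-to-seed spread is about ±0.04 on a
  1.3–1.6 ratio.
* Edge projection uses a single nearest gene; a shuffled or missing
  flanking ortholog flips individual confirmations (the observed ~2/3
  confirmation rate for true spanners is set by which side of an edge
  the nearest gene happens to lie on, a real resolution limit of the
  approach).
* Chimeras joining loci that are genuinely adjacent on the second
  reference are confirmed as if true — the cross-check cannot, even in
  principle, exclude them.
* The greedy tiling path is optimal for the overlap-chain covering
  problem it solves; it does not model clone-fingerprint verification or
  scaffolding across gaps.
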