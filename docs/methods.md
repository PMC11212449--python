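# Methods

## Data model and coordinates

All genomic coordinates are 0-based half-open, so `length == end -
start` everywhere; 1-based inclusive formats (VCF POS, TRF `.dat`,
GFF3) are converted at the boundary.  Genotypes are stored as allele
indices per sample with two slots (the second slot is a sentinel for
haploid calls), which keeps multi-allelic sites and diploid
heterozygous calls representable — both are needed by the QC rules.

## Quality control

Hard filters remove sites with FS > 60, MQ < 50 or SOR > 3 (strict
inequalities) and any site with a missing genotype; absent annotations
pass with a log message unless strict mode is set.  The biological
rules then run per colony, in order, with each discarded site
attributed to its first-failing rule so the report is a partition:

1. lack of polymorphism — fewer than two distinct alleles observed
   across all supplied colonies (queens and drones pooled).  The rule
   is evaluated across colonies, not within one: a site homozygous in
   one colony but segregating elsewhere is discarded by rule 2 there,
   not silently absorbed by rule 1;
2. queen homozygous;
3. heterozygous drone call (drones are haploid; a het call is an
   artefact);
4. replicate-drone discordance (a replicate is the same meiosis
   resequenced, so any disagreement is a genotyping error);
5. cross-colony inconsistency — the colony's observed allele set is
   disjoint from, or extends beyond, the union of queen alleles in the
   other colonies.  The source procedure does not define this
   predicate precisely; this reading is isolated in one function so it
   can be swapped.  With a single colony the rule is skipped with a
   warning;
6. drone allele absent from the queen's two alleles.

Ordering rules 1–3 before the replicate check and 4–5 after mirrors
the order in which the categories are conventionally reported.  The
filter is idempotent: every retained site has a heterozygous queen,
hence stays polymorphic on a second pass.

The assembly-polishing filter is separate: QUAL ≥ 20 and either
homozygous-alt or heterozygous with zero reference-supporting reads
(AD), the standard criterion for base-level consensus correction from
short reads.

## Vectors, bins and phasing

Allele labels at a SNP carry no phase information relative to the
queen's haplotypes, so a site vector and its complement are the same
observation; site vectors are canonicalised (first non-missing drone
= 0) before run detection, and runs absorb missing entries as
wildcards, filling the bin consensus as they go.  Bin length is the
span from first to last member SNP — the only length observable from
the data — so a single-SNP bin has length 0.

Phasing chooses, per bin, the vector or complement closer (Hamming
over mutually non-missing entries) to the previous phased vector,
ties keeping the unflipped vector.  Because flipping any suffix of
bins is itself a valid phase assignment, each junction can be
minimised independently and the greedy pass attains the exhaustive
2^(B−1) minimum; the test suite verifies this against full
enumeration.

## NCO detection

A bin spanning < 2 kb is flagged as a non-crossover conversion tract
when its flanks are identical (the tract is then excised and the
flanks merged into one bin) or when the events entering plus leaving
it exceed the events needed to go from the preceding to the following
bin (the tract is excised, the flanks stay distinct).  First and last
bins are never flagged.  The procedure iterates to a fixed point.

Candidate order matters and is a deliberate choice here: candidates
are processed shortest-first (SNP span, then SNP count, then
position).  A positional left-to-right scan can meet a genuine short
inter-crossover segment whose neighbour is an isolated-error singleton
bin; the singleton makes the segment's flanks look identical and the
scan erases a real crossover.  Removing the shortest candidate first
eliminates the singleton, after which the genuine segment's flanks
differ and it survives.  The merged bin's SNP count excludes the
excised tract's SNPs (their genotypes are conversion artefacts); the
flagged bins are returned separately as the NCO call set.

## Scaffolding

Joining two contig ends costs, per colony informative for both, the
smaller Hamming distance between the end vectors or one vector's
complement (contig phase is free), summed over colonies.  Chains are
built greedily: the cheapest available end pair is joined unless it
reuses an end or closes a cycle, ties broken by more informative
drones then lexicographic contig id.  Contigs without an a-priori
chromosome assignment float: they may join any group, but only
through junctions costing at most 1 recombination in *every*
informative colony (one apparent crossover can be a residual
genotyping error; more is unreliable linkage).  Physical orientation
follows from which ends were joined; a single-bin contig has
identical end vectors, so its orientation is reported unknown unless
its boundary tandem arrays resolve it (exact period match plus
rotation- and strand-aware consensus identity ≥ 95%, via edlib on the
doubled monomer — strand-awareness matters because a flipped contig
reports its terminal monomer reverse-complemented).

An exhaustive solver over all signed orders (n!·2ⁿ/2) validates the
greedy chain for small groups.  Greedy chaining is *not* optimal for
arbitrary cost matrices — a counterexample with i.i.d.-random end
vectors exists — but in meiotically linked data (true junctions cost
≈ 0–2, non-adjacent pairs cost about half the drone count per colony)
the two agree, and the oracle tests draw instances from that regime.

Placement status: `placed` needs both evidence sources (ordered by
crossover data and an a-priori assignment); a chromosome known from
exactly one source is `unlocalised`; neither is `unplaced`.

## Crossover map

Phased bins are projected onto scaffold coordinates (orientation
applied; each contig's global phase complemented when that reduces
the junction distance to the running chain) and one event is emitted
per drone per discordant adjacent-bin pair, on the interval between
the flanking informative SNPs — including pairs that straddle a
contig junction, which is how a wrongly oriented contig manufactures
events.  Windowed rates spread each event's unit mass uniformly over
its localisation interval (midpoint assignment would sharpen peaks
artificially given the interval is all the data offers); the last
window of a chromosome uses its actual size, so window mass times
meioses recovers the event count exactly.  Hotspots are inter-SNP
intervals with strictly more than five pooled events across colonies.
Meioses pool across colonies and replicate drones count once.

## Repeat analytics

Family windows are period 91–93 and 367–371; the selected set uses
the raw (fractional) TRF copy number strictly greater than 10 — the
stricter of the two published thresholds, consistent with the
published selected-array counts.  Monomer canonicalisation uses
Booth's least-rotation algorithm (O(n), deterministic,
enumeration-checkable).  Hit grouping is single-linkage with gap <
period on sorted intervals, equivalent to the quadratic transitive
closure.  Telomere calls match the motif up to rotation and reverse
complement (TTAGG ≡ CCTAA); `terminal` means within 10 kb of a
chromosome end — the sources give no numeric cut-off for
"extremities", and 10 kb separates the two observed regimes (hundreds
of copies terminal vs ≲100 interstitial) by two orders of magnitude.
Non-motif short-period arrays at ends are still reported as
candidates.

## SV genotyping

Flank width defaults to the indel length, floored at 500 bp and
capped at 5 kb — local enough to track coverage trends, wide enough
to stabilise the denominator.  The 1-D 2-means is solved exactly by
enumerating split points over the sorted ratios (prefix sums), which
removes initialisation nondeterminism entirely.  The higher-centre
cluster is "present".  When the relative centre separation
(c₁−c₀)/max(|c₀|,|c₁|) is below 0.3 the clustering is degenerate
(monomorphic panel) and all defined samples receive the dominant call
(present iff the pooled mean ratio ≥ 0.5); the relative form keeps
the non-degenerate behaviour invariant to uniform rescaling of the
ratios.  A diploid no-call band around the midpoint exists but is off
by default — haploid samples have no heterozygous state, so
intermediate ratios are artefacts.

## Simulator: what it emulates, and what it does not

Defaults are the study conditions at desk scale: three colonies of
15/15/13 drones (43 meioses; three drones of colony 1 duplicated as
replicates), queen heterozygous at every site, 1 het-SNP/kb, Poisson
crossovers at 23 cM/Mb with uniform positions and no interference,
one conversion tract per meiosis per chromosome with geometric length
of mean 500 bp (most tracts then fall under the 2 kb detection span,
matching "often shorter than a few kb"), 0.2% genotyping error, and a
genome of four 5 Mb chromosomes (a 220 Mb genome scaled to 20 Mb so a
full run takes seconds).  The repeat landscape plants 131 arrays of
the 371 bp family (74 with > 10 copies, 16 of them long enough to
break the assembly at 4 per chromosome) and 345 of the 91 bp family
(43 selected), giving 20 contigs whose boundaries each carry the two
halves of the interrupting array — the structure the
boundary-orientation logic exploits.  Sequence outside arrays is
uniform random; arrays are exact tandem copies with 1% per-copy
mutation.  A minimal exact-tandem annotator exists solely to build
fixture-scale `.dat` files.  10% of contigs are withheld from the
a-priori assignment table to exercise genotype-only placement.  The
depth simulator draws Poisson(λ) per base over flanks and over
present indels, Poisson(0.02 λ) over absent ones (background
mismapping), for a panel of 35/30/15 haploids with subspecies-typical
presence frequencies for two indels of 745 and 576 bp.

Not emulated: read-level artefacts (mapping bias, duplicated reads,
indel-realignment errors), linkage between SNP ascertainment and
repeat content, crossover interference, per-colony rate
heterogeneity (a single genome-wide rate with optional window
multipliers), and diploid workers.  Passing tests therefore
demonstrate correctness of the inference machinery under the stated
generative model, not robustness to alignment pathology in real
data.

## Known limitations and degenerate cases

- A single-bin contig between two crossover-free regions with the
  same genotype vector is position-ambiguous; the map cannot
  distinguish the candidate junctions (all cost 0) and tie-breaking
  occasionally places such a contig at the wrong zero-cost junction.
  This is an identifiability limit of the data, not of the solver;
  boundary-repeat matching resolves it when terminal arrays differ.
- Two genuine crossovers in the same drone closer than the NCO span
  threshold are indistinguishable from a conversion tract and will be
  removed.
- The genome-wide rate estimate is biased slightly upward by
  conversion tracts that escape the filter (tracts at contig edges or
  split by contig breaks) and slightly downward by crossovers outside
  the terminal informative SNPs; at the default conditions the net
  effect stays within 10% of the simulated rate.
- Windowed rates at chromosome edges divide by the short window's
  actual size, so a sparse terminal window has high variance.
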