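# Methods

## The system being modelled

A synthetic yeast chromosome carries a 34-bp symmetric Cre recombination
site (loxPsym) in the 3'UTR of most non-essential genes. Inducing Cre
("SCRaMbLE") recombines pairs of these palindromic sites; because the site
is its own reverse complement, a single crossover can yield a deletion, an
inversion or a tandem duplication of the intervening block with, in
principle, equal probability. Selection then shapes what is observed:
a rearrangement that removes an *essential segment* — an inter-site
interval containing at least one essential gene, the centromere, or a
telomere — is lethal. Recombined cells are recognised by a reporter
cassette (ReSCuES): two convergent auxotrophic markers (URA3/LEU2) flanked
by two *asymmetric* loxP sites, so Cre flips the cassette and switches
which marker is expressed. The two site classes are orthogonal — loxP
never recombines with loxPsym — so the reporter reads out Cre activity
without touching the synthetic chromosome.

This package implements the full in-silico counterpart: the annotated
chromosome model, the rearrangement/selection/read simulator, the
split-read + depth structural-variant caller with chromosome
reconstruction, and the PCR/segregation verification logic.

## Chromosome model

Coordinates are 0-based, half-open everywhere (BED convention; GFF3 is
converted on read). The loxPsym motifs partition the chromosome: each
motif belongs to the junction between two segments, never to a segment, so
segment lengths plus `n_sites x 34` tile the chromosome exactly. Cre
crossover bookkeeping always leaves exactly one motif at every junction,
and because the motif is palindromic, rendering a path with inverted
segments reproduces every motif byte-identically — which is also why the
exact breakpoint of a real junction is ambiguous anywhere inside the
34 bp.

The motif sequence itself is a configurable default, not an assumption:
any even-length palindrome works, and the scanner
(`scan_lox_sites`) verifies palindromy rather than trusting it.

Viability of a rearranged path requires: every essential segment present
at least once, the centromere-bearing segment present exactly once, and
the two telomeric segments terminal and outward-oriented. Fitness effects
short of lethality are not modelled.

The ReSCuES cassette is represented as a logical marker state
(`URA_on`/`LEU_on`, flip = involution) plus two annotated loxP sites on
the map. The ~300 bp cassette inversion itself is not rendered into the
sequenced genome: it sits at a fixed locus away from the loxPsym system,
its flip is the *expected* reporter event rather than a rearrangement to
be discovered, and rendering it would only add two known loxP-loxP
junctions to every selected strain.

## Synthetic-data generator

`random_chromosome` emulates a large linear synthetic chromosome:

| parameter | default | why |
|---|---|---|
| length / n_sites | 500 kb / 100 | desk-scale stand-in for a multi-Mb chromosome with ~300 sites; the 2.5 Mb / 299-site census fixture uses the real numbers |
| min inter-site spacing | 300 bp | sites sit in 3'UTRs, so blocks are gene-sized; also keeps every block longer than one read |
| telomeres | 500 bp terminal intervals | modelled only as essential elements; subtelomeric repeat structure is out of scope |
| centromere | 120 bp, mid-chromosome segment | point centromere, yeast-like |
| essential layout | n_essential segments incl. the 3 element-bearing ones; essential genes placed to hit an exact (segments, genes) census | reproduces the ~70 essential segments / 109 essential genes census at synXII scale |
| PCRtags | 2 recoded 20-mer primer pairs per megachunk (16 megachunks A–P) | the synthetic/wild-type discrimination markers used for segregation mapping |
| junction primers | one pair per site, ~314 bp amplicon across the motif | the junction-PCR verification panel |

Chance extra copies of the motif elsewhere in the random sequence are
re-randomised away so the designed site list is exactly the truth.

Event sampling: events address junctions of the *current* path, so
composite rearrangements are emergent (two successive overlapping
inversions produce the large relocation pattern seen in real strains), and
every event's junction pair is uniform over the current path with type
probabilities uniform by default — the observed excess of inversions among
survivors should emerge from selection, not be baked in. The number of
events per cell defaults to Poisson(λ=3), reflecting that most
characterised strains carry about three simple events.

Two sampling modes matter:

* **Unconditioned** (`condition_on_viability=False`, default): the raw
  induced population; used for viability statistics and their exact
  enumeration cross-check.
* **Survivor sampling** (`condition_on_viability=True`): each event is
  resampled until the chromosome stays viable *and* total length stays
  within 5% of the reference. This is the sampler for strains picked off a
  selective plate: deletions can only survive in the gaps between
  essential segments, and selected strains keep gene content and
  chromosome length essentially unchanged — unbounded amplifications are
  not observed among survivors of a linear chromosome even though they are
  not lethal in the strict sense. Without the length condition,
  whole-outcome rejection cannot reach, e.g., a five-deletion strain at
  all (a uniform deletion on a 25%-essential map is ~97% lethal).

Reads: single-end, fixed length (200 bp default), uniform start positions
on both strands, read count = `round(depth x genome / read_length)`.
Errors are i.i.d. substitutions; error bases get Phred 2–9, correct bases
20–40, and 10% of reads receive a low-quality 3' tail (5–30 bp, Q<10) to
exercise QC trimming. Not modelled: indels, homopolymer/flowgram errors,
GC bias, PCR duplicates, quality-by-cycle decay. Consequently the
round-trip results certify the calling logic under the stated error model,
not performance on real single-end data, where indel errors would blur
split offsets by a few bases (the 5-bp clustering tolerance is the
designed allowance for exactly that).

## Quality control

In order: reads shorter than 30 bp are removed; reads with more than 1% of
bases under Q10 or with any unknown base have their maximal low-quality/N
3' suffix trimmed once and are removed if they still fail; duplicate
sequences keep one representative. A read counts as "trimmed" only when a
non-empty suffix was actually removed. Note that with error bases always
assigned Q<10, reads with 4+ errors fail the 1% rule and are dropped
(~2% of reads at 0.5% error) — a deliberate coupling that also removes the
error-richest reads before alignment.

## Alignment and split reads

The aligner is authored in-repo because its contract is what the pipeline
depends on: end-to-end, ungapped, exact-20-mer seeding with full-length
verification under a mismatch budget of ceil(3 x L/200), up to 100
candidate placements per read, ties broken by lowest (chromosome,
position). Seeds advance in 20-bp steps until a read resolves, so a read
whose first seed carries an error still maps. Reads with no acceptable
end-to-end placement — junction-spanning reads and error-heavy survivors —
form the unmapped set.

Each unmapped read is split at every offset leaving both ends >= 30 bp
(L − 59 candidate splits). Rather than aligning every end of every split
separately, both read extremities are anchored once per strand (seed
offsets 0 and 7) and per-anchor cumulative mismatch arrays give the score
of *all* splits for an anchor pair in one vector; the best (anchor pair,
offset) minimises total mismatches, tie-broken by mapping class then
leftmost offset. Mapping classes follow the five-priority scheme:
(1) colinear/no recombination — any within-budget colinear split
reclassifies the read and excludes it from junction support, (2) same
chromosome, (3) two wild-type chromosomes, (4) involving a synthetic
chromosome, (5) single-end only.

Breakends carry the junction-adjacent reference coordinate plus a
direction flag (retained sequence 5' or 3' of the locus). A breakend
falling inside a loxPsym motif (padded by the 5-bp error range — chance
base coincidences at the junction can extend the ambiguity a few bases
past the motif) is snapped to the motif start, the canonical choice for an
intrinsically ambiguous position. Junction calling is single-linkage
clustering of breakend pairs sharing the chromosome/direction signature
with both sides within 5 bp; canonical position is the member median;
clusters with fewer than 2 supporting reads are dropped (the minimum
support is a package choice; single-read junctions are noise-prone).

## Depth and copy number

Per-segment mean coverage uses primary whole-read alignments *plus* the
end placements of split reads — reads crossing a novel junction never map
end-to-end, and without their ends a short junction-flanked segment at
four copies can measure below three. Copy number is coverage divided by a
single-copy baseline, rounded; fractional parts in (0.3, 0.7) are flagged
ambiguous. The baseline is the centromere segment's coverage: selection
guarantees exactly one centromere copy, whereas the median segment
coverage (kept as an option) is biased whenever a duplication spans most
of the chromosome. Duplicate-read removal systematically deflates
high-multiplicity segments (identical reads from different copies
collapse), which is the main source of ambiguous flags; reconstruction
therefore retries flagged segments at both roundings.

## Reconstruction

Nodes are segment extremities (left/right end of each segment); edges are
reference adjacencies plus called junctions. A reference adjacency enters
the graph only while both neighbours retain copies *and* at least 2
whole-mapped reads still straddle its motif by 30 bp on each side — the
read-level form of "reference adjacencies minus those contradicted by
depth", and the constraint that eliminates most spurious walks. A
depth-first search (memoised on dead states) enumerates walks from the
left-telomere segment to the right-telomere segment that consume each
segment exactly its copy number of times and traverse every placed
junction at least once. If no walk satisfies all junctions, copy-number
variants for ambiguous segments are tried nearest-first, then the
lowest-support junctions (the false-positive suspects) are dropped one at
a time, with diagnostics.

All consistent walks are reported. Tandem or inverted repeat stacks admit
multiple walks with *identical* adjacency usage — genuinely
indistinguishable by reads shorter than the repeated block — so choosing
silently would be dishonest; instead walks are ranked by how well each
adjacency's traversal count matches its read support (expected straddlers
per traversal = baseline x (L − 94 + 1)/L), then by parsimony (fewest
interpreted rearrangements). The first path is interpreted into canonical
reference-relative calls: maximal zero-copy runs (DEL), maximal
uniformly-amplified runs (DUP, with copy number), maximal
reverse-oriented runs (INV). The same interpreter applied to a truth path
makes simulated and called events comparable even when sequential Cre
events overlap. The evaluation harness (`best_event_comparison`) scores
every reported alternative and keeps the best — the honest reading of a
method that deliberately preserves ambiguity.

## PCR and segregation logic

In-silico PCR is exact-match only (presence and size are used
qualitatively, as on a gel): all inward-facing placements of a primer pair
within the size cap (default 5 kb), on both template orientations, so a
pair inside an inverted block still amplifies at unchanged size — PCR
cannot see an interior inversion, only a junction between the primers.
PCRtag profiling reduces to presence/absence of version-specific pairs.
Segregation mapping demands perfect concordance per tag (synthetic version
present in every tolerant sample, absent from every intolerant one) and
merges maximal concordant runs into candidate regions; no tag-error model.
The backcross fixture generates 2:2 tetrads with one crossover each,
cycling crossover points over every inter-tag interval outside the causal
region, so the mapped region is exactly the causal tag run — on real
tetrad counts the resolution would be whatever the observed crossovers
bound. Recurrence analysis (`locate_common_junction`) intersects the
loxPsym sites used by independent strains' callsets and ranks by count.

## Problem sizes used by the test suite

The round-trip study runs a 500 kb / 100-site / 25-essential-segment
chromosome, 20 survivor outcomes with 3–12 events (one fixed 5-deletion +
7-inversion strain), 30x 200-bp reads at 0.5% error (~75,000 reads per
strain). The viability calibration enumerates the exact two-event space
of a 10-segment toy (~35,000 branches) against 4,000 Monte-Carlo draws.
Selection fractions use populations of 2x10^5 (leak) and 10^4 (induced)
cells. The census fixture is full scale: 2.5 Mb, 299 sites, 70/109
essential segments/genes.

## Known limitations

* Substitution-only reads and ungapped alignment: real data would need an
  indel-tolerant aligner (or the SAM ingestion path) and would lose some
  breakpoint precision.
* Reconstruction is per-chromosome; inter-chromosomal junction classes
  (3–4) are classified and reported but not walked into paths.
* Repeat stacks longer than the read leave Eulerian ambiguity that no
  amount of short-read depth can resolve; the caller reports alternatives
  rather than deciding.
* Viability is binary; growth-rate effects of rearrangements (which the
  length-conservation condition of the survivor sampler only caricatures)
  are not modelled.
* No modelling of rDNA repeat arrays or 3D chromosome structure.
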