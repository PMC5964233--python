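# scramble-suite

Simulate and characterise SCRaMbLEd synthetic yeast chromosomes.

Synthetic yeast chromosomes (Sc2.0) carry hundreds of 34-bp palindromic
loxPsym sites. Inducing Cre recombinase ("SCRaMbLE") recombines random
pairs of them, producing deletions, inversions and tandem duplications of
the intervening segments; selection removes every outcome that loses an
*essential segment* (an inter-site interval holding an essential gene, the
centromere or a telomere). Recombined cells are isolated with a
loxP-flanked URA3/LEU2 flip cassette (ReSCuES) whose inversion switches the
expressed marker — orthogonal to loxPsym, so the reporter never rearranges
the synthetic chromosome itself. The remaining problem, and the one this
package solves end to end, is *genome characterisation*: given short
single-end reads from a survivor strain, work out exactly what its
chromosome now looks like.

The package is for people building or evaluating SCRaMbLE-style
pipelines: it provides both the forward model (annotated chromosome
generator, Cre event simulator with viability selection, read simulator)
and the inverse method (QC → alignment → split-read junction detection →
breakpoint clustering → depth profiling → chromosome reconstruction),
plus the wet-lab-mirroring verification logic (junction PCR, PCRtag
profiling, backcross segregation mapping).

## Method at its core

Reads that fail end-to-end alignment are split into pairwise ends (each
≥ 30 bp) over **all** intermediate positions — L − 2·30 + 1 candidate
splits for an L-bp read — and each end is aligned independently (exact
20-mer seeds, ≤ 3 mismatches per 200 bp, up to 100 candidates). Each split
read takes the most favourable of five mapping classes: no recombination,
intra-chromosome, between wild-type chromosomes, synthetic × wild-type,
single-end. Breakpoints cluster with a 5-bp error range (single linkage,
member median as canonical position; positions inside the palindromic
motif are snapped to its start, since the motif makes them intrinsically
ambiguous). Per-segment read depth — including split-read ends — yields
integer copy numbers n_i against a single-copy baseline anchored on the
centromere segment. Reconstruction then searches the segment-adjacency
multigraph (reference adjacencies that still have straddling reads, plus
called junctions) for walks telomere→telomere using segment i exactly n_i
times and every junction at least once, reports *all* consistent walks,
and interprets the best-supported one as DEL/INV/DUP calls relative to
the reference.

## Worked example

```
$ scramble-suite simulate-genome --length 100000 --n-sites 20 --n-essential 8 \
      --seed 7 --out-prefix toy
synTOY: 100000 bp, 20 loxPsym sites, 21 segments (8 essential, 5 essential genes)

$ scramble-suite scramble --map toy.json --fasta toy.fa --n-events 3 --seed 21 \
      --out-prefix strain1
3 events, viable=True, markers=Leu+

$ cat strain1.events.tsv
order	type	site_i	site_j
0	duplication	3	8
1	inversion	2	20
2	inversion	3	6

$ scramble-suite simulate-reads --fasta strain1.fa --depth 30 --seed 5 \
      --out strain1.fastq
17978 reads -> strain1.fastq

$ scramble-suite call --ref-fasta toy.fa --ref-map toy.json \
      --reads strain1.fastq --out-prefix strain1.calls
5 junctions, 3 events, 1 consistent path(s)

$ grep -v "^##" strain1.calls.vcf
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
synTOY	2759	sv_0	T	<INV>	.	PASS	SVTYPE=INV;END=40548
synTOY	6659	sv_1	C	<DUP>	.	PASS	SVTYPE=DUP;END=26477;CN=2
synTOY	53234	sv_2	A	<INV>	.	PASS	SVTYPE=INV;END=53958
```

The simulated strain underwent a duplication and two overlapping
inversions (`strain1.events.tsv` is the ground truth, as junction indices
of the evolving chromosome). From reads alone the caller finds the five
novel adjacencies (written as BEDPE with split-read support counts), the
copy-number profile (`.bedgraph`), and a single consistent chromosome walk
whose reference-relative interpretation — an inversion of 2,759–40,548, a
two-copy tandem duplication of 6,659–26,477 and an inversion of
53,234–53,958 — is the canonical decomposition of those three overlapping
events. `strain1.calls.fa` is the reconstructed chromosome sequence and
`strain1.calls.callset.json` the full machine-readable call set.

The same objects are available as a library
(`scramble_suite.run_pipeline`, `simulate_scramble`, `predict_amplicons`,
`segregation_map`, …) — the CLI is a thin wrapper.

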