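"""Simulation of SCRaMbLE outcomes, selection and sequencing reads.

This module is the ground-truth generator for the whole pipeline: it builds
annotated toy chromosomes, applies Cre recombination events between symmetric
loxPsym sites (deletion / inversion / tandem duplication), applies the
viability filter imposed by essential segments, models the two-marker
reporter switch used to select recombined cells, and simulates single-end
short reads with substitution errors and low-quality tails.

Events address junctions of the *current* path, so composite rearrangements
(e.g. two successive overlapping inversions) are emergent rather than
primitive.  The reporter cassette's own asymmetric loxP sites never
participate: the two site classes are orthogonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _dna
from ._dna import LOXP, LOXPSYM, as_array, random_dna, revcomp
from .genome_model import (
    ChromosomeMap,
    GeneFeature,
    LoxSite,
    PrimerPair,
    SegmentPath,
    build_segments,
)

EVENT_TYPES = ("deletion", "inversion", "duplication")


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecombinationEvent:
    """One Cre crossover between two loxPsym junctions of the current path.

    ``site_pair`` = (i, j) with i < j are 0-based junction indices on the
    path the event is applied to (junction k sits between path steps k and
    k+1); the block between them is deleted, inverted in place, or tandemly
    duplicated.
    """

    type: str
    site_pair: tuple[int, int]
    order: int = 0

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        i, j = self.site_pair
        if i == j:
            raise ValueError("event must span at least one segment")
        if i > j:
            raise ValueError("site_pair must be ordered (i < j)")

    def as_tuple(self):
        return [self.order, self.type, self.site_pair[0], self.site_pair[1]]


def apply_event(path: SegmentPath, event: RecombinationEvent,
                cmap: ChromosomeMap | None = None) -> SegmentPath:
    """Apply one recombination event; returns a new path."""
    i, j = event.site_pair
    # junction indices live in [0, len(steps) - 2]
    n_junctions = len(path.steps) - 1
    if i < 0 or j > n_junctions - 1:
        raise IndexError(
            f"junction pair {event.site_pair} invalid for path of {len(path.steps)} steps")
    block = path.steps[i + 1:j + 1]
    if not block:
        raise ValueError("event spans zero segments")
    head, tail = path.steps[:i + 1], path.steps[j + 1:]
    if event.type == "deletion":
        steps = head + tail
    elif event.type == "inversion":
        steps = head + [(s, -o) for s, o in reversed(block)] + tail
    else:  # duplication (tandem)
        steps = head + block + block + tail
    return SegmentPath(steps=steps, provenance=path.provenance + [event])


# ---------------------------------------------------------------------------
# viability
# ---------------------------------------------------------------------------

def check_viability(path: SegmentPath, cmap: ChromosomeMap) -> tuple[bool, list[str]]:
    """A rearranged chromosome is viable iff every essential segment is
    retained (>= 1 copy), the centromere-bearing segment is present exactly
    once, and the two telomeric segments cap the path ends pointing outward.
    """
    n = len(cmap.segments)
    counts = path.segment_counts(n)
    reasons: list[str] = []
    for seg in cmap.segments:
        if seg.essential and counts[seg.index] == 0:
            reasons.append(f"essential segment {seg.index} deleted")
    cen = cmap.centromere_segment()
    if cen is not None and counts[cen] != 1:
        reasons.append(f"centromere segment {cen} present {counts[cen]}x")
    if not path.steps:
        reasons.append("empty path")
    else:
        if path.steps[0] != (0, 1):
            reasons.append("left telomere segment not terminal/outward")
        if path.steps[-1] != (n - 1, 1):
            reasons.append("right telomere segment not terminal/outward")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# reporter switch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReSCuESState:
    """On/off state of the convergent URA3/LEU2 flip cassette.

    Exactly one marker is expressed at any time; Cre-mediated inversion
    between the cassette's two asymmetric loxP sites toggles which one.
    """

    orientation: str = "URA_on"  # {"URA_on", "LEU_on"}

    @property
    def ura_plus(self) -> bool:
        return self.orientation == "URA_on"

    @property
    def leu_plus(self) -> bool:
        return self.orientation == "LEU_on"


def rescues_flip(state: ReSCuESState) -> ReSCuESState:
    """Toggle the cassette; an involution, enabling multi-round selection."""
    return ReSCuESState("LEU_on" if state.orientation == "URA_on" else "URA_on")


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

@dataclass
class ScrambleOutcome:
    path: SegmentPath
    events: list[RecombinationEvent]
    viable: bool
    inviability_reasons: list[str]
    rescues: ReSCuESState = field(default_factory=ReSCuESState)


def simulate_scramble(
    cmap: ChromosomeMap,
    n_events: int | None = None,
    type_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int | np.random.Generator = 0,
    event_rate: float = 3.0,
    p_flip: float = 1.0,
    event_types: list[str] | None = None,
    condition_on_viability: bool = False,
    max_length_change: float = 0.05,
    max_event_tries: int = 500,
) -> ScrambleOutcome:
    """Draw one SCRaMbLE outcome.

    Events are drawn uniformly over valid junction pairs of the *current*
    path with types from ``type_probs`` (uniform by default: per-site event
    frequencies should in principle be identical, and the observed excess of
    inversions among survivors is expected to emerge from viability
    filtering, not to be baked in).  ``n_events=None`` draws
    Poisson(``event_rate``); ``event_types`` fixes the exact type sequence
    instead.  Deterministic under a fixed seed.

    ``condition_on_viability`` resamples each event until the chromosome
    stays viable — the sampler for *selected survivors*, where a deletion
    can only survive in the gaps between essential segments.  Survivor
    sampling also rejects events that change total chromosome length by
    more than ``max_length_change`` (selected strains keep gene content and
    chromosome length essentially unchanged; massive amplifications carry a
    fitness cost that colony selection removes even though they are not
    lethal).  Unconditioned sampling (the default) represents the raw
    induced population.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if abs(sum(type_probs) - 1.0) > 1e-9:
        raise ValueError("type_probs must sum to 1")
    if event_types is not None:
        n_events = len(event_types)
    elif n_events is None:
        n_events = int(rng.poisson(event_rate))
    if n_events < 0:
        raise ValueError("n_events must be >= 0")

    seg_len = np.array([s.length for s in cmap.segments], dtype=np.int64)
    ref_len = cmap.length

    def rendered_length(p: SegmentPath) -> int:
        counts = p.segment_counts(len(seg_len))
        return int(counts @ seg_len + (len(p.steps) - 1) * cmap.motif_length)

    path = SegmentPath.reference(cmap)
    events: list[RecombinationEvent] = []
    for order in range(n_events):
        if event_types is not None:
            etype = event_types[order]
        else:
            etype = EVENT_TYPES[int(rng.choice(3, p=type_probs))]
        tries = max_event_tries if condition_on_viability else 1
        applied = None
        for _ in range(tries):
            n_junctions = len(path.steps) - 1
            if n_junctions < 2:
                break
            i, j = sorted(rng.choice(n_junctions, size=2, replace=False).tolist())
            ev = RecombinationEvent(type=etype, site_pair=(int(i), int(j)), order=order)
            candidate = apply_event(path, ev, cmap)
            if not condition_on_viability:
                applied = (candidate, ev)
                break
            if (check_viability(candidate, cmap)[0]
                    and abs(rendered_length(candidate) - ref_len) <= max_length_change * ref_len):
                applied = (candidate, ev)
                break
        if applied is None:
            break
        path, ev = applied[0], applied[1]
        events.append(ev)

    viable, reasons = check_viability(path, cmap)
    state = ReSCuESState()
    if rng.random() < p_flip:
        state = rescues_flip(state)
    return ScrambleOutcome(path=path, events=events, viable=viable,
                           inviability_reasons=reasons, rescues=state)


def simulate_viable_scramble(cmap, n_events, seed, max_tries=10_000, **kw) -> ScrambleOutcome:
    """Rejection-sample outcomes until one survives selection (viable and
    marker-flipped) — the population a selective plate retains."""
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        out = simulate_scramble(cmap, n_events=n_events, seed=rng, **kw)
        if out.viable and out.rescues.leu_plus and len(out.events) == (
                n_events if n_events is not None else len(out.events)):
            return out
    raise RuntimeError("no viable outcome found")


def simulate_population(
    cmap: ChromosomeMap,
    pop_size: int,
    leak_rate: float = 0.0129,
    induced: bool = False,
    p_flip: float = 0.30,
    seed: int = 0,
    event_rate: float = 3.0,
) -> list[tuple[ScrambleOutcome, bool]]:
    """A population of cells under (possibly un-induced) Cre.

    Each cell independently flips the reporter — with probability ``p_flip``
    under induction, else with the leaky ``leak_rate`` — and flipped cells
    undergo recombination.  ``selected`` = viable AND Leu+; cells that never
    flipped are never selected, which is how escapers and mother cells are
    excluded.
    """
    if not 0.0 <= leak_rate <= 1.0:
        raise ValueError("leak_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = p_flip if induced else leak_rate
    flips = rng.random(pop_size) < p
    idle = ScrambleOutcome(path=SegmentPath.reference(cmap), events=[], viable=True,
                           inviability_reasons=[], rescues=ReSCuESState())
    out: list[tuple[ScrambleOutcome, bool]] = []
    for flipped in flips:
        if not flipped:
            out.append((idle, False))
            continue
        o = simulate_scramble(cmap, n_events=None, seed=rng,
                              event_rate=event_rate, p_flip=1.0)
        out.append((o, o.viable and o.rescues.leu_plus))
    return out


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Single-end reads as dense arrays (rows padded to the longest read)."""

    seqs: np.ndarray            # (n, L) uint8 ASCII
    quals: np.ndarray           # (n, L) uint8 Phred scores (not ASCII)
    lengths: np.ndarray         # (n,) int
    ids: list[str]
    source_start: np.ndarray | None = None  # provenance on the source genome
    source_strand: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.lengths)

    def read_seq(self, i: int) -> np.ndarray:
        return self.seqs[i, :self.lengths[i]]

    def read_qual(self, i: int) -> np.ndarray:
        return self.quals[i, :self.lengths[i]]

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self)):
                seq = self.read_seq(i).tobytes().decode("ascii")
                qual = (self.read_qual(i) + 33).tobytes().decode("ascii")
                fh.write(f"@{self.ids[i]}\n{seq}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        ids, seqs, quals = [], [], []
        with open(path) as fh:
            lines = fh.read().splitlines()
        if len(lines) % 4 not in (0,) and lines and lines[-1] == "":
            lines = lines[:-1]
        for rec in range(0, len(lines) - len(lines) % 4, 4):
            head, seq, plus, qual = lines[rec:rec + 4]
            if not head.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ at record {rec // 4}")
            ids.append(head[1:].split()[0])
            seqs.append(as_array(seq))
            quals.append(np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33)
        return cls.from_lists(seqs, quals, ids)

    @classmethod
    def from_lists(cls, seqs, quals, ids) -> "ReadSet":
        n = len(seqs)
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        lmax = int(lengths.max()) if n else 0
        smat = np.full((n, lmax), ord("N"), dtype=np.uint8)
        qmat = np.zeros((n, lmax), dtype=np.uint8)
        for i, (s, q) in enumerate(zip(seqs, quals)):
            smat[i, :len(s)] = s
            qmat[i, :len(q)] = q
        return cls(seqs=smat, quals=qmat, lengths=lengths, ids=list(ids))


def simulate_reads(
    sequence,
    depth: float,
    read_length: int = 200,
    sub_error_rate: float = 0.005,
    lowq_tail_rate: float = 0.10,
    seed: int = 0,
    id_prefix: str = "read",
) -> ReadSet:
    """Uniform single-end reads from both strands with i.i.d. substitution
    errors; a configurable fraction of reads carries a low-quality (Q < 10)
    3' tail to exercise QC trimming.  Read count =
    round(depth * genome_length / read_length).
    """
    seq = as_array(sequence)
    glen = len(seq)
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if read_length > glen:
        raise ValueError("read_length exceeds sequence length")
    rng = np.random.default_rng(seed)
    n = int(round(depth * glen / read_length))
    starts = rng.integers(0, glen - read_length + 1, size=n)
    strands = rng.integers(0, 2, size=n)  # 0 = fwd, 1 = rev

    mat = seq[starts[:, None] + np.arange(read_length)[None, :]].copy()
    rev_rows = strands == 1
    mat[rev_rows] = _dna._COMP[mat[rev_rows]][:, ::-1]

    err = rng.random((n, read_length)) < sub_error_rate
    if err.any():
        codes = _dna.base_codes(mat[err]).astype(np.int64)
        shift = rng.integers(1, 4, size=codes.shape)
        mat[err] = _dna._DECODE[(codes + shift) % 4]

    quals = rng.integers(20, 41, size=(n, read_length)).astype(np.uint8)
    quals[err] = rng.integers(2, 10, size=int(err.sum()))
    tails = rng.random(n) < lowq_tail_rate
    tail_len = rng.integers(5, 31, size=n)
    if tails.any():
        col = np.arange(read_length)[None, :]
        tail_mask = tails[:, None] & (col >= (read_length - tail_len)[:, None])
        quals[tail_mask] = rng.integers(2, 10, size=int(tail_mask.sum()))

    ids = [f"{id_prefix}-{i:07d}" for i in range(n)]
    return ReadSet(seqs=mat, quals=quals,
                   lengths=np.full(n, read_length, dtype=np.int64), ids=ids,
                   source_start=starts, source_strand=strands)


# ---------------------------------------------------------------------------
# chromosome generator
# ---------------------------------------------------------------------------

def random_chromosome(
    length: int = 500_000,
    n_sites: int = 100,
    n_essential: int = 25,
    seed: int = 0,
    n_essential_genes: int | None = None,
    n_nonessential_genes: int | None = None,
    motif: bytes = LOXPSYM,
    min_spacing: int = 300,
    telomere_length: int = 500,
    centromere_length: int = 120,
    with_rescues_cassette: bool = True,
    n_megachunks: int = 16,
    pcrtags_per_megachunk: int = 2,
    junction_primers: bool = True,
    name: str = "synTOY",
) -> ChromosomeMap:
    """Generate an annotated toy synthetic chromosome.

    The layout emulates a large linear synthetic yeast chromosome: hundreds
    of evenly scattered loxPsym motifs (minimum spacing ``min_spacing``),
    telomeric intervals at both ends, one centromere, essential genes
    concentrated so that ``n_essential`` segments are essential, recoded
    PCRtag loci in every megachunk and, optionally, the reporter cassette's
    two asymmetric loxP sites in a non-essential segment.
    """
    rng = np.random.default_rng(seed)
    motif = as_array(motif)
    mlen = len(motif)
    if n_sites * (min_spacing + mlen) + min_spacing > length:
        raise ValueError("chromosome too short for requested sites/spacing")

    seq = random_dna(length, rng)

    # --- site placement: shuffled spacing with a guaranteed minimum gap ----
    slack = length - n_sites * mlen - (n_sites + 1) * min_spacing
    cuts = np.sort(rng.integers(0, slack + 1, size=n_sites))
    positions = (cuts + min_spacing * (np.arange(n_sites) + 1)
                 + mlen * np.arange(n_sites))
    sites = [LoxSite(id=i, position=int(p), length=mlen) for i, p in enumerate(positions)]
    for p in positions:
        seq[p:p + mlen] = motif
    # re-randomise any accidental extra motif copies elsewhere
    _purge_spurious_motifs(seq, motif, set(int(p) for p in positions), rng)

    telomeres = ((0, telomere_length), (length - telomere_length, length))

    # provisional segmentation to place the centromere & genes
    spans = _segment_spans(length, positions, mlen)
    n_segments = len(spans)

    mid = n_segments // 2
    cs, ce = spans[mid]
    c0 = int((cs + ce) // 2 - centromere_length // 2)
    centromere = (c0, c0 + centromere_length)

    # --- essentiality layout ----------------------------------------------
    element_segments = {0, n_segments - 1, mid}
    if n_essential < len(element_segments):
        raise ValueError("n_essential must cover telomeres and centromere")
    candidates = [i for i in range(n_segments) if i not in element_segments
                  and spans[i][1] - spans[i][0] >= 200]
    rng.shuffle(candidates)
    gene_segments = sorted(candidates[:n_essential - len(element_segments)])
    essential_hosts = sorted(set(gene_segments) | element_segments)
    if n_essential_genes is None:
        n_essential_genes = len(gene_segments)
    if n_essential_genes < len(gene_segments):
        raise ValueError("n_essential_genes too small for n_essential segments")

    genes: list[GeneFeature] = []
    hosts = list(gene_segments)
    extra = n_essential_genes - len(gene_segments)
    hosts += [int(h) for h in rng.choice(essential_hosts, size=extra)] if extra else []
    for gi, segidx in enumerate(sorted(hosts)):
        a, b = spans[segidx]
        glen_ = int(min(800, (b - a) - 80))
        if glen_ < 60:
            continue
        off = int(rng.integers(a + 20, b - glen_ - 20))
        genes.append(GeneFeature(name=f"ESG{gi + 1:04d}", start=off, end=off + glen_,
                                 strand="+-"[int(rng.integers(2))], essential=True))
    if n_nonessential_genes is None:
        n_nonessential_genes = max(4, n_segments // 4)
    free = [i for i in range(n_segments)
            if i not in essential_hosts and spans[i][1] - spans[i][0] >= 300]
    for gi in range(n_nonessential_genes):
        if not free:
            break
        segidx = free[int(rng.integers(len(free)))]
        a, b = spans[segidx]
        glen_ = int(min(600, (b - a) - 100))
        off = int(rng.integers(a + 30, b - glen_ - 30))
        genes.append(GeneFeature(name=f"GEN{gi + 1:04d}", start=off, end=off + glen_,
                                 strand="+-"[int(rng.integers(2))], essential=False))

    # --- reporter cassette (two inward asymmetric loxP sites) --------------
    if with_rescues_cassette:
        host = next(i for i in free if spans[i][1] - spans[i][0] >= 3 * mlen + 600)
        a, b = spans[host]
        cass0 = int((a + b) // 2 - 150)
        loxp = as_array(LOXP)
        seq[cass0:cass0 + mlen] = loxp
        seq[cass0 + 300 - mlen:cass0 + 300] = revcomp(loxp)
        nid = len(sites)
        sites.append(LoxSite(id=nid, position=cass0, length=mlen,
                             kind="loxP", orientation="fwd"))
        sites.append(LoxSite(id=nid + 1, position=cass0 + 300 - mlen, length=mlen,
                             kind="loxP", orientation="rev"))

    # --- megachunks & PCR primers ------------------------------------------
    chunk = length / n_megachunks
    megachunks = [(chr(ord("A") + i), int(i * chunk), int(min(length, (i + 1) * chunk)))
                  for i in range(n_megachunks)]

    pcrtags: list[PrimerPair] = []
    order = 0
    for label, a, b in megachunks:
        placed = 0
        tries = 0
        while placed < pcrtags_per_megachunk and tries < 200:
            tries += 1
            x = int(rng.integers(a + 50, max(a + 51, b - 300)))
            if _overlaps_any(x, x + 240, positions, mlen):
                continue
            fwd = seq[x:x + 20].tobytes().decode()
            rev = revcomp(seq[x + 220:x + 240]).tobytes().decode()
            pcrtags.append(PrimerPair(name=f"tag_{label}{placed}", fwd=fwd, rev=rev,
                                      tag_class="pcrtag_syn", order=order, megachunk=label))
            placed += 1
            order += 1

    if junction_primers:
        for s in sites:
            if s.kind != "loxPsym":
                continue
            p = s.position
            if p - 160 < 0 or p + mlen + 160 > length:
                continue
            fwd = seq[p - 150:p - 130].tobytes().decode()
            rev = revcomp(seq[p + mlen + 110:p + mlen + 130]).tobytes().decode()
            label = next((lbl for lbl, a, b in megachunks if a <= p < b), "")
            pcrtags.append(PrimerPair(name=f"jnc_{s.id:04d}", fwd=fwd, rev=rev,
                                      tag_class="junction", order=-1, megachunk=label))

    cmap = ChromosomeMap(name=name, length=length, sequence=seq, sites=sites,
                         genes=genes, centromere=centromere, telomeres=telomeres,
                         pcrtags=pcrtags, megachunks=megachunks, synthetic=True)
    cmap.segments = build_segments(length, sites, genes, centromere, telomeres)
    return cmap


def _segment_spans(length, positions, mlen):
    bounds = [0]
    for p in positions:
        bounds.extend([int(p), int(p) + mlen])
    bounds.append(length)
    return [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]


def _overlaps_any(a, b, positions, mlen):
    for p in positions:
        if a < p + mlen and p < b:
            return True
    return False


def _purge_spurious_motifs(seq, motif, wanted: set[int], rng, max_rounds: int = 10):
    """Re-randomise chance occurrences of the motif outside designed loci."""
    mb = motif.tobytes()
    for _ in range(max_rounds):
        hits = [p for p in _dna.find_all(seq.tobytes(), mb) if p not in wanted]
        hits += [p for p in _dna.find_all(seq.tobytes(), revcomp(motif).tobytes())
                 if p not in wanted]
        if not hits:
            return
        for p in hits:
            if not any(w <= p < w + len(motif) or p <= w < p + len(motif) for w in wanted):
                seq[p:p + len(motif)] = random_dna(len(motif), rng)


# ---------------------------------------------------------------------------
# wild-type counterpart & backcross pools
# ---------------------------------------------------------------------------

def wildtype_variant(cmap: ChromosomeMap, seed: int = 0) -> tuple[np.ndarray, list[PrimerPair]]:
    """A 'native' version of the chromosome: identical except that every
    PCRtag locus is recoded, so version-specific primers can tell the two
    apart.  Returns (wild-type sequence, wild-type PCRtag primer pairs).
    """
    rng = np.random.default_rng(seed)
    wt = cmap.sequence.copy()
    wt_tags: list[PrimerPair] = []
    for tag in cmap.pcrtags:
        if tag.tag_class != "pcrtag_syn":
            continue
        fwd = as_array(tag.fwd)
        hits = _dna.find_all(cmap.sequence.tobytes(), fwd.tobytes())
        if not hits:
            continue
        x = hits[0]
        wt[x:x + 20] = random_dna(20, rng)
        wt[x + 220:x + 240] = random_dna(20, rng)
        wt_tags.append(PrimerPair(name=tag.name, fwd=wt[x:x + 20].tobytes().decode(),
                                  rev=revcomp(wt[x + 220:x + 240]).tobytes().decode(),
                                  tag_class="pcrtag_wt", order=tag.order,
                                  megachunk=tag.megachunk))
    return wt, wt_tags


def simulate_backcross_pools(
    cmap: ChromosomeMap,
    wt_sequence: np.ndarray,
    causal_span: tuple[int, int],
    n_tetrads: int | None = None,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Tetrads from a synthetic x wild-type backcross with Mendelian 2:2
    segregation of a single causal locus.

    The phenotype follows the synthetic allele at the midpoint of
    ``causal_span``.  Each tetrad carries one crossover involving two of
    the four chromatids (two parental plus two recombinant spores);
    crossover points cycle over every inter-tag interval *outside* the
    causal span, so the mapped candidate region — bounded by the nearest
    observed crossovers — comes out as exactly the tags inside the span.
    Returns (tolerant spore genomes, intolerant spore genomes).
    """
    rng = np.random.default_rng(seed)
    tags = sorted((t for t in cmap.pcrtags if t.tag_class == "pcrtag_syn"),
                  key=lambda t: t.order)
    if not tags:
        raise ValueError("map carries no PCRtags")
    tag_pos = [_dna.find_all(cmap.sequence.tobytes(), as_array(t.fwd).tobytes())[0]
               for t in tags]
    causal_point = (causal_span[0] + causal_span[1]) // 2
    in_span = [p for p in tag_pos if causal_span[0] <= p < causal_span[1]]
    lo = min(in_span) if in_span else causal_span[0]
    hi = max(in_span) if in_span else causal_span[1]
    inner = [(a + b) // 2 for a, b in zip(tag_pos, tag_pos[1:])]
    inner = [x for x in inner if not lo <= x <= hi]
    if n_tetrads is None:
        n_tetrads = len(inner)

    syn = cmap.sequence
    tolerant, intolerant = [], []

    def mosaic(cut, left_syn):
        if left_syn:
            return np.concatenate([syn[:cut], wt_sequence[cut:]])
        return np.concatenate([wt_sequence[:cut], syn[cut:]])

    def carries_causal(cut, left_syn):
        return (causal_point < cut) if left_syn else (causal_point >= cut)

    for t in range(n_tetrads):
        cut = inner[t % len(inner)] if inner else cmap.length // 2
        spores = [(syn, True), (wt_sequence, False),
                  (mosaic(cut, True), carries_causal(cut, True)),
                  (mosaic(cut, False), carries_causal(cut, False))]
        for genome, tol in spores:
            (tolerant if tol else intolerant).append(genome)
    return tolerant, intolerant


# ---------------------------------------------------------------------------
# ground-truth serialisation
# ---------------------------------------------------------------------------

def write_events_tsv(path, events: list[RecombinationEvent]) -> None:
    with open(path, "w") as fh:
        fh.write("order\ttype\tsite_i\tsite_j\n")
        for e in events:
            fh.write(f"{e.order}\t{e.type}\t{e.site_pair[0]}\t{e.site_pair[1]}\n")


def read_events_tsv(path) -> list[RecombinationEvent]:
    events = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            o, t, i, j = line.rstrip("\n").split("\t")
            events.append(RecombinationEvent(type=t, site_pair=(int(i), int(j)), order=int(o)))
    return events
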