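"""Structural-variant detection and chromosome reconstruction.

The calling strategy combines read depth with split-read mapping:

1. Read QC — drop reads under 30 bp or duplicated; reads with more than 1%
   of bases below Q10 or with unknown bases are 3'-trimmed once and removed
   if they still fail.
2. End-to-end alignment (substitution-only, up to 100 candidates per read).
3. Unmapped reads are split into pairwise ends (each at least 30 bp) over
   every intermediate position and each end aligned independently.
4. Each split read is assigned the most favourable of five mapping classes:
   (1) no recombination, (2) intra-chromosome, (3) between wild-type
   chromosomes, (4) involving a synthetic chromosome, (5) single-end only.
5. Breakpoints cluster with a 5-bp error range into supported junctions.
6. Per-segment depth yields integer copy numbers; junctions plus copy
   numbers drive a walk through the segment-adjacency multigraph that
   reconstructs the rearranged chromosome and interprets it as deletion /
   inversion / duplication calls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aligner as _al
from ._dna import as_array
from .aligner import Breakend, ReferenceIndex, SplitCall, split_align_read
from .genome_model import ChromosomeMap, SegmentPath
from .synthetic_data import ReadSet

MIN_END = 30
CLUSTER_TOLERANCE = 5
MIN_SUPPORT = 2


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    reads: ReadSet,
    min_length: int = 30,
    lowq_threshold: int = 10,
    max_lowq_frac: float = 0.01,
) -> tuple[ReadSet, dict]:
    """Quality-control filter; returns (cleaned reads, per-rule statistics).

    Rules, in order: reads shorter than ``min_length`` are removed; reads
    with more than ``max_lowq_frac`` of bases under ``lowq_threshold`` or
    with any unknown base are trimmed of their maximal low-quality/N 3'
    suffix and removed if they still fail; duplicated sequences keep one
    representative.
    """
    n = len(reads)
    stats = {"input": n, "removed_short": 0, "removed_quality": 0,
             "removed_duplicate": 0, "trimmed": 0, "output": 0}
    keep_seqs: list[np.ndarray] = []
    keep_quals: list[np.ndarray] = []
    keep_ids: list[str] = []
    keep_src: list[int] = []
    seen: set[bytes] = set()

    lengths = reads.lengths
    cols = np.arange(reads.seqs.shape[1])[None, :]
    valid = cols < lengths[:, None]
    bad_base = ((reads.quals < lowq_threshold) | (reads.seqs == ord("N"))) & valid
    n_bad = bad_base.sum(axis=1)
    has_n = ((reads.seqs == ord("N")) & valid).any(axis=1)
    needs_fix = (n_bad > max_lowq_frac * lengths) | has_n

    for i in range(n):
        L = int(lengths[i])
        if L < min_length:
            stats["removed_short"] += 1
            continue
        seq, qual = reads.read_seq(i), reads.read_qual(i)
        if needs_fix[i]:
            row = bad_base[i, :L]
            # maximal 3' suffix made of low-quality/N bases
            good = np.flatnonzero(~row)
            cut = (good[-1] + 1) if len(good) else 0
            if cut < L:
                seq, qual = seq[:cut], qual[:cut]
                stats["trimmed"] += 1
            L2 = len(seq)
            ok = (L2 >= min_length
                  and not (seq == ord("N")).any()
                  and (qual < lowq_threshold).sum() <= max_lowq_frac * L2)
            if not ok:
                stats["removed_quality"] += 1
                continue
        key = seq.tobytes()
        if key in seen:
            stats["removed_duplicate"] += 1
            continue
        seen.add(key)
        keep_seqs.append(seq)
        keep_quals.append(qual)
        keep_ids.append(reads.ids[i])
        keep_src.append(i)

    out = ReadSet.from_lists(keep_seqs, keep_quals, keep_ids)
    if reads.source_start is not None:
        src = np.array(keep_src, dtype=np.int64)
        out.source_start = reads.source_start[src]
        out.source_strand = reads.source_strand[src]
    stats["output"] = len(out)
    return out, stats


# ---------------------------------------------------------------------------
# alignment wrappers
# ---------------------------------------------------------------------------

def build_index(references: dict[str, np.ndarray] | ChromosomeMap,
                synthetic: set[str] | None = None, k: int = 20) -> ReferenceIndex:
    if isinstance(references, ChromosomeMap):
        cmap = references
        synthetic = {cmap.name} if cmap.synthetic else set()
        references = {cmap.name: cmap.sequence}
    return ReferenceIndex(references, synthetic=synthetic or set(), k=k)


def align_reads(
    reads: ReadSet,
    index: ReferenceIndex,
    max_candidates: int = 100,
    mismatch_rate: float = _al.DEFAULT_MISMATCH_RATE,
) -> tuple[pd.DataFrame, np.ndarray]:
    """End-to-end alignment of a read set.

    Returns an alignment table (one row per candidate, ``primary`` marking
    the best per read) and the indices of unmapped reads.
    """
    r, gpos, strand, mm, unmapped = _al.align_batch(
        index, reads.seqs, reads.lengths,
        mismatch_rate=mismatch_rate, max_candidates=max_candidates)
    ci, local = (np.empty(0, dtype=np.int64),) * 2 if len(r) == 0 else index.to_local(gpos)
    df = pd.DataFrame({
        "read": r,
        "chrom": [index.names[c] for c in ci] if len(r) else [],
        "pos": local,
        "strand": np.where(strand == 0, "+", "-") if len(r) else [],
        "mismatches": mm,
        "length": reads.lengths[r] if len(r) else [],
    })
    primary = np.zeros(len(df), dtype=bool)
    if len(df):
        order = np.lexsort((strand, local, ci, mm, r))
        first = np.ones(len(r), dtype=bool)
        first[1:] = np.diff(r[order]) != 0
        primary[order[first]] = True
    df["primary"] = primary
    return df, unmapped


# ---------------------------------------------------------------------------
# split reads
# ---------------------------------------------------------------------------

def split_read(read, min_end: int = MIN_END) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """All candidate (offset, left end, right end) splits of a read.

    Split offsets run over every intermediate position at least ``min_end``
    from both read ends: L - 2*min_end + 1 candidates for an L-bp read.
    """
    arr = as_array(read)
    L = len(arr)
    if L < 2 * min_end:
        return []
    return [(s, arr[:s], arr[s:]) for s in range(min_end, L - min_end + 1)]


@dataclass(frozen=True)
class EndAlignment:
    chrom: str
    pos: int       # 0-based start of the end's reference interval
    strand: str
    length: int
    mismatches: int = 0


@dataclass
class SplitPair:
    """One split of a read with the candidate placements of its two ends."""

    read_id: str
    offset: int
    left: list[EndAlignment]
    right: list[EndAlignment]
    mapping_type: int | None = None


def classify_split(pair: SplitPair, registry: dict[str, bool]) -> int | None:
    """Assign the most favourable of the five mapping classes.

    ``registry`` maps chromosome name -> is_synthetic.  Returns ``None``
    (discard) when neither end has any placement.
    """
    if not pair.left and not pair.right:
        return None
    if not pair.left or not pair.right:
        pair.mapping_type = 5
        return 5
    best = 5
    for la in pair.left:
        for ra in pair.right:
            if la.chrom == ra.chrom and la.strand == ra.strand:
                colinear = (la.pos + la.length == ra.pos if la.strand == "+"
                            else ra.pos + ra.length == la.pos)
                if colinear:
                    return _set(pair, 1)
            if la.chrom == ra.chrom:
                best = min(best, 2)
            elif not registry.get(la.chrom, False) and not registry.get(ra.chrom, False):
                best = min(best, 3)
            else:
                best = min(best, 4)
    return _set(pair, best)


def _set(pair, value):
    pair.mapping_type = value
    return value


def split_map_unmapped(
    reads: ReadSet,
    unmapped: np.ndarray,
    index: ReferenceIndex,
    min_end: int = MIN_END,
    mismatch_rate: float = _al.DEFAULT_MISMATCH_RATE,
) -> tuple[list[SplitCall], dict]:
    """Best split placement for every unmapped read, plus class statistics."""
    calls: list[SplitCall] = []
    stats = {p: 0 for p in (1, 2, 3, 4, 5)}
    stats["discarded"] = 0
    for ri in unmapped:
        call = split_align_read(index, reads.read_seq(int(ri)), read_id=int(ri),
                                min_end=min_end, mismatch_rate=mismatch_rate)
        if call is None:
            stats["discarded"] += 1
            continue
        stats[call.priority] += 1
        calls.append(call)
    return calls, stats


# ---------------------------------------------------------------------------
# junction clustering
# ---------------------------------------------------------------------------

@dataclass
class Junction:
    """A called novel adjacency between two reference loci."""

    bk1: Breakend
    bk2: Breakend
    support: int
    member_loci: list[tuple[int, int]] = field(default_factory=list)
    reads: list[int] = field(default_factory=list)

    def key(self):
        return (self.bk1.key(), self.bk2.key())


def snap_to_motif(locus: int, site_positions: np.ndarray, motif_length: int,
                  tolerance: int = CLUSTER_TOLERANCE) -> int:
    """Left-shift a breakpoint that falls inside a recombination motif to the
    motif start.

    The palindromic motif makes split offsets ambiguous across its whole
    length, and chance base coincidences flanking the junction can extend
    the ambiguity by a few extra bases, so the snap window is the motif
    padded by the breakpoint error range on both sides.
    """
    if len(site_positions) == 0:
        return locus
    i = int(np.searchsorted(site_positions, locus + tolerance, side="right")) - 1
    if i >= 0 and (site_positions[i] - tolerance <= locus
                   <= site_positions[i] + motif_length + tolerance):
        return int(site_positions[i])
    return locus


def _canonical_pair(b1: Breakend, b2: Breakend) -> tuple[Breakend, Breakend]:
    return (b1, b2) if b1.key() <= b2.key() else (b2, b1)


def call_junctions(
    split_calls: list[SplitCall],
    tolerance: int = CLUSTER_TOLERANCE,
    min_support: int = MIN_SUPPORT,
    sites: dict[str, np.ndarray] | None = None,
    motif_length: int = 34,
) -> list[Junction]:
    """Single-linkage clustering of split-read breakpoints.

    Only junction-class calls (priorities 2-4) enter.  Two observations
    merge when both sides are within ``tolerance`` bp and share the strand
    signature; the canonical position is the member median.  Junctions with
    fewer than ``min_support`` reads are dropped.
    """
    obs = []
    for c in split_calls:
        if c.priority not in (2, 3, 4) or c.left is None or c.right is None:
            continue
        b1, b2 = c.left, c.right
        if sites is not None:
            b1 = Breakend(b1.chrom, snap_to_motif(b1.locus, sites.get(b1.chrom, np.empty(0)),
                                                  motif_length), b1.dir, b1.strand)
            b2 = Breakend(b2.chrom, snap_to_motif(b2.locus, sites.get(b2.chrom, np.empty(0)),
                                                  motif_length), b2.dir, b2.strand)
        b1, b2 = _canonical_pair(b1, b2)
        obs.append((b1, b2, c.read))
    if not obs:
        return []

    # group by signature (chrom+dir of both sides)
    groups: dict[tuple, list[tuple[Breakend, Breakend, int]]] = {}
    for b1, b2, rid in obs:
        sig = (b1.chrom, b1.dir, b2.chrom, b2.dir)
        groups.setdefault(sig, []).append((b1, b2, rid))

    junctions: list[Junction] = []
    for sig, members in groups.items():
        members.sort(key=lambda t: (t[0].locus, t[1].locus))
        parent = list(range(len(members)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                if members[b][0].locus - members[a][0].locus > tolerance:
                    break
                if abs(members[b][1].locus - members[a][1].locus) <= tolerance:
                    parent[find(a)] = find(b)
        clusters: dict[int, list[int]] = {}
        for idx in range(len(members)):
            clusters.setdefault(find(idx), []).append(idx)
        for idxs in clusters.values():
            l1 = int(np.median([members[i][0].locus for i in idxs]))
            l2 = int(np.median([members[i][1].locus for i in idxs]))
            b1 = Breakend(sig[0], l1, sig[1], members[idxs[0]][0].strand)
            b2 = Breakend(sig[2], l2, sig[3], members[idxs[0]][1].strand)
            rids = sorted({members[i][2] for i in idxs})
            if len(rids) >= min_support:
                junctions.append(Junction(
                    bk1=b1, bk2=b2, support=len(rids),
                    member_loci=[(members[i][0].locus, members[i][1].locus) for i in idxs],
                    reads=rids))
    junctions.sort(key=lambda j: j.key())
    return junctions


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    coverage: np.ndarray       # per-segment mean coverage
    copy_number: np.ndarray    # rounded coverage / baseline
    baseline: float
    ambiguous: np.ndarray      # True where the fractional part was 0.3-0.7


def depth_profile(alignments: pd.DataFrame, cmap: ChromosomeMap,
                  baseline: str = "auto",
                  extra_intervals: list[tuple[int, int]] | None = None) -> DepthProfile:
    """Per-segment mean coverage and integer copy number.

    The single-copy baseline defaults to the coverage of the
    centromere-bearing segment: selection guarantees a viable chromosome
    carries exactly one centromere, so that segment is single copy by
    construction, whereas the median per-segment coverage (the ``median``
    method, robust only to a minority of altered segments) is biased when a
    duplication spans most of the chromosome.  Copy numbers round to the
    nearest integer; fractional parts in (0.3, 0.7) are flagged ambiguous.

    ``extra_intervals`` lets split-read end placements contribute coverage:
    reads crossing a novel junction never map end-to-end, so without their
    ends the copy number of short junction-flanked segments is biased down.
    """
    prim = alignments[(alignments["primary"]) & (alignments["chrom"] == cmap.name)]
    if len(prim) == 0 and not extra_intervals:
        raise ValueError("zero coverage on target chromosome")
    diff = np.zeros(cmap.length + 1, dtype=np.int64)
    starts = prim["pos"].to_numpy()
    ends = np.minimum(starts + prim["length"].to_numpy(), cmap.length)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    for a, b in extra_intervals or ():
        a, b = max(int(a), 0), min(int(b), cmap.length)
        if a < b:
            diff[a] += 1
            diff[b] -= 1
    cov = np.cumsum(diff[:-1]).astype(np.float64)

    seg_cov = np.array([cov[s.start:s.end].mean() if s.length else 0.0
                        for s in cmap.segments])
    base = 0.0
    if baseline == "auto":
        cen = cmap.centromere_segment()
        if cen is not None:
            base = float(seg_cov[cen])
    if base <= 0 and baseline in ("auto", "median"):
        base = float(np.median(seg_cov))
    elif baseline == "mean":
        base = float(np.mean(seg_cov))
    if base <= 0:
        raise ValueError("zero baseline coverage")
    ratio = seg_cov / base
    cn = np.rint(ratio).astype(np.int64)
    frac = np.abs(ratio - np.floor(ratio))
    ambiguous = (frac > 0.3) & (frac < 0.7)
    return DepthProfile(coverage=seg_cov, copy_number=cn, baseline=base,
                        ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventCall:
    """A rearrangement relative to the reference: DEL / INV / DUP over a
    reference span (segment-boundary coordinates, bp)."""

    type: str
    start: int
    end: int
    copies: int = 1


@dataclass
class Reconstruction:
    paths: list[SegmentPath]
    events: list[EventCall]
    used_junctions: list[Junction]
    unplaced_junctions: list[Junction]
    diagnostics: list[str] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)

    @property
    def path(self) -> SegmentPath | None:
        return self.paths[0] if self.paths else None


def reference_adjacency_support(alignments: pd.DataFrame, cmap: ChromosomeMap,
                                min_end: int = MIN_END) -> np.ndarray:
    """Reads straddling each loxPsym site by >= ``min_end`` bp on both sides.

    A reference adjacency that survives rearrangement keeps collecting
    whole-mapped reads across its motif; an adjacency destroyed by
    recombination collects none.  This is the depth-side evidence for which
    reference adjacencies remain in the adjacency graph, and for how many
    times a walk should traverse each one.
    """
    pos = cmap.site_positions
    m = cmap.motif_length
    support = np.zeros(len(pos), dtype=np.int64)
    prim = alignments[(alignments["primary"]) & (alignments["chrom"] == cmap.name)]
    starts = prim["pos"].to_numpy()
    ends = starts + prim["length"].to_numpy()
    for k, p in enumerate(pos):
        support[k] = int(((starts <= p - min_end) & (ends >= p + m + min_end)).sum())
    return support


def _junction_extremity(bk: Breakend, cmap: ChromosomeMap) -> tuple[int, str] | None:
    """Map a snapped breakend to a segment extremity: (segment, 'L'|'R').

    A breakend at loxPsym site k with retained sequence on the 5' side exits
    segment k through its right end; with retained sequence 3' it enters
    segment k+1 through its left end.
    """
    if bk.chrom != cmap.name:
        return None
    pos = cmap.site_positions
    if len(pos) == 0:
        return None
    i = int(np.argmin(np.abs(pos - bk.locus)))
    if abs(int(pos[i]) - bk.locus) > CLUSTER_TOLERANCE:
        return None
    return (i, "R") if bk.dir == "+" else (i + 1, "L")


def reconstruct(
    junctions: list[Junction],
    depth: DepthProfile,
    cmap: ChromosomeMap,
    ref_support: np.ndarray | None = None,
    per_use: float | None = None,
    min_support: int = MIN_SUPPORT,
    max_paths: int = 64,
    max_steps: int = 400_000,
) -> Reconstruction:
    """Walk the segment-adjacency multigraph.

    Nodes are segment extremities; edges are the reference adjacencies —
    kept only while both neighbours retain copies and, when straddling-read
    counts (``ref_support``) are available, while at least ``min_support``
    whole-mapped reads still straddle the motif — plus the called novel
    junctions.  The search enumerates walks from the left-telomere segment
    to the right-telomere segment using each segment exactly its copy number
    of times and every placed junction at least once; every consistent walk
    is emitted (ambiguity preserved).  When several walks are consistent,
    they are ranked by how well each adjacency's traversal count matches its
    read support (``per_use`` = expected straddling reads per traversal).
    If no walk satisfies all junctions, junctions are relaxed one at a time
    and a partial reconstruction is reported with diagnostics.
    """
    n = len(cmap.segments)
    cn = depth.copy_number.copy()
    diagnostics: list[str] = []
    placed: list[tuple[int, tuple, tuple]] = []  # (junction idx, extremity, extremity)
    unplaced: list[Junction] = []
    for ji, j in enumerate(junctions):
        e1, e2 = _junction_extremity(j.bk1, cmap), _junction_extremity(j.bk2, cmap)
        if e1 is None or e2 is None or not (0 <= e1[0] < n and 0 <= e2[0] < n):
            unplaced.append(j)
            diagnostics.append(f"junction {j.key()} not at a loxPsym boundary")
            continue
        placed.append((ji, e1, e2))

    if cn[0] < 1 or cn[n - 1] < 1:
        diagnostics.append("telomeric segment lost from depth profile")
        return Reconstruction([], [], [], unplaced, diagnostics)

    required_all = {ji for ji, _, _ in placed}
    n_junc = len(junctions)
    adj: dict[tuple, list[tuple[tuple, int]]] = {}

    def build_graph():
        adj.clear()

        def add_edge(a, b, jid):
            adj.setdefault(a, []).append((b, jid))
            adj.setdefault(b, []).append((a, jid))

        for k in range(n - 1):
            if cn[k] == 0 or cn[k + 1] == 0:
                continue
            if (ref_support is not None and k < len(ref_support)
                    and ref_support[k] < min_support):
                continue  # contradicted: no read straddles this motif any more
            add_edge((k, "R"), (k + 1, "L"), -1)
        for ji, e1, e2 in placed:
            add_edge(e1, e2, ji)

    def search(required: set[int]):
        paths: list[list[tuple[int, int]]] = []
        remaining = cn.copy()
        steps = [0]
        dead: set = set()  # memoized dead states
        used = np.zeros(n_junc + 1, dtype=np.int64)

        def dfs(seg, side) -> int:
            if steps[0] > max_steps or len(paths) >= max_paths:
                return 1  # poisoned: do not memoize as dead
            steps[0] += 1
            remaining[seg] -= 1
            found = 0
            if seg == n - 1 and side == "L":
                if remaining.sum() == 0 and all(used[j] > 0 for j in required):
                    paths.append(None)  # placeholder; filled by caller stack
                    found += 1
                    paths[-1] = list(stack)
            state = (seg, side, remaining.tobytes(),
                     frozenset(j for j in required if used[j] == 0))
            if state in dead:
                remaining[seg] += 1
                return 0
            exit_ext = (seg, "R" if side == "L" else "L")
            for nxt, jid in adj.get(exit_ext, []):
                if remaining[nxt[0]] <= 0:
                    continue
                if jid >= 0:
                    used[jid] += 1
                stack.append((nxt[0], 1 if nxt[1] == "L" else -1))
                found += dfs(nxt[0], nxt[1])
                stack.pop()
                if jid >= 0:
                    used[jid] -= 1
            remaining[seg] += 1
            if found == 0:
                dead.add(state)
            return found

        stack: list[tuple[int, int]] = [(0, 1)]
        dfs(0, "L")
        return paths

    # Copy numbers with an ambiguous fractional part may be off by one (high
    # multiplicities lose coverage to duplicate removal); try both roundings,
    # nearest first.
    ratio = depth.coverage / depth.baseline
    amb = [int(i) for i in np.flatnonzero(depth.ambiguous)][:4]
    variants: list[tuple[float, tuple[int, ...]]] = []
    from itertools import product
    for choice in product(*([math.floor(ratio[i]), math.ceil(ratio[i])] for i in amb)) \
            if amb else [()]:
        dist = sum(abs(ratio[i] - c) for i, c in zip(amb, choice))
        variants.append((dist, tuple(int(max(c, 0)) for c in choice)))
    variants.sort()

    base_cn = cn.copy()
    raw_paths: list = []
    dropped: list[int] = []

    def try_variants(required: set[int]):
        nonlocal cn
        for _, choice in variants:
            cn = base_cn.copy()
            for i, c in zip(amb, choice):
                cn[i] = c
            if cn[0] < 1 or cn[n - 1] < 1:
                continue
            build_graph()
            found = search(required)
            if found:
                return found
        return []

    raw_paths = try_variants(required_all)
    if not raw_paths and required_all:
        # Relax: junctions whose support is far below one traversal's worth
        # of reads are the suspects; drop the weakest first, then pairs.
        from itertools import combinations
        weak = sorted(required_all, key=lambda ji: junctions[ji].support)
        candidates = weak[:4]
        for r in range(1, len(candidates) + 1):
            for drop in combinations(candidates, r):
                raw_paths = try_variants(required_all - set(drop))
                if raw_paths:
                    dropped = list(drop)
                    break
            if raw_paths:
                break
        if dropped:
            diagnostics.append(
                f"no walk satisfies all junctions; dropped {len(dropped)} junction(s)")
    if not raw_paths:
        diagnostics.append("no consistent walk found; partial reconstruction")
        return Reconstruction([], [], [], unplaced, diagnostics)

    seg_paths = [SegmentPath(steps=p) for p in raw_paths]
    scored = [(_usage_score(p, cmap, placed, junctions, ref_support, per_use,
                            min_support),
               len(canonical_events(p, cmap)), p.steps, p) for p in seg_paths]
    scored.sort(key=lambda t: t[:3])
    seg_paths = [t[3] for t in scored]
    events = canonical_events(seg_paths[0], cmap)
    used_j = [junctions[ji] for ji, _, _ in placed if ji not in dropped]
    return Reconstruction(paths=seg_paths, events=events, used_junctions=used_j,
                          unplaced_junctions=unplaced, diagnostics=diagnostics,
                          scores=[t[0] for t in scored])


def _usage_score(path: SegmentPath, cmap, placed, junctions,
                 ref_support, per_use, min_support) -> float:
    """Discrepancy between a walk's adjacency traversal counts and the
    traversal counts implied by read support; 0 is a perfect fit."""
    if per_use is None or per_use <= 0:
        return 0.0
    ref_usage: dict[int, int] = {}
    nov_usage: dict[frozenset, int] = {}
    nov_edges = {frozenset((e1, e2)): ji for ji, e1, e2 in placed}
    nov_support = {frozenset((e1, e2)): junctions[ji].support for ji, e1, e2 in placed}
    steps = path.steps
    for (a, oa), (b, ob) in zip(steps, steps[1:]):
        exit_ext = (a, "R" if oa > 0 else "L")
        enter_ext = (b, "L" if ob > 0 else "R")
        pair = frozenset((exit_ext, enter_ext))
        if (oa > 0 and ob > 0 and b == a + 1) or (oa < 0 and ob < 0 and a == b + 1):
            k = min(a, b)  # reference adjacency at site k
            ref_usage[k] = ref_usage.get(k, 0) + 1
        elif pair in nov_edges:
            nov_usage[pair] = nov_usage.get(pair, 0) + 1
    score = 0.0
    if ref_support is not None:
        for k in range(min(len(ref_support), len(cmap.segments) - 1)):
            est = ref_support[k] / per_use
            score += abs(ref_usage.get(k, 0) - est)
    for pair, sup in nov_support.items():
        score += abs(nov_usage.get(pair, 0) - sup / per_use)
    return score


def canonical_events(path: SegmentPath, cmap: ChromosomeMap) -> list[EventCall]:
    """Interpret a segment path as reference-relative DEL/INV/DUP calls.

    Deletions are maximal runs of absent segments; duplications maximal runs
    of uniformly over-represented segments; inversions maximal runs of
    reverse-oriented steps.  Composite rearrangements decompose into these
    canonical calls, so truth and reconstruction are comparable even when
    successive Cre events overlap.
    """
    n = len(cmap.segments)
    counts = path.segment_counts(n)
    calls: list[EventCall] = []

    def span(i, j):
        return cmap.segments[i].start, cmap.segments[j].end

    # deletions: runs of zero-copy segments
    k = 0
    while k < n:
        if counts[k] == 0:
            j = k
            while j + 1 < n and counts[j + 1] == 0:
                j += 1
            a, b = span(k, j)
            calls.append(EventCall("DEL", a, b))
            k = j + 1
        else:
            k += 1
    # duplications: runs of same multiplicity > 1
    k = 0
    while k < n:
        if counts[k] > 1:
            j = k
            while j + 1 < n and counts[j + 1] == counts[k]:
                j += 1
            a, b = span(k, j)
            calls.append(EventCall("DUP", a, b, copies=int(counts[k])))
            k = j + 1
        else:
            k += 1
    # inversions: maximal reverse-oriented runs in the path
    i = 0
    steps = path.steps
    while i < len(steps):
        if steps[i][1] < 0:
            j = i
            while j + 1 < len(steps) and steps[j + 1][1] < 0:
                j += 1
            segs = [s for s, _ in steps[i:j + 1]]
            a, b = span(min(segs), max(segs))
            calls.append(EventCall("INV", a, b))
            i = j + 1
        else:
            i += 1
    calls.sort(key=lambda c: (c.start, c.end, c.type))
    return calls


# ---------------------------------------------------------------------------
# comparison harness
# ---------------------------------------------------------------------------

@dataclass
class CallComparison:
    precision: float
    recall: float
    n_called: int
    n_truth: int
    matched: int
    breakpoint_errors: list[int]


def compare_callsets(
    called: list[EventCall],
    truth: list[EventCall],
    tolerance: int = CLUSTER_TOLERANCE,
    min_block: int = 0,
) -> CallComparison:
    """Match events by type with both breakpoints within ``tolerance`` bp.

    ``min_block`` restricts the recall denominator to truth events whose
    span exceeds that size (shorter blocks may be intrinsically invisible to
    reads of finite length).
    """
    truth_eval = [t for t in truth if (t.end - t.start) >= min_block]
    unmatched = list(truth)
    matched = 0
    errors: list[int] = []
    matched_truth: list[EventCall] = []
    for c in called:
        hit = None
        for t in unmatched:
            if (t.type == c.type and abs(t.start - c.start) <= tolerance
                    and abs(t.end - c.end) <= tolerance):
                hit = t
                break
        if hit is not None:
            unmatched.remove(hit)
            matched_truth.append(hit)
            matched += 1
            errors.extend([abs(hit.start - c.start), abs(hit.end - c.end)])
    precision = matched / len(called) if called else 1.0
    matched_eval = sum(1 for t in matched_truth if (t.end - t.start) >= min_block)
    recall = matched_eval / len(truth_eval) if truth_eval else 1.0
    return CallComparison(precision=precision, recall=recall, n_called=len(called),
                          n_truth=len(truth_eval), matched=matched,
                          breakpoint_errors=errors)


def best_event_comparison(
    reconstruction: Reconstruction,
    truth_events: list[EventCall],
    cmap: ChromosomeMap,
    tolerance: int = CLUSTER_TOLERANCE,
    min_block: int = 0,
) -> tuple[CallComparison, int]:
    """Score the emitted reconstruction alternatives against the truth.

    Tandemly repeated blocks make some walks data-equivalent (identical
    adjacency usage), so the reconstruction deliberately reports every
    consistent path; evaluation picks the alternative whose canonical event
    set agrees best with the truth.  Returns (comparison, path index).
    """
    best: tuple[CallComparison, int] | None = None
    for i, p in enumerate(reconstruction.paths):
        comp = compare_callsets(canonical_events(p, cmap), truth_events,
                                tolerance=tolerance, min_block=min_block)
        if best is None or (comp.precision + comp.recall
                            > best[0].precision + best[0].recall):
            best = (comp, i)
    if best is None:
        return compare_callsets([], truth_events, tolerance, min_block), -1
    return best


def path_novel_adjacencies(path: SegmentPath) -> list[frozenset]:
    """Extremity pairs of a path's non-reference adjacencies."""
    out = []
    for (a, oa), (b, ob) in zip(path.steps, path.steps[1:]):
        if (oa > 0 and ob > 0 and b == a + 1) or (oa < 0 and ob < 0 and a == b + 1):
            continue
        exit_ext = (a, "R" if oa > 0 else "L")
        enter_ext = (b, "L" if ob > 0 else "R")
        out.append(frozenset((exit_ext, enter_ext)))
    return out


def junction_coordinate_errors(
    junctions: list[Junction],
    truth_path: SegmentPath,
    cmap: ChromosomeMap,
) -> tuple[list[int], int]:
    """Distance (bp) of each called junction's breakends from the loxPsym
    boundaries of the truth path's novel adjacencies; unmatched junction
    count is returned alongside."""
    truth_pairs = set(path_novel_adjacencies(truth_path))
    pos = cmap.site_positions

    def ext_locus(ext):
        k, side = ext
        return int(pos[k]) if side == "R" else int(pos[k - 1])

    errors: list[int] = []
    unmatched = 0
    for j in junctions:
        e1, e2 = _junction_extremity(j.bk1, cmap), _junction_extremity(j.bk2, cmap)
        if e1 is None or e2 is None or frozenset((e1, e2)) not in truth_pairs:
            unmatched += 1
            continue
        errors.append(abs(j.bk1.locus - ext_locus(e1)))
        errors.append(abs(j.bk2.locus - ext_locus(e2)))
    return errors, unmatched


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class CallSet:
    junctions: list[Junction]
    depth: DepthProfile
    reconstruction: Reconstruction
    qc_stats: dict
    split_stats: dict
    alignments: pd.DataFrame | None = None

    @property
    def events(self) -> list[EventCall]:
        return self.reconstruction.events

    @property
    def path(self) -> SegmentPath | None:
        return self.reconstruction.path


def run_pipeline(
    cmap: ChromosomeMap,
    reads: ReadSet,
    min_end: int = MIN_END,
    tolerance: int = CLUSTER_TOLERANCE,
    min_support: int = MIN_SUPPORT,
    max_candidates: int = 100,
    mismatch_rate: float = _al.DEFAULT_MISMATCH_RATE,
    index: ReferenceIndex | None = None,
    keep_alignments: bool = False,
) -> CallSet:
    """QC -> align -> split -> classify -> cluster -> depth -> reconstruct."""
    clean, qc_stats = qc_filter(reads)
    if index is None:
        index = build_index(cmap)
    aln, unmapped = align_reads(clean, index, max_candidates=max_candidates,
                                mismatch_rate=mismatch_rate)
    calls, split_stats = split_map_unmapped(clean, unmapped, index,
                                            min_end=min_end, mismatch_rate=mismatch_rate)
    site_arr = {cmap.name: np.sort(np.array([s.position for s in cmap.sites], dtype=np.int64))}
    junctions = call_junctions(calls, tolerance=tolerance, min_support=min_support,
                               sites=site_arr, motif_length=cmap.motif_length)
    split_cov = []
    for c in calls:
        if c.left is None or c.right is None or c.offset < 0:
            continue
        L = int(clean.lengths[c.read])
        for bk, elen in ((c.left, c.offset), (c.right, L - c.offset)):
            if bk.chrom != cmap.name:
                continue
            iv = (bk.locus - elen, bk.locus) if bk.dir == "+" else (bk.locus, bk.locus + elen)
            split_cov.append(iv)
    depth = depth_profile(aln, cmap, extra_intervals=split_cov)
    ref_support = reference_adjacency_support(aln, cmap, min_end=min_end)
    mean_len = float(clean.lengths.mean()) if len(clean) else 0.0
    window = cmap.motif_length + 2 * min_end
    per_use = depth.baseline * max(mean_len - window + 1, 1.0) / max(mean_len, 1.0)
    rec = reconstruct(junctions, depth, cmap, ref_support=ref_support,
                      per_use=per_use, min_support=min_support)
    return CallSet(junctions=junctions, depth=depth, reconstruction=rec,
                   qc_stats=qc_stats, split_stats=split_stats,
                   alignments=aln if keep_alignments else None)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_bedpe(path, junctions: list[Junction]) -> None:
    with open(path, "w") as fh:
        for i, j in enumerate(junctions):
            s1 = "+" if j.bk1.dir == "+" else "-"
            s2 = "+" if j.bk2.dir == "+" else "-"
            fh.write(f"{j.bk1.chrom}\t{j.bk1.locus}\t{j.bk1.locus + 1}\t"
                     f"{j.bk2.chrom}\t{j.bk2.locus}\t{j.bk2.locus + 1}\t"
                     f"junction_{i}\t{j.support}\t{s1}\t{s2}\n")


def write_vcf(path, events: list[EventCall], cmap: ChromosomeMap) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={cmap.name},length={cmap.length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=CN,Number=1,Type=Integer,Description="Copy number">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, e in enumerate(events):
            ref = "N"
            if cmap.sequence is not None and e.start < cmap.length:
                ref = chr(cmap.sequence[e.start])
            info = f"SVTYPE={e.type};END={e.end}"
            if e.type == "DUP":
                info += f";CN={e.copies}"
            fh.write(f"{cmap.name}\t{e.start + 1}\tsv_{i}\t{ref}\t<{e.type}>\t.\tPASS\t{info}\n")


def write_bedgraph(path, depth: DepthProfile, cmap: ChromosomeMap,
                   value: str = "copy_number") -> None:
    vals = getattr(depth, value)
    with open(path, "w") as fh:
        for seg, v in zip(cmap.segments, vals):
            fh.write(f"{cmap.name}\t{seg.start}\t{seg.end}\t{v}\n")


def callset_to_json(path, callset: CallSet, cmap: ChromosomeMap) -> None:
    d = {
        "junctions": [{"bk1": [j.bk1.chrom, j.bk1.locus, j.bk1.dir],
                       "bk2": [j.bk2.chrom, j.bk2.locus, j.bk2.dir],
                       "support": j.support} for j in callset.junctions],
        "copy_number": callset.depth.copy_number.tolist(),
        "paths": [[list(s) for s in p.steps] for p in callset.reconstruction.paths],
        "events": [{"type": e.type, "start": e.start, "end": e.end, "copies": e.copies}
                   for e in callset.events],
        "diagnostics": callset.reconstruction.diagnostics,
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)
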