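"""Exact-seed short-read aligner and split-end alignment.

End-to-end, ungapped alignment by exact 20-mer seeding and full-length
verification under a mismatch budget (default 3 per 200 bp, scaled to read
length).  Up to ``max_candidates`` alignments are reported per read; ties are
broken by lowest (chromosome, position).  Reads with no acceptable end-to-end
placement form the unmapped set that feeds split-read junction detection.

The aligner is deliberately substitution-only: the read model it serves has
no indels, and ungapped verification keeps the whole pipeline vectorisable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._dna import _COMP, as_array, kmer_code, kmer_codes

GAP_CHAR = ord("^")  # never equal to a base, so windows across gaps self-reject
DEFAULT_K = 20
DEFAULT_MISMATCH_RATE = 3 / 200


def mismatch_budget(length: int, rate: float = DEFAULT_MISMATCH_RATE) -> int:
    return int(math.ceil(rate * length))


class ReferenceIndex:
    """Concatenated multi-chromosome reference with a sorted k-mer index."""

    def __init__(self, chroms: dict[str, np.ndarray], synthetic: set[str] | None = None,
                 k: int = DEFAULT_K, pad: int = 1024):
        self.k = k
        self.pad = pad
        self.names: list[str] = list(chroms)
        self.synthetic = set(synthetic or set())
        parts = [np.full(pad, GAP_CHAR, dtype=np.uint8)]
        self.offsets: dict[str, int] = {}
        self.starts = []
        cursor = pad
        for name, seq in chroms.items():
            seq = as_array(seq)
            self.offsets[name] = cursor
            self.starts.append(cursor)
            parts.append(seq)
            parts.append(np.full(pad, GAP_CHAR, dtype=np.uint8))
            cursor += len(seq) + pad
        self.conc = np.concatenate(parts)
        self.lengths = {n: len(as_array(s)) for n, s in chroms.items()}
        self.starts = np.array(self.starts, dtype=np.int64)

        codes = kmer_codes(self.conc, k)
        valid = np.flatnonzero(codes >= 0)
        order = np.argsort(codes[valid], kind="stable")
        self.sorted_codes = codes[valid][order]
        self.sorted_pos = valid[order]

    # -- coordinate helpers -------------------------------------------------
    def to_local(self, gpos: np.ndarray | int):
        gpos_arr = np.atleast_1d(np.asarray(gpos, dtype=np.int64))
        ci = np.searchsorted(self.starts, gpos_arr, side="right") - 1
        ci = np.clip(ci, 0, len(self.names) - 1)
        local = gpos_arr - self.starts[ci]
        if np.isscalar(gpos) or np.ndim(gpos) == 0:
            return self.names[int(ci[0])], int(local[0])
        return ci, local

    def chrom_index(self, name: str) -> int:
        return self.names.index(name)

    def is_synthetic(self, name: str) -> bool:
        return name in self.synthetic

    # -- seed lookup ---------------------------------------------------------
    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        bad = codes < 0
        lo[bad] = hi[bad] = 0
        return lo, hi

    def seed_positions(self, kmer: np.ndarray, cap: int = 100) -> np.ndarray:
        code = kmer_code(kmer, self.k)
        if code < 0:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self.sorted_codes, code, side="left")
        hi = np.searchsorted(self.sorted_codes, code, side="right")
        return np.sort(self.sorted_pos[lo:hi])[:cap]


# ---------------------------------------------------------------------------
# whole-read batch alignment
# ---------------------------------------------------------------------------

def align_batch(
    index: ReferenceIndex,
    seqs: np.ndarray,
    lengths: np.ndarray,
    mismatch_rate: float = DEFAULT_MISMATCH_RATE,
    max_candidates: int = 100,
    max_passes: int = 8,
):
    """End-to-end alignment of a dense read matrix.

    Returns ``(read, gstart, strand, mm)`` candidate arrays plus the indices
    of reads with no acceptable placement.  Strand 0 aligns the read as
    given, strand 1 its reverse complement.
    """
    n = len(lengths)
    cand_read: list[np.ndarray] = []
    cand_pos: list[np.ndarray] = []
    cand_strand: list[np.ndarray] = []
    cand_mm: list[np.ndarray] = []
    resolved = np.zeros(n, dtype=bool)
    k = index.k
    conclen = len(index.conc)

    for length in np.unique(lengths):
        L = int(length)
        if L < k:
            continue
        rows = np.flatnonzero(lengths == L)
        mat = seqs[rows, :L]
        rc = _COMP[mat][:, ::-1]
        budget = mismatch_budget(L, mismatch_rate)
        live = np.ones(len(rows), dtype=bool)
        offsets = list(range(0, L - k + 1, k))[:max_passes]
        for off in offsets:
            if not live.any():
                break
            sub = np.flatnonzero(live)
            hit_any = np.zeros(len(sub), dtype=bool)
            for strand, m in ((0, mat), (1, rc)):
                window = m[sub, off:off + k]
                codes = _window_codes(window, k)
                lo, hi = index.lookup(codes)
                counts = np.minimum(hi - lo, max_candidates)
                total = int(counts.sum())
                if total == 0:
                    continue
                rep = np.repeat(np.arange(len(sub)), counts)
                csum = np.cumsum(counts)
                inner = np.arange(total) - np.repeat(csum - counts, counts)
                gseed = index.sorted_pos[np.repeat(lo, counts) + inner]
                gstart = gseed - off
                ok = (gstart >= 0) & (gstart + L <= conclen)
                rep, gstart = rep[ok], gstart[ok]
                if len(rep) == 0:
                    continue
                refm = index.conc[gstart[:, None] + np.arange(L)[None, :]]
                mm = (refm != m[sub[rep]]).sum(axis=1)
                acc = mm <= budget
                if acc.any():
                    hit_any[rep[acc]] = True
                    cand_read.append(rows[sub[rep[acc]]])
                    cand_pos.append(gstart[acc])
                    cand_strand.append(np.full(int(acc.sum()), strand, dtype=np.int8))
                    cand_mm.append(mm[acc].astype(np.int32))
            live[sub[hit_any]] = False
        resolved[rows[~live]] = True

    if cand_read:
        read = np.concatenate(cand_read)
        pos = np.concatenate(cand_pos)
        strand = np.concatenate(cand_strand)
        mm = np.concatenate(cand_mm)
        # dedupe (read, pos, strand) keeping min mm; cap per read
        order = np.lexsort((mm, pos, strand, read))
        read, pos, strand, mm = read[order], pos[order], strand[order], mm[order]
        keep = np.ones(len(read), dtype=bool)
        keep[1:] = (np.diff(read) != 0) | (np.diff(pos) != 0) | (np.diff(strand) != 0)
        read, pos, strand, mm = read[keep], pos[keep], strand[keep], mm[keep]
        read, pos, strand, mm = _cap_per_read(read, pos, strand, mm, max_candidates)
    else:
        read = np.empty(0, dtype=np.int64)
        pos = np.empty(0, dtype=np.int64)
        strand = np.empty(0, dtype=np.int8)
        mm = np.empty(0, dtype=np.int32)
    unmapped = np.flatnonzero(~resolved)
    return read, pos, strand, mm, unmapped


def _window_codes(window: np.ndarray, k: int) -> np.ndarray:
    from ._dna import _CODE
    codes = _CODE[window].astype(np.int64)
    bad = (codes == 255).any(axis=1)
    out = codes @ (4 ** np.arange(k, dtype=np.int64))
    out[bad] = -1
    return out


def _cap_per_read(read, pos, strand, mm, cap):
    # sort by (read, mm, pos, strand) then keep first `cap` rows per read
    order = np.lexsort((strand, pos, mm, read))
    read, pos, strand, mm = read[order], pos[order], strand[order], mm[order]
    new_read = np.ones(len(read), dtype=bool)
    new_read[1:] = np.diff(read) != 0
    group = np.cumsum(new_read) - 1
    first = np.zeros(group[-1] + 1 if len(group) else 0, dtype=np.int64)
    np.add.at(first, group, 1)
    rank = np.arange(len(read)) - np.repeat(np.cumsum(first) - first, first)
    keep = rank < cap
    return read[keep], pos[keep], strand[keep], mm[keep]


# ---------------------------------------------------------------------------
# split-end alignment for unmapped reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Breakend:
    """One side of a novel adjacency: the reference coordinate adjacent to
    the junction, with ``dir`` '+' when the retained sequence lies left
    (5') of the locus and '-' when it lies right."""

    chrom: str
    locus: int
    dir: str
    strand: str  # strand of the end alignment ('+' read-as-given)

    def key(self):
        return (self.chrom, self.locus, self.dir)


@dataclass
class SplitCall:
    read: int
    priority: int
    offset: int
    mismatches: int
    left: Breakend | None = None
    right: Breakend | None = None


def split_align_read(
    index: ReferenceIndex,
    seq: np.ndarray,
    read_id: int = 0,
    min_end: int = 30,
    mismatch_rate: float = DEFAULT_MISMATCH_RATE,
    seed_offsets: tuple[int, ...] = (0, 7),
    max_anchors: int = 100,
) -> SplitCall | None:
    """Best split placement of one unmapped read.

    Scans all split offsets with both ends at least ``min_end`` bp, anchoring
    each end by exact seeds on either strand and scoring every (left anchor,
    right anchor, offset) combination by total mismatches.  Ties prefer the
    higher-priority class, then the leftmost offset.  Returns ``None`` when
    neither end can be anchored.
    """
    seq = as_array(seq)
    L = len(seq)
    if L < 2 * min_end:
        return None
    k = index.k
    rc = _COMP[seq][::-1]
    budget = mismatch_budget(L, mismatch_rate)
    conc = index.conc

    def seeds_prefix(arr):
        """Implied full-alignment start positions from seeds near arr[0]."""
        out = set()
        for o in seed_offsets:
            if o + k <= len(arr):
                for p in index.seed_positions(arr[o:o + k], cap=max_anchors):
                    out.add(int(p) - o)
        return sorted(out)[:max_anchors]

    def seeds_suffix(arr):
        """Implied full-alignment start positions from seeds near arr[-1]."""
        n, out = len(arr), set()
        for o in seed_offsets:
            if n - k - o >= 0:
                for p in index.seed_positions(arr[n - k - o:n - o], cap=max_anchors):
                    out.add(int(p) - (n - k - o))
        return sorted(out)[:max_anchors]

    i = np.arange(L)
    # left-end anchors -------------------------------------------------------
    left: list[tuple[str, int, np.ndarray]] = []  # (strand, anchor, cum[s])
    for pL in seeds_prefix(seq):  # forward: read[:s] at conc[pL:pL+s]
        win = conc[np.clip(pL + i, 0, len(conc) - 1)]
        cum = np.concatenate([[0], np.cumsum(seq != win)])
        left.append(("+", pL, cum))
    for gstart in seeds_suffix(rc):  # reverse: read[:s] at conc[pE-s:pE]
        pE = gstart + L
        win = _COMP[conc[np.clip(pE - 1 - i, 0, len(conc) - 1)]]
        cum = np.concatenate([[0], np.cumsum(seq != win)])
        left.append(("-", pE, cum))

    # right-end anchors ------------------------------------------------------
    right: list[tuple[str, int, np.ndarray]] = []  # (strand, anchor, mmR[s])
    for gstart in seeds_suffix(seq):  # forward: read[s:] at [RE-(L-s), RE)
        RE = gstart + L
        win = conc[np.clip(RE - L + i, 0, len(conc) - 1)]
        d = (seq != win).astype(np.int64)
        suf = np.concatenate([np.cumsum(d[::-1])[::-1], [0]])  # suf[s] = sum d[s:]
        right.append(("+", RE, suf))
    for v in seeds_prefix(rc):  # reverse: rc[:L-s] at [v, v+L-s)
        win = conc[np.clip(v + i, 0, len(conc) - 1)]
        e = (rc != win).astype(np.int64)
        cum = np.concatenate([[0], np.cumsum(e)])
        suf = cum[::-1].copy()  # suf[s] = cum[L-s]
        right.append(("-", v, suf))

    if not left and not right:
        return None
    if not left or not right:
        return SplitCall(read=read_id, priority=5, offset=-1, mismatches=-1)

    s_lo, s_hi = min_end, L - min_end
    s_range = np.arange(s_lo, s_hi + 1)
    best = None  # (mm, priority, offset, la, ra)
    colinear_ok = False
    for ls, lanchor, cum in left:
        mmL = cum[s_range]
        for rs, ranchor, suf in right:
            tot = mmL + suf[s_range]
            smin = int(np.argmin(tot))
            mm = int(tot[smin])
            if mm > budget:
                continue
            colinear = (ls == rs and
                        ((ls == "+" and lanchor + L == ranchor) or
                         (ls == "-" and lanchor - L == ranchor)))
            if colinear:
                colinear_ok = True
                continue
            offset = int(s_range[smin])
            prio = _pair_priority(index, ls, lanchor, rs, ranchor, offset, L)
            cand = (mm, prio, offset, (ls, lanchor), (rs, ranchor))
            if best is None or cand[:3] < best[:3]:
                best = cand
    if colinear_ok:
        return SplitCall(read=read_id, priority=1, offset=-1, mismatches=0)
    if best is None:
        return SplitCall(read=read_id, priority=5, offset=-1, mismatches=-1)

    mm, prio, s, (ls, lanchor), (rs, ranchor) = best
    if ls == "+":
        lchrom, llocus = index.to_local(lanchor + s)
        lbk = Breakend(lchrom, llocus, "+", "+")
    else:
        lchrom, llocus = index.to_local(lanchor - s)
        lbk = Breakend(lchrom, llocus, "-", "-")
    if rs == "+":
        rchrom, rlocus = index.to_local(ranchor - (L - s))
        rbk = Breakend(rchrom, rlocus, "-", "+")
    else:
        rchrom, rlocus = index.to_local(ranchor + (L - s))
        rbk = Breakend(rchrom, rlocus, "+", "-")
    return SplitCall(read=read_id, priority=prio, offset=s, mismatches=mm,
                     left=lbk, right=rbk)


def _pair_priority(index, ls, lanchor, rs, ranchor, s, L) -> int:
    lg = lanchor + s if ls == "+" else lanchor - s
    rg = ranchor - (L - s) if rs == "+" else ranchor + (L - s)
    lchrom, _ = index.to_local(lg)
    rchrom, _ = index.to_local(rg)
    if lchrom == rchrom:
        return 2
    lsyn, rsyn = index.is_synthetic(lchrom), index.is_synthetic(rchrom)
    if not lsyn and not rsyn:
        return 3
    return 4
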