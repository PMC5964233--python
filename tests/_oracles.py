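"""Independent oracles used by the test suite.

Everything here is deliberately implemented with plain string/tuple
operations, independent of the package's segment-path machinery, so it can
serve as ground truth for round-trip checks.
"""

from __future__ import annotations

from itertools import combinations

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def naive_motif_scan(seq: str, motif: str) -> list[int]:
    """Sliding-window scan for a motif on either strand, one hit per locus."""
    hits = set()
    m = len(motif)
    rcm = rc(motif)
    for i in range(len(seq) - m + 1):
        w = seq[i:i + m]
        if w == motif or w == rcm:
            hits.add(i)
    return sorted(hits)


def motif_positions(seq: str, motif: str) -> list[int]:
    """Non-overlapping occurrences of an exact motif (forward strand)."""
    out, i = [], 0
    while True:
        i = seq.find(motif, i)
        if i == -1:
            return out
        out.append(i)
        i += len(motif)


def splice_oracle(seq: str, events, motif: str) -> str:
    """Apply recombination events by direct string edits.

    Junctions are re-scanned as motif occurrences in the *current* string
    after every event; the crossover retains exactly one motif copy.
    """
    m = len(motif)
    for ev in events:
        pos = motif_positions(seq, motif)
        i, j = ev.site_pair
        pi, pj = pos[i], pos[j]
        if ev.type == "deletion":
            seq = seq[:pi + m] + seq[pj + m:]
        elif ev.type == "inversion":
            seq = seq[:pi + m] + rc(seq[pi + m:pj]) + seq[pj:]
        elif ev.type == "duplication":
            seq = seq[:pj] + seq[pi:pj] + seq[pj:]
        else:
            raise ValueError(ev.type)
    return seq


# ---------------------------------------------------------------------------
# exhaustive viability enumeration (tuple-based, no package imports)
# ---------------------------------------------------------------------------

def _apply(path: tuple, etype: str, i: int, j: int) -> tuple:
    block = path[i + 1:j + 1]
    head, tail = path[:i + 1], path[j + 1:]
    if etype == "deletion":
        return head + tail
    if etype == "inversion":
        return head + tuple((s, -o) for s, o in reversed(block)) + tail
    return head + block + block + tail


def _viable(path: tuple, essential: set, cen: int, last: int) -> bool:
    segs = [s for s, _ in path]
    present = set(segs)
    if not essential.issubset(present):
        return False
    if segs.count(cen) != 1:
        return False
    return bool(path) and path[0] == (0, 1) and path[-1] == (last, 1)


def enumerate_viable_probability(
    n_segments: int,
    essential: set,
    cen: int,
    n_events: int,
    type_probs=(1 / 3, 1 / 3, 1 / 3),
) -> float:
    """Exact P(viable) after ``n_events`` sequential uniform events.

    Events are uniform over junction pairs of the current path, with the
    given type probabilities; branch probabilities are accumulated exactly.
    """
    last = n_segments - 1
    ref = tuple((k, 1) for k in range(n_segments))
    types = ("deletion", "inversion", "duplication")

    def recurse(path: tuple, depth: int, prob: float) -> float:
        if depth == 0:
            return prob if _viable(path, essential, cen, last) else 0.0
        nj = len(path) - 1
        pairs = list(combinations(range(nj), 2))
        if not pairs:
            return prob if _viable(path, essential, cen, last) else 0.0
        total = 0.0
        for tp, etype in zip(type_probs, types):
            for i, j in pairs:
                child = _apply(path, etype, i, j)
                total += recurse(child, depth - 1, prob * tp / len(pairs))
        return total

    return recurse(ref, n_events, 1.0)


# ---------------------------------------------------------------------------
# geometric PCR oracle
# ---------------------------------------------------------------------------

def geometric_products(path_steps, segments, motif_len, primer_sites, max_product):
    """Amplicon sizes from primer *placements* propagated through a path.

    ``primer_sites`` = (fwd_interval, rev_rc_interval): the reference
    intervals where the forward primer and the reverse-complemented reverse
    primer match.  Each placement is carried into the rearranged genome by
    locating its segment copy/copies and orientation; inward-facing pairs
    within the size cap yield products.  Independent of any sequence scan.
    """
    offsets = []
    cursor = 0
    for idx, (seg, orient) in enumerate(path_steps):
        offsets.append(cursor)
        cursor += segments[seg][1] - segments[seg][0]
        if idx < len(path_steps) - 1:
            cursor += motif_len

    def placements(interval):
        a, b = interval
        out = []
        for (seg, orient), off in zip(path_steps, offsets):
            s0, s1 = segments[seg]
            if a >= s0 and b <= s1:
                if orient > 0:
                    out.append((off + (a - s0), off + (b - s0), "+"))
                else:
                    out.append((off + (s1 - b), off + (s1 - a), "-"))
        return out

    fwd_p = placements(primer_sites[0])
    rev_p = placements(primer_sites[1])
    sizes = set()
    # forward primer on top strand, reverse-primer site downstream, same copy
    for fa, fb, fs in fwd_p:
        for ra, rb, rs in rev_p:
            if fs == "+" and rs == "+" and ra >= fa and rb - fa <= max_product:
                sizes.add(rb - fa)
            # both placements inverted: the pair amplifies the bottom strand
            if fs == "-" and rs == "-" and fa >= ra and fb - ra <= max_product:
                sizes.add(fb - ra)
    return sizes
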