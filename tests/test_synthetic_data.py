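"""Recombination simulation, viability, reporter switch, read simulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import scramble_suite as ss
from scramble_suite import _dna, genome_model as gm, synthetic_data as sd

from _oracles import splice_oracle

MOTIF = _dna.LOXPSYM.decode()


# ---------------------------------------------------------------------------
# event application
# ---------------------------------------------------------------------------

class TestApplyEvent:
    def _ref(self, cmap):
        return gm.SegmentPath.reference(cmap)

    def test_deletion_excises_block(self, mini_map):
        path = sd.apply_event(self._ref(mini_map),
                              sd.RecombinationEvent("deletion", (0, 1)), mini_map)
        assert path.steps == [(0, 1)] + [(k, 1) for k in range(2, 7)]

    def test_inversion_flips_block_in_place(self, mini_map):
        path = sd.apply_event(self._ref(mini_map),
                              sd.RecombinationEvent("inversion", (0, 1)), mini_map)
        assert path.steps[1] == (1, -1)
        rendered = ss.render_sequence(path, mini_map)
        assert len(rendered) == mini_map.length  # inversion conserves length

    def test_duplication_inserts_tandem_copy(self, mini_map):
        path = sd.apply_event(self._ref(mini_map),
                              sd.RecombinationEvent("duplication", (0, 1)), mini_map)
        assert path.steps[:3] == [(0, 1), (1, 1), (1, 1)]
        rendered = ss.render_sequence(path, mini_map)
        block = mini_map.segments[1].length
        assert len(rendered) == mini_map.length + block + 34

    def test_zero_segment_event_rejected(self):
        with pytest.raises(ValueError):
            sd.RecombinationEvent("deletion", (2, 2))

    def test_out_of_range_junction_rejected(self, mini_map):
        with pytest.raises(IndexError):
            sd.apply_event(self._ref(mini_map),
                           sd.RecombinationEvent("deletion", (4, 40)), mini_map)

    @given(st.integers(0, 10_000))
    def test_event_sequences_match_splice_oracle(self, seed):
        """render(apply_all(events)) equals the brute-force string-edit
        oracle for random event lists."""
        rng = np.random.default_rng(seed)
        cmap = ss.random_chromosome(length=20_000, n_sites=5, n_essential=3,
                                    seed=seed % 17, with_rescues_cassette=False,
                                    junction_primers=False, pcrtags_per_megachunk=0)
        path = gm.SegmentPath.reference(cmap)
        events = []
        for order in range(int(rng.integers(1, 5))):
            nj = len(path.steps) - 1
            if nj < 2:
                break
            i, j = sorted(rng.choice(nj, 2, replace=False).tolist())
            ev = sd.RecombinationEvent(
                sd.EVENT_TYPES[int(rng.integers(3))], (int(i), int(j)), order)
            path = sd.apply_event(path, ev, cmap)
            events.append(ev)
        rendered = _dna.to_str(ss.render_sequence(path, cmap))
        assert rendered == splice_oracle(_dna.to_str(cmap.sequence), events, MOTIF)


# ---------------------------------------------------------------------------
# viability
# ---------------------------------------------------------------------------

class TestViability:
    def test_reference_is_viable(self, toy_map):
        ok, reasons = ss.check_viability(gm.SegmentPath.reference(toy_map), toy_map)
        assert ok and reasons == []

    def test_deleting_essential_segment_is_lethal(self, toy_map):
        ess = next(s.index for s in toy_map.segments
                   if s.essential and 0 < s.index < len(toy_map.segments) - 1)
        steps = [(i, 1) for i in range(len(toy_map.segments)) if i != ess]
        ok, reasons = ss.check_viability(gm.SegmentPath(steps=steps), toy_map)
        assert not ok
        assert any(str(ess) in r for r in reasons)

    def test_deleting_nonessential_run_is_viable(self, toy_map):
        """A deletion confined to non-essential segments between two
        essential ones survives (the large viable deletion class)."""
        non = [s.index for s in toy_map.segments
               if not s.essential and 0 < s.index < len(toy_map.segments) - 1]
        drop = non[0]
        steps = [(i, 1) for i in range(len(toy_map.segments)) if i != drop]
        ok, _ = ss.check_viability(gm.SegmentPath(steps=steps), toy_map)
        assert ok

    def test_centromere_duplication_is_lethal(self, toy_map):
        cen = toy_map.centromere_segment()
        steps = [(i, 1) for i in range(len(toy_map.segments))]
        steps.insert(cen + 1, (cen, 1))
        ok, reasons = ss.check_viability(gm.SegmentPath(steps=steps), toy_map)
        assert not ok and any("centromere" in r for r in reasons)

    def test_inverted_telomere_is_lethal(self, toy_map):
        steps = [(i, 1) for i in range(len(toy_map.segments))]
        steps[0] = (0, -1)
        ok, reasons = ss.check_viability(gm.SegmentPath(steps=steps), toy_map)
        assert not ok and any("telomere" in r for r in reasons)

    def test_added_deletion_never_restores_viability(self, toy_map):
        """Viability is monotone: deleting more from an inviable path cannot
        make it viable."""
        rng = np.random.default_rng(4)
        n = len(toy_map.segments)
        ess = next(s.index for s in toy_map.segments if s.essential and 0 < s.index < n - 1)
        steps = [(i, 1) for i in range(n) if i != ess]
        path = gm.SegmentPath(steps=steps)
        assert not ss.check_viability(path, toy_map)[0]
        for _ in range(5):
            nj = len(path.steps) - 1
            if nj < 2:
                break
            i, j = sorted(rng.choice(nj, 2, replace=False).tolist())
            path = sd.apply_event(
                path, sd.RecombinationEvent("deletion", (int(i), int(j))), toy_map)
            assert not ss.check_viability(path, toy_map)[0]


# ---------------------------------------------------------------------------
# reporter switch
# ---------------------------------------------------------------------------

def test_rescues_flip_switches_markers():
    s = sd.ReSCuESState()
    assert s.ura_plus and not s.leu_plus
    flipped = ss.rescues_flip(s)
    assert flipped.leu_plus and not flipped.ura_plus
    assert ss.rescues_flip(flipped) == s  # second round restores the start


def test_exactly_one_marker_on():
    for state in (sd.ReSCuESState("URA_on"), sd.ReSCuESState("LEU_on")):
        assert state.ura_plus != state.leu_plus


# ---------------------------------------------------------------------------
# scramble simulation
# ---------------------------------------------------------------------------

def test_zero_events_is_reference(toy_map):
    out = ss.simulate_scramble(toy_map, n_events=0, seed=1)
    assert out.path.is_reference(len(toy_map.segments))
    assert out.viable and out.events == []


def test_scramble_deterministic_under_seed(toy_map):
    a = ss.simulate_scramble(toy_map, n_events=4, seed=42)
    b = ss.simulate_scramble(toy_map, n_events=4, seed=42)
    assert a.path == b.path
    assert [e.as_tuple() for e in a.events] == [e.as_tuple() for e in b.events]


def test_fixed_event_types_respected(toy_map):
    types = ["deletion"] * 2 + ["inversion"] * 3
    out = sd.simulate_viable_scramble(toy_map, 5, seed=8, event_types=types,
                                      condition_on_viability=True)
    assert [e.type for e in out.events] == types
    assert out.viable


def test_survivor_sampler_conserves_length(toy_map):
    seg_len = np.array([s.length for s in toy_map.segments])
    for seed in range(5):
        out = sd.simulate_viable_scramble(toy_map, 6, seed=seed,
                                          condition_on_viability=True)
        L = len(ss.render_sequence(out.path, toy_map))
        assert abs(L - toy_map.length) <= 0.05 * toy_map.length


def test_events_only_address_loxpsym_junctions(toy_map):
    """Events pair junctions of the segment path, which are loxPsym by
    construction; the cassette's loxP sites are never drawn."""
    n_j = len(toy_map.segments) - 1
    for seed in range(20):
        out = ss.simulate_scramble(toy_map, n_events=3, seed=seed)
        first = out.events[0]
        assert 0 <= first.site_pair[0] < first.site_pair[1] <= n_j - 1


# ---------------------------------------------------------------------------
# population / selection
# ---------------------------------------------------------------------------

def test_population_no_leak_no_selection(toy_map):
    pop = ss.simulate_population(toy_map, 500, leak_rate=0.0, seed=0)
    assert sum(sel for _, sel in pop) == 0


def test_population_leak_selection_fraction(toy_map):
    """Un-induced leak: selected fraction ~ leak_rate x viable fraction."""
    leak = 0.0129
    pop = ss.simulate_population(toy_map, 40_000, leak_rate=leak, seed=1)
    flipped = [o for o, _ in pop if o.rescues.leu_plus]
    selected = sum(sel for _, sel in pop)
    frac_flipped = len(flipped) / len(pop)
    se = np.sqrt(leak * (1 - leak) / len(pop))
    assert abs(frac_flipped - leak) < 4 * se
    viable_frac = np.mean([o.viable for o in flipped])
    expect = frac_flipped * viable_frac
    assert abs(selected / len(pop) - expect) < 1e-9  # selected == flipped & viable
    assert all(o.rescues.leu_plus for o, sel in pop if sel)


def test_population_induction_flip_rate(toy_map):
    pop = ss.simulate_population(toy_map, 5_000, induced=True, p_flip=0.30, seed=2)
    frac = np.mean([o.rescues.leu_plus for o, _ in pop])
    assert abs(frac - 0.30) < 4 * np.sqrt(0.3 * 0.7 / 5_000)


def test_population_rejects_bad_leak(toy_map):
    with pytest.raises(ValueError):
        ss.simulate_population(toy_map, 10, leak_rate=1.5)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

class TestSimulateReads:
    def test_single_perfect_read_is_genome(self):
        rng = np.random.default_rng(3)
        seq = _dna.random_dna(400, rng)
        reads = ss.simulate_reads(seq, depth=1, read_length=400,
                                  sub_error_rate=0.0, lowq_tail_rate=0.0, seed=0)
        assert len(reads) == 1
        got = reads.read_seq(0)
        assert (np.array_equal(got, seq)
                or np.array_equal(got, _dna.revcomp(seq)))

    def test_read_count_formula(self):
        rng = np.random.default_rng(3)
        seq = _dna.random_dna(100_000, rng)
        reads = ss.simulate_reads(seq, depth=30, read_length=200, seed=0)
        assert len(reads) == 15_000  # 30 x 100000 / 200

    def test_observed_error_rate(self):
        rng = np.random.default_rng(5)
        seq = _dna.random_dna(50_000, rng)
        reads = ss.simulate_reads(seq, depth=8, read_length=200,
                                  sub_error_rate=0.01, lowq_tail_rate=0.0, seed=1)
        mism = 0
        total = 0
        for i in range(len(reads)):
            src = seq[reads.source_start[i]:reads.source_start[i] + 200]
            if reads.source_strand[i] == 1:
                src = _dna.revcomp(src)
            mism += int((reads.read_seq(i) != src).sum())
            total += 200
        rate = mism / total
        assert abs(rate - 0.01) < 4 * np.sqrt(0.01 * 0.99 / total)

    def test_fastq_deterministic_and_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        seq = _dna.random_dna(5_000, rng)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        ss.simulate_reads(seq, depth=5, read_length=100, seed=7).to_fastq(p1)
        ss.simulate_reads(seq, depth=5, read_length=100, seed=7).to_fastq(p2)
        assert p1.read_bytes() == p2.read_bytes()  # byte-identical under seed
        back = sd.ReadSet.from_fastq(p1)
        assert len(back) == 250
        assert back.ids[0].startswith("read-")

    def test_malformed_fastq_reports_record(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r0\nACGT\n+\nII\n")  # qual length mismatch
        with pytest.raises(ValueError, match="record 0"):
            sd.ReadSet.from_fastq(p)

    def test_lowq_tail_fraction(self):
        rng = np.random.default_rng(2)
        seq = _dna.random_dna(60_000, rng)
        reads = ss.simulate_reads(seq, depth=5, read_length=200,
                                  sub_error_rate=0.0, lowq_tail_rate=0.2, seed=3)
        tails = sum(1 for i in range(len(reads))
                    if (reads.read_qual(i)[-5:] < 10).all())
        frac = tails / len(reads)
        assert abs(frac - 0.2) < 4 * np.sqrt(0.2 * 0.8 / len(reads))


# ---------------------------------------------------------------------------
# ground-truth serialisation
# ---------------------------------------------------------------------------

def test_events_tsv_roundtrip(tmp_path):
    evs = [sd.RecombinationEvent("deletion", (1, 3), 0),
           sd.RecombinationEvent("inversion", (0, 5), 1)]
    p = tmp_path / "ev.tsv"
    sd.write_events_tsv(p, evs)
    back = sd.read_events_tsv(p)
    assert [(e.type, e.site_pair, e.order) for e in back] == \
        [(e.type, e.site_pair, e.order) for e in evs]
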