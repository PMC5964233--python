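"""QC rules, split enumeration, classification, clustering, depth,
reconstruction and the comparison harness."""

import numpy as np
import pytest

import scramble_suite as ss
from scramble_suite import _dna, genome_model as gm, sv_caller as sv
from scramble_suite import synthetic_data as sd
from scramble_suite.aligner import Breakend, SplitCall
from scramble_suite.synthetic_data import ReadSet


def _reads(entries):
    """entries: list of (seq str, qual value or list)."""
    seqs, quals = [], []
    for seq, q in entries:
        arr = _dna.as_array(seq)
        if isinstance(q, int):
            qv = np.full(len(arr), q, dtype=np.uint8)
        else:
            qv = np.array(q, dtype=np.uint8)
        seqs.append(arr)
        quals.append(qv)
    return ReadSet.from_lists(seqs, quals, [f"r{i}" for i in range(len(seqs))])


BASE = "ACGTTGCA" * 30  # 240 bp of clean sequence to slice from


class TestQcFilter:
    def test_short_read_removed(self):
        clean, stats = sv.qc_filter(_reads([(BASE[:25], 30), (BASE[:40], 30)]))
        assert stats["removed_short"] == 1
        assert len(clean) == 1 and clean.lengths[0] == 40

    def test_duplicates_keep_one(self):
        clean, stats = sv.qc_filter(_reads([(BASE[:100], 30)] * 2))
        assert stats["removed_duplicate"] == 1
        assert len(clean) == 1

    def test_lowq_tail_trimmed_then_retained(self):
        """100 bp with 2 low-quality bases confined to the 3' tail: 2% > 1%
        pre-trim, 0/98 post-trim -> trimmed to 98 bp and kept."""
        qual = [30] * 98 + [5, 5]
        clean, stats = sv.qc_filter(_reads([(BASE[:100], qual)]))
        assert stats["trimmed"] == 1 and stats["removed_quality"] == 0
        assert len(clean) == 1 and clean.lengths[0] == 98

    def test_scattered_lowq_removed(self):
        qual = [30] * 100
        for p in (10, 40, 70):
            qual[p] = 4
        clean, stats = sv.qc_filter(_reads([(BASE[:100], qual)]))
        assert stats["removed_quality"] == 1 and len(clean) == 0

    def test_n_in_tail_trimmed_midread_removed(self):
        tail_n = BASE[:98] + "NN"
        mid_n = BASE[:50] + "N" + BASE[51:100]
        clean, stats = sv.qc_filter(_reads([(tail_n, 30), (mid_n, 30)]))
        assert len(clean) == 1
        assert clean.lengths[0] == 98
        assert not (clean.read_seq(0) == ord("N")).any()
        assert stats["removed_quality"] == 1

    def test_exactly_one_percent_not_trimmed(self):
        qual = [30] * 198 + [5, 5]  # 2/200 = 1%, not more
        clean, stats = sv.qc_filter(_reads([((BASE * 2)[:200], qual)]))
        assert stats["trimmed"] == 0 and clean.lengths[0] == 200


class TestSplitRead:
    @pytest.mark.parametrize("length,expected", [(200, 141), (60, 1), (100, 41)])
    def test_split_count_formula(self, length, expected):
        splits = sv.split_read("A" * length)
        assert len(splits) == expected  # L - 2*30 + 1

    def test_below_twice_min_end_no_splits(self):
        assert sv.split_read("A" * 59) == []

    def test_split_ends_partition_read(self):
        read = BASE[:80]
        for offset, left, right in sv.split_read(read):
            assert 30 <= offset <= 50
            assert _dna.to_str(left) + _dna.to_str(right) == read


class TestClassifySplit:
    REG = {"syn": True, "wt1": False, "wt2": False}

    def _pair(self, left, right):
        return sv.SplitPair(read_id="r", offset=100, left=left, right=right)

    def test_colinear_is_priority_one(self):
        pair = self._pair([sv.EndAlignment("syn", 1_000, "+", 100)],
                          [sv.EndAlignment("syn", 1_100, "+", 100)])
        assert sv.classify_split(pair, self.REG) == 1

    def test_same_chromosome_distant_is_two(self):
        pair = self._pair([sv.EndAlignment("syn", 1_000, "+", 100)],
                          [sv.EndAlignment("syn", 41_000, "-", 100)])
        assert sv.classify_split(pair, self.REG) == 2

    def test_wildtype_pair_is_three_synthetic_cross_is_four(self):
        wt = self._pair([sv.EndAlignment("wt1", 0, "+", 100)],
                        [sv.EndAlignment("wt2", 0, "+", 100)])
        assert sv.classify_split(wt, self.REG) == 3
        xs = self._pair([sv.EndAlignment("syn", 0, "+", 100)],
                        [sv.EndAlignment("wt2", 0, "+", 100)])
        assert sv.classify_split(xs, self.REG) == 4

    def test_single_end_is_five_neither_discard(self):
        assert sv.classify_split(self._pair([sv.EndAlignment("syn", 0, "+", 100)], []),
                                 self.REG) == 5
        assert sv.classify_split(self._pair([], []), self.REG) is None


def _call(l1, d1, l2, d2, read, chrom="c"):
    return SplitCall(read=read, priority=2, offset=100, mismatches=0,
                     left=Breakend(chrom, l1, d1, "+"),
                     right=Breakend(chrom, l2, d2, "+"))


class TestCallJunctions:
    def test_within_tolerance_merges(self):
        calls = [_call(10_000, "+", 50_000, "-", 0),
                 _call(10_003, "+", 50_002, "-", 1)]
        out = sv.call_junctions(calls, tolerance=5, min_support=2)
        assert len(out) == 1
        assert out[0].support == 2
        assert out[0].bk1.locus == 10_001  # median of members (int)

    @pytest.mark.parametrize("delta", [6, 7])
    def test_beyond_tolerance_splits(self, delta):
        calls = [_call(10_000, "+", 50_000, "-", 0),
                 _call(10_000 + delta, "+", 50_000, "-", 1)]
        out = sv.call_junctions(calls, tolerance=5, min_support=1)
        assert len(out) == 2

    def test_exactly_five_apart_merges(self):
        calls = [_call(10_000, "+", 50_000, "-", 0),
                 _call(10_005, "+", 50_005, "-", 1)]
        assert len(sv.call_junctions(calls, tolerance=5, min_support=1)) == 1

    def test_different_strand_signature_never_merges(self):
        calls = [_call(10_000, "+", 50_000, "-", 0),
                 _call(10_000, "-", 50_000, "+", 1)]
        assert len(sv.call_junctions(calls, tolerance=5, min_support=1)) == 2

    def test_min_support_filters(self):
        calls = [_call(10_000, "+", 50_000, "-", 0)]
        assert sv.call_junctions(calls, min_support=2) == []

    def test_empty_input(self):
        assert sv.call_junctions([]) == []

    def test_clustering_idempotent(self):
        calls = [_call(10_000 + i, "+", 50_000 + i, "-", i) for i in range(4)]
        once = sv.call_junctions(calls, tolerance=5, min_support=1)
        again_calls = [
            SplitCall(read=0, priority=2, offset=0, mismatches=0,
                      left=j.bk1, right=j.bk2) for j in once]
        twice = sv.call_junctions(again_calls, tolerance=5, min_support=1)
        assert [(j.bk1.locus, j.bk2.locus) for j in twice] == \
            [(j.bk1.locus, j.bk2.locus) for j in once]

    def test_snap_to_motif_canonicalizes(self):
        sites = {"c": np.array([9_990, 50_000])}
        calls = [_call(9_990, "+", 50_000, "-", 0),
                 _call(10_020, "+", 50_030, "-", 1)]
        out = sv.call_junctions(calls, min_support=2, sites=sites, motif_length=34)
        assert len(out) == 1 and out[0].bk1.locus == 9_990


class TestDepthProfile:
    def _pipeline(self, event=None, seed=0):
        cmap = ss.random_chromosome(length=50_000, n_sites=8, n_essential=3,
                                    seed=21, with_rescues_cassette=False,
                                    junction_primers=False)
        path = gm.SegmentPath.reference(cmap)
        if event is not None:
            path = sd.apply_event(path, event, cmap)
        genome = ss.render_sequence(path, cmap)
        reads = ss.simulate_reads(genome, depth=25, read_length=200,
                                  sub_error_rate=0.002, seed=seed)
        cs = sv.run_pipeline(cmap, reads)
        return cmap, path, cs

    def test_unrearranged_all_single_copy(self):
        cmap, _, cs = self._pipeline()
        assert (cs.depth.copy_number == 1).all()

    def test_deleted_segment_copy_zero(self):
        cmap, path, cs = self._pipeline(sd.RecombinationEvent("deletion", (2, 3)))
        assert cs.depth.copy_number[3] == 0
        assert (np.delete(cs.depth.copy_number, 3) == 1).all()

    def test_duplicated_block_copy_two(self):
        cmap, path, cs = self._pipeline(sd.RecombinationEvent("duplication", (4, 6)))
        assert list(cs.depth.copy_number[5:7]) == [2, 2]

    def test_depth_conservation(self):
        """Sum of copy number x segment length tracks rendered genome length
        within 10% at this coverage."""
        for ev in (None, sd.RecombinationEvent("duplication", (1, 3)),
                   sd.RecombinationEvent("deletion", (5, 6))):
            cmap, path, cs = self._pipeline(ev)
            seg_len = np.array([s.length for s in cmap.segments])
            modeled = int(cs.depth.copy_number @ seg_len)
            rendered = len(ss.render_sequence(path, cmap)) \
                - (len(path.steps) - 1) * cmap.motif_length
            assert abs(modeled - rendered) <= 0.10 * rendered

    def test_zero_coverage_rejected(self):
        cmap = ss.random_chromosome(length=50_000, n_sites=8, n_essential=3, seed=21)
        import pandas as pd
        empty = pd.DataFrame({"read": [], "chrom": [], "pos": [], "strand": [],
                              "mismatches": [], "length": [], "primary": []})
        with pytest.raises(ValueError):
            sv.depth_profile(empty, cmap)


class TestReconstruct:
    def _run(self, event_specs, seed=3):
        cmap = ss.random_chromosome(length=60_000, n_sites=10, n_essential=4,
                                    seed=31, with_rescues_cassette=False,
                                    junction_primers=False)
        path = gm.SegmentPath.reference(cmap)
        for ev in event_specs:
            path = sd.apply_event(path, ev, cmap)
        genome = ss.render_sequence(path, cmap)
        reads = ss.simulate_reads(genome, depth=30, read_length=200,
                                  sub_error_rate=0.005, seed=seed)
        cs = sv.run_pipeline(cmap, reads)
        return cmap, path, cs

    def test_no_junctions_flat_depth_reference(self):
        cmap, path, cs = self._run([])
        assert cs.junctions == []
        assert cs.path == path
        assert cs.events == []

    def test_single_inversion_roundtrip(self):
        ev = sd.RecombinationEvent("inversion", (3, 6))
        cmap, path, cs = self._run([ev])
        assert cs.path == path
        assert len(cs.events) == 1
        call = cs.events[0]
        assert call.type == "INV"
        assert call.start == cmap.segments[4].start
        assert call.end == cmap.segments[6].end

    def test_deletion_plus_duplication_roundtrip(self):
        evs = [sd.RecombinationEvent("deletion", (1, 2), 0),
               sd.RecombinationEvent("duplication", (5, 7), 1)]
        cmap, path, cs = self._run(evs)
        assert cs.path == path
        assert sorted(e.type for e in cs.events) == ["DEL", "DUP"]


class TestCompareCallsets:
    E = sv.EventCall

    def test_identical_sets_perfect(self):
        evs = [self.E("DEL", 100, 500), self.E("INV", 900, 2_000)]
        comp = sv.compare_callsets(evs, list(evs))
        assert comp.precision == comp.recall == 1.0
        assert comp.breakpoint_errors == [0, 0, 0, 0]

    def test_twelve_of_twelve_recalled(self):
        truth = [self.E("INV", i * 1_000, i * 1_000 + 400) for i in range(12)]
        comp = sv.compare_callsets(list(truth), truth)
        assert comp.recall == 1.0 and comp.matched == 12

    def test_spurious_call_costs_precision(self):
        truth = [self.E("INV", i * 1_000, i * 1_000 + 400) for i in range(12)]
        called = truth + [self.E("DEL", 90_000, 90_300)]
        comp = sv.compare_callsets(called, truth)
        assert comp.precision == pytest.approx(12 / 13)
        assert comp.recall == 1.0

    def test_breakpoints_beyond_tolerance_unmatched(self):
        truth = [self.E("DEL", 1_000, 2_000)]
        called = [self.E("DEL", 1_007, 2_000)]
        comp = sv.compare_callsets(called, truth, tolerance=5)
        assert comp.matched == 0

    def test_min_block_restricts_recall_denominator(self):
        truth = [self.E("DEL", 0, 150), self.E("DEL", 1_000, 2_000)]
        called = [self.E("DEL", 1_000, 2_000)]
        comp = sv.compare_callsets(called, truth, min_block=200)
        assert comp.recall == 1.0 and comp.precision == 1.0


def test_writers_produce_wellformed_text(tmp_path, mini_map):
    ev = sd.RecombinationEvent("deletion", (0, 1))
    path = sd.apply_event(gm.SegmentPath.reference(mini_map), ev, mini_map)
    genome = ss.render_sequence(path, mini_map)
    reads = ss.simulate_reads(genome, depth=25, read_length=200,
                              sub_error_rate=0.002, seed=5)
    cs = sv.run_pipeline(mini_map, reads)
    sv.write_bedpe(tmp_path / "j.bedpe", cs.junctions)
    sv.write_vcf(tmp_path / "e.vcf", cs.events, mini_map)
    sv.write_bedgraph(tmp_path / "d.bedgraph", cs.depth, mini_map)
    sv.callset_to_json(tmp_path / "c.json", cs, mini_map)

    bedpe = (tmp_path / "j.bedpe").read_text().strip().splitlines()
    assert all(len(line.split("\t")) == 10 for line in bedpe)
    vcf = (tmp_path / "e.vcf").read_text().splitlines()
    assert vcf[0] == "##fileformat=VCFv4.2"
    records = [l for l in vcf if not l.startswith("#")]
    assert any("SVTYPE=DEL" in r for r in records)
    bg = (tmp_path / "d.bedgraph").read_text().strip().splitlines()
    assert len(bg) == len(mini_map.segments)
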