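import numpy as np
import pysam
import pytest

from nomehic import bsreads, contexts, simulate
from nomehic.bsreads import (
    AnchorPairSet,
    MethylCall,
    AlignedEnd,
    classify_pair,
    call_read_methylation,
    is_incompletely_converted,
    load_linked_pairs,
)
from nomehic.contexts import GenomeSequence, build_context_index

# reference laid out by hand:  pos:  0123456789
# TAGCAATCGA -> C at 3 is GCH (G,A); C at 7 is WCG (T,G); G at 8 carries the
# minus-strand CG partner (context WCG)
REF = "TAGCAATCGA"


@pytest.fixture(scope="module")
def ref_index():
    return build_context_index(GenomeSequence({"chr1": REF}))


def make_read(
    seq,
    start=0,
    chrom="chr1",
    qual=40,
    mapq=60,
    conv="CT",
    name="r1",
    flag=0x1 | 0x2 | 0x40,
):
    header = pysam.AlignmentHeader.from_references(["chr1", "chr2"], [10_000, 10_000])
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = header.get_tid(chrom)
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigartuples = [(0, len(seq))]
    a.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * len(seq))
    a.set_tag("XG", conv)
    return a


class TestCallReadMethylation:
    def test_ot_c_is_methylated(self, ref_index):
        calls = call_read_methylation(make_read(REF), "OT", ref_index)
        gch = [c for c in calls if c.position == 3]
        assert gch[0].label == "GCH" and gch[0].methylated

    def test_ot_t_is_unmethylated(self, ref_index):
        seq = REF[:3] + "T" + REF[4:]
        calls = call_read_methylation(make_read(seq), "OT", ref_index)
        gch = [c for c in calls if c.position == 3]
        assert not gch[0].methylated

    def test_low_base_quality_dropped(self, ref_index):
        calls = call_read_methylation(make_read(REF, qual=4), "OT", ref_index)
        assert calls == []
        calls = call_read_methylation(make_read(REF, qual=6), "OT", ref_index)
        assert calls != []

    def test_ob_reports_minus_strand(self, ref_index):
        # G at 8 (minus-strand C): read G -> methylated, read A -> unmethylated
        calls = call_read_methylation(make_read(REF), "OB", ref_index)
        by_pos = {c.position: c for c in calls}
        assert by_pos[8].strand == "-" and by_pos[8].methylated
        seq = REF[:8] + "A" + REF[9:]
        calls = call_read_methylation(make_read(seq), "OB", ref_index)
        assert not {c.position: c for c in calls}[8].methylated

    def test_mismatch_base_skipped(self, ref_index):
        seq = REF[:3] + "G" + REF[4:]  # neither C nor T at the GCH site
        calls = call_read_methylation(make_read(seq), "OT", ref_index)
        assert 3 not in {c.position for c in calls}

    def test_gcg_calls_excluded_from_summaries(self):
        idx = build_context_index(GenomeSequence({"chr1": "AGCGAT" + "A" * 4}))
        end_calls = call_read_methylation(make_read("AGCGAT" + "A" * 4), "OT", idx)
        gcg = [c for c in end_calls if c.position == 2]
        assert gcg[0].label == "GCG" and gcg[0].methylated
        end = AlignedEnd("chr1", 0, 10, 60, "OT", calls=end_calls)
        # the ambiguous GCG call contributes to neither GCH nor HCG totals
        assert end.summarize(frozenset({"GCH"})) == (0, 0)
        assert end.summarize(frozenset({"WCG", "CCG"})) == (0, 0)

    def test_fast_and_general_paths_agree(self, ref_index):
        read = make_read(REF)
        general = call_read_methylation(read, "OT", ref_index)
        fast = bsreads._call_fast(read, "OT", ref_index, 5)
        assert general == fast

    def test_unknown_conversion_strand_rejected(self, ref_index):
        with pytest.raises(bsreads.ReadError):
            call_read_methylation(make_read(REF), "XX", ref_index)


class TestConversionFilter:
    def _wch_calls(self, n_meth, n_unmeth):
        mk = lambda i, m: MethylCall("chr1", i, "+", "WCH", m, 40)
        return [mk(i, True) for i in range(n_meth)] + [
            mk(100 + i, False) for i in range(n_unmeth)
        ]

    def test_threshold_reached(self):
        assert is_incompletely_converted(self._wch_calls(3, 2))

    def test_below_threshold(self):
        assert not is_incompletely_converted(self._wch_calls(2, 3))
        assert not is_incompletely_converted(self._wch_calls(0, 5))
        assert not is_incompletely_converted([])

    def test_cch_not_counted(self):
        calls = [MethylCall("chr1", i, "+", "CCH", True, 40) for i in range(5)]
        assert not is_incompletely_converted(calls)


class TestLoadLinkedPairs:
    def _pair(self, mapq2=60, chrom2="chr1", start2=5000, dup=False, name="p"):
        r1 = make_read(REF, start=0, name=name)
        r2 = make_read(
            REF, start=start2, chrom=chrom2, mapq=mapq2, name=name,
            flag=0x1 | 0x2 | 0x80 | (0x400 if dup else 0),
        )
        return [r1, r2]

    def test_long_range_classification(self, ref_index):
        pairs = load_linked_pairs(self._pair(start2=25_000), ref_index)
        assert pairs[0].pair_class == "CIS_LONG"
        assert pairs[0].separation == 25_000 + len(REF)

    def test_short_range_classification(self, ref_index):
        pairs = load_linked_pairs(self._pair(start2=500), ref_index)
        assert pairs[0].pair_class == "CIS_SHORT"

    def test_trans_classification(self, ref_index):
        pairs = load_linked_pairs(self._pair(chrom2="chr2"), ref_index)
        assert pairs[0].pair_class == "TRANS" and pairs[0].separation is None

    def test_low_mapq_pair_dropped(self, ref_index):
        stats = {}
        pairs = load_linked_pairs(self._pair(mapq2=10), ref_index, stats=stats)
        assert pairs == [] and stats["fail_mapq"] == 1

    def test_mapq_boundary_is_exclusive(self, ref_index):
        assert load_linked_pairs(self._pair(mapq2=30), ref_index) == []
        assert len(load_linked_pairs(self._pair(mapq2=31), ref_index)) == 1

    def test_duplicates_dropped(self, ref_index):
        stats = {}
        pairs = load_linked_pairs(self._pair(dup=True), ref_index, stats=stats)
        assert pairs == [] and stats["fail_duplicate"] == 1

    def test_unmated_counted(self, ref_index):
        stats = {}
        load_linked_pairs([make_read(REF)], ref_index, stats=stats)
        assert stats["unmated"] == 1

    def test_classification_symmetric_in_end_order(self, ref_index):
        fwd = load_linked_pairs(self._pair(start2=25_000), ref_index)
        rev = load_linked_pairs(self._pair(start2=25_000)[::-1], ref_index)
        assert fwd[0].pair_class == rev[0].pair_class
        assert fwd[0].separation == rev[0].separation


class TestAnchorAssignment:
    @pytest.fixture()
    def anchors(self):
        return AnchorPairSet.from_records(
            [("chr1", 0, 1000, "chr1", 30_000, 31_000)]
        )

    def _mk_pair(self, s1, s2, chrom2="chr1"):
        e1 = AlignedEnd("chr1", s1, s1 + 100, 60, "OT")
        e2 = AlignedEnd(chrom2, s2, s2 + 100, 60, "OT")
        cls, sep = classify_pair(e1, e2)
        return bsreads.LinkedReadPair("m", e1, e2, cls, sep)

    def test_one_end_in_each_anchor(self, anchors):
        out = bsreads.assign_pairs_to_anchor_pairs(
            [self._mk_pair(100, 30_500)], anchors
        )
        assert len(out["ap0"]) == 1

    def test_either_orientation(self, anchors):
        out = bsreads.assign_pairs_to_anchor_pairs(
            [self._mk_pair(30_500, 100)], anchors
        )
        assert len(out["ap0"]) == 1

    def test_both_ends_same_anchor_not_assigned(self, anchors):
        out = bsreads.assign_pairs_to_anchor_pairs(
            [self._mk_pair(100, 600)], anchors
        )
        assert out["ap0"] == []

    def test_no_overlap_unassigned(self, anchors):
        out = bsreads.assign_pairs_to_anchor_pairs(
            [self._mk_pair(5_000, 50_000)], anchors
        )
        assert out["ap0"] == []


class TestOnSimulatedData:
    def test_all_retained_calls_pass_quality_gates(self, small_pairs):
        pairs, _ = small_pairs
        assert pairs
        for p in pairs:
            for end in p.ends():
                assert end.mapq > 30
                assert all(c.base_quality > 5 for c in end.calls)

    def test_conversion_filter_matches_planted_failures(self):
        """Reads planted with >= 3 failed WCH conversions are exactly the
        ones the conversion filter removes (no sequencing error)."""
        cfg = simulate.SimulationConfig(
            seed=11,
            genome_length=200_000,
            n_anchor_pairs=4,
            n_pairs_per_anchor=60,
            conversion_failure=0.02,
            sequencing_error=0.0,
        )
        ds = simulate.simulate_linked_readpairs(cfg)
        pairs = bsreads.load_linked_pairs(ds.reads, ds.index)
        kept = {p.name for p in pairs}
        truth = ds.truth.molecules
        should_drop = set(
            truth.mol_id[
                (truth.wch_failures1 >= 3) | (truth.wch_failures2 >= 3)
            ]
        )
        assert kept == set(truth.mol_id) - should_drop

    def test_open_state_emission_rate_recovered(self, small_dataset, small_pairs):
        """GCH methylation among open-state ends matches p_open within
        binomial tolerance."""
        pairs, _ = small_pairs
        truth = small_dataset.truth.molecules.set_index("mol_id")
        meth = total = 0
        for p in pairs:
            row = truth.loc[p.name]
            if row.kind != "long":
                continue
            for end, state in ((p.end1, row.state1), (p.end2, row.state2)):
                if state == 1:
                    m, t = end.summarize(frozenset({"GCH"}))
                    meth += m
                    total += t
        frac = meth / total
        se = np.sqrt(0.8 * 0.2 / total)
        assert abs(frac - 0.8) < 4 * se + 0.01


def test_bedpe_round_trip(tmp_path, small_dataset):
    path = tmp_path / "loops.bedpe"
    small_dataset.anchors.to_bedpe(str(path))
    loaded = AnchorPairSet.from_bedpe(str(path))
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    assert loaded.rows[cols].equals(small_dataset.anchors.rows[cols])
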