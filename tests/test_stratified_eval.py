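import math

import pytest

from qualstrat import (
    AlignmentRecord,
    BaseOutcome,
    ReadRecord,
    classify_alignment_bases,
    mapped_fraction,
    stratify,
    summarize,
    symbol_distribution,
)
from qualstrat.stratified_eval import (
    ConsistencyError,
    StratifiedCounts,
    SymbolTally,
    UnresolvableMatchError,
    md_aligned_columns,
)


def _aln(cigar, seq, read_id="r1", flags=0, pos=1, qual=None, tags=None):
    return AlignmentRecord(read_id=read_id, flags=flags, reference_name="ref",
                           position=pos, cigar=cigar, seq=seq, qual=qual, tags=tags)


def _counts_by_outcome(triples):
    out = {o: 0 for o in BaseOutcome}
    for _, _, outcome in triples:
        out[outcome] += 1
    return out


class TestClassify:
    def test_toy_mixed_cigar(self):
        """2S 3= 1X 2= 1I 2= over an 11-base read: 7/1/1/2."""
        read = ReadRecord("r1", "A" * 11, "I" * 11)
        aln = _aln((("S", 2), ("=", 3), ("X", 1), ("=", 2), ("I", 1), ("=", 2)),
                   seq="A" * 11)
        by = _counts_by_outcome(classify_alignment_bases(aln, read))
        assert by[BaseOutcome.MATCHED] == 7
        assert by[BaseOutcome.MISMATCHED] == 1
        assert by[BaseOutcome.INSERTED] == 1
        assert by[BaseOutcome.CLIPPED] == 2

    def test_forward_symbols_in_order(self):
        read = ReadRecord("r1", "ACGT", "!#%5")
        aln = _aln((("=", 4),), seq="ACGT")
        triples = classify_alignment_bases(aln, read)
        assert triples == [
            (0, "!", BaseOutcome.MATCHED),
            (1, "#", BaseOutcome.MATCHED),
            (2, "%", BaseOutcome.MATCHED),
            (3, "5", BaseOutcome.MATCHED),
        ]

    def test_reverse_strand_positions_mapped_back(self):
        # read ACGT, stored as revcomp ACGT -> ACGT; use asymmetric read
        read = ReadRecord("r1", "AACG", "!#%5")
        stored = "CGTT"  # revcomp of AACG
        aln = _aln((("=", 1), ("X", 3),), seq=stored, flags=16)
        triples = classify_alignment_bases(aln, read)
        # stored position 0 ('C', matched) is read position 3 (symbol '5')
        assert triples[3] == (3, "5", BaseOutcome.MATCHED)
        assert triples[0] == (0, "!", BaseOutcome.MISMATCHED)

    def test_hard_clip_recovered_from_original(self):
        read = ReadRecord("r1", "AAACGT", "!!!###")
        aln = _aln((("H", 2), ("=", 4)), seq="ACGT")
        by = _counts_by_outcome(classify_alignment_bases(aln, read))
        assert by[BaseOutcome.CLIPPED] == 2
        assert by[BaseOutcome.MATCHED] == 4

    def test_m_resolved_via_md(self):
        read = ReadRecord("r1", "ACGTAC", "IIIIII")
        aln = _aln((("M", 6),), seq="ACGTAC", tags={"MD": "3T2"})
        triples = classify_alignment_bases(aln, read)
        assert triples[3][2] is BaseOutcome.MISMATCHED
        assert sum(t[2] is BaseOutcome.MATCHED for t in triples) == 5

    def test_m_resolved_via_reference(self):
        read = ReadRecord("r1", "ACGTAC", "IIIIII")
        aln = _aln((("M", 6),), seq="ACGTAC")
        reference = {"ref": "ACCTAC"}
        triples = classify_alignment_bases(aln, read, reference)
        assert triples[2][2] is BaseOutcome.MISMATCHED
        assert sum(t[2] is BaseOutcome.MATCHED for t in triples) == 5

    def test_reference_n_column_counts_as_mismatch(self):
        read = ReadRecord("r1", "ACGT", "IIII")
        aln = _aln((("M", 4),), seq="ACGT")
        triples = classify_alignment_bases(aln, read, {"ref": "ANGT"})
        assert triples[1][2] is BaseOutcome.MISMATCHED

    def test_m_without_md_or_reference_aborts(self):
        read = ReadRecord("r1", "ACGT", "IIII")
        aln = _aln((("M", 4),), seq="ACGT")
        with pytest.raises(UnresolvableMatchError, match="r1"):
            classify_alignment_bases(aln, read)

    def test_seq_disagreement_detected(self):
        read = ReadRecord("r1", "ACGT", "IIII")
        aln = _aln((("=", 4),), seq="TTTT")
        with pytest.raises(ConsistencyError):
            classify_alignment_bases(aln, read)

    def test_deletion_consumes_no_read_base(self):
        read = ReadRecord("r1", "ACGT", "IIII")
        aln = _aln((("=", 2), ("D", 3), ("=", 2)), seq="ACGT")
        triples = classify_alignment_bases(aln, read)
        assert len(triples) == 4
        assert all(t[2] is BaseOutcome.MATCHED for t in triples)


class TestMdColumns:
    @pytest.mark.parametrize("md,expected", [
        ("6", [None] * 6),
        ("3T2", [None, None, None, "T", None, None]),
        ("0A5", ["A"] + [None] * 5),
        ("2^ACG2", [None, None, None, None]),
    ])
    def test_expansion(self, md, expected):
        assert md_aligned_columns(md) == expected

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            md_aligned_columns("3T^")


class TestSymbolDistribution:
    def test_small_example(self):
        dist = symbol_distribution([ReadRecord("a", "AC", "!5"), ReadRecord("b", "G", "!")])
        assert dist.per_symbol == {"!": pytest.approx(2 / 3), "5": pytest.approx(1 / 3)}
        assert dist.n_total == 3

    def test_single_symbol(self):
        dist = symbol_distribution([ReadRecord("a", "ACGT", "????")])
        assert dist.per_symbol == {"?": 1.0}

    def test_fractions_sum_to_one(self, small_simulation):
        _, _, reads, _ = small_simulation
        dist = symbol_distribution(reads)
        assert math.isclose(sum(dist.per_symbol.values()), 1.0, abs_tol=1e-9)

    def test_matches_simulator_profile(self, small_simulation):
        """Empirical symbol fractions within 3 sigma of the sampling profile."""
        _, model, reads, _ = small_simulation
        dist = symbol_distribution(reads)
        n = dist.n_total
        for symbol, p in model.symbol_profile.items():
            sigma = math.sqrt(p * (1 - p) / n)
            # aligned bases, clipped flanks and insertions all draw their
            # symbol from the profile, so the whole read set follows it
            assert abs(dist.per_symbol[symbol] - p) <= 3 * sigma

    def test_quality_less_read_rejected(self):
        with pytest.raises(ValueError):
            symbol_distribution([ReadRecord("a", "ACGT")])


class TestStratify:
    def test_fully_matched_read(self):
        read = ReadRecord("r1", "ACGT", "????")
        aln = _aln((("=", 4),), seq="ACGT")
        counts = stratify([aln], [read])
        t = counts.per_symbol["?"]
        assert (t.matched, t.mismatched, t.inserted, t.clipped) == (4, 0, 0, 0)
        assert t.total_in_fastq == 4
        assert t.total_in_mapped_reads == 4

    def test_unmapped_only_read_set(self):
        read = ReadRecord("r1", "ACGT", "????")
        aln = AlignmentRecord("r1", 4, None, 0, ())
        counts = stratify([aln], [read])
        t = counts.per_symbol["?"]
        assert t.outcome_total == 0
        assert t.total_in_fastq == 4
        assert t.total_in_mapped_reads == 0

    def test_secondary_and_supplementary_skipped(self):
        read = ReadRecord("r1", "ACGT", "????")
        primary = _aln((("=", 4),), seq="ACGT")
        secondary = _aln((("=", 4),), seq="ACGT", flags=256)
        supp = _aln((("=", 2), ("S", 2)), seq="ACGT", flags=2048)
        counts = stratify([primary, secondary, supp], [read])
        assert counts.per_symbol["?"].matched == 4
        assert counts.per_symbol["?"].outcome_total == 4

    def test_missing_read_id_is_error(self):
        aln = _aln((("=", 4),), seq="ACGT", read_id="ghost")
        with pytest.raises(KeyError, match="ghost"):
            stratify([aln], [ReadRecord("r1", "ACGT", "????")])

    def test_conservation_on_simulation(self, small_simulation):
        import os
        import tempfile

        from qualstrat import emit_truth_sam, read_sam

        reference, _, reads, truths = small_simulation
        with tempfile.TemporaryDirectory() as d:
            sam = os.path.join(d, "truth.sam")
            emit_truth_sam(truths, reads, reference, sam)
            counts = stratify(read_sam(sam), reads)
        counts.check_conservation()  # raises on violation
        for t in counts.per_symbol.values():
            assert t.outcome_total == t.total_in_mapped_reads

    def test_conservation_violation_detected(self):
        counts = StratifiedCounts(per_symbol={"?": SymbolTally(matched=3, total_in_mapped_reads=4)})
        with pytest.raises(AssertionError):
            counts.check_conservation()


class TestMappedFraction:
    def test_fully_matched_symbol(self):
        counts = StratifiedCounts(per_symbol={
            "?": SymbolTally(matched=10, total_in_fastq=10, total_in_mapped_reads=10)})
        assert mapped_fraction(counts) == {"?": 1.0}

    def test_never_aligned_symbol(self):
        counts = StratifiedCounts(per_symbol={"!": SymbolTally(total_in_fastq=50)})
        assert mapped_fraction(counts) == {"!": 0.0}

    def test_half_clipped_symbol(self):
        counts = StratifiedCounts(per_symbol={
            "5": SymbolTally(matched=5, clipped=5, total_in_fastq=10,
                             total_in_mapped_reads=10)})
        assert mapped_fraction(counts) == {"5": 0.5}


class TestSummarize:
    def test_toy_single_read(self):
        read = ReadRecord("r1", "A" * 11, "I" * 11)
        aln = _aln((("S", 2), ("=", 3), ("X", 1), ("=", 2), ("I", 1), ("=", 2)),
                   seq="A" * 11)
        s = summarize([aln], [read])
        assert s.mapped_pct == 81.82
        assert s.match_pct == 77.78
        assert s.sub_pct == 11.11
        assert s.ins_pct == 11.11
        assert s.del_pct == 0.0

    def test_error_free(self):
        read = ReadRecord("r1", "ACGT", "????")
        s = summarize([_aln((("=", 4),), seq="ACGT")], [read])
        assert (s.mapped_pct, s.match_pct) == (100.0, 100.0)
        assert s.sub_pct == s.del_pct == s.ins_pct == 0.0

    def test_percentages_sum_to_100(self, small_simulation):
        import os
        import tempfile

        from qualstrat import emit_truth_sam, read_sam

        reference, _, reads, truths = small_simulation
        with tempfile.TemporaryDirectory() as d:
            sam = os.path.join(d, "truth.sam")
            emit_truth_sam(truths, reads, reference, sam)
            s = summarize(read_sam(sam), reads)
        assert s.match_pct + s.sub_pct + s.del_pct + s.ins_pct == pytest.approx(100.0, abs=0.02)
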