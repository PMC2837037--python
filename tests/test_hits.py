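import numpy as np
import pandas as pd
import pytest

from bacmap import hits as H
from bacmap.errors import InputError, LiftError
from bacmap.hits import AlignmentHit, AnchorRecord
from bacmap.simulate import BLAST_COLUMNS, SimConfig, simulate_experiment


def hit(read="r1", chrom="chr01", start=100, end=800, strand="+",
        evalue=1e-50, bitscore=100.0, **kw):
    return AlignmentHit(read, chrom, start, end, strand, evalue, bitscore,
                        **kw)


class TestFilterUnique:
    def test_accepts_clearly_unique_best(self):
        best, reason = H.filter_unique(
            [hit(evalue=1e-20), hit(start=5000, end=5700, evalue=1e-10)],
            evalue_cutoff=1e-5, ratio_threshold=1e5)
        assert reason is None and best.evalue == 1e-20

    def test_rejects_ambiguous_when_ratio_fails(self):
        best, reason = H.filter_unique(
            [hit(evalue=1e-6), hit(start=5000, end=5700, evalue=1e-4)],
            evalue_cutoff=1e-5, ratio_threshold=1e5)
        assert best is None and reason == "ambiguous"

    def test_rejects_single_hit_above_cutoff(self):
        best, reason = H.filter_unique([hit(evalue=1e-4)],
                                       evalue_cutoff=1e-5)
        assert best is None and reason == "above_cutoff"

    def test_zero_evalue_uses_floor_substitution(self):
        # oracle: substitute the floor by hand, then apply the ratio rule
        floor = H.EVALUE_FLOOR
        second = 1e-30
        expected_accept = second >= 1e5 * floor
        best, reason = H.filter_unique(
            [hit(evalue=0.0), hit(start=5000, end=5700, evalue=second)])
        assert expected_accept and reason is None and best.evalue == 0.0

    def test_tied_best_evalues_are_ambiguous(self):
        best, reason = H.filter_unique(
            [hit(evalue=1e-50), hit(start=5000, end=5700, evalue=1e-50)])
        assert best is None and reason == "ambiguous"

    def test_no_hits(self):
        assert H.filter_unique([]) == (None, "no_hits")

    def test_mixed_read_ids_rejected(self):
        with pytest.raises(InputError):
            H.filter_unique([hit(read="a"), hit(read="b")])


def test_normalization_encodes_minus_strand_by_reversed_coordinates():
    df = pd.DataFrame(
        [["r1", "chr01", 98, 700, 5, 0, 1, 700, 101, 800, 1e-50, 100],
         ["r2", "chr01", 98, 700, 5, 0, 1, 700, 800, 101, 1e-50, 100]],
        columns=BLAST_COLUMNS)
    norm = H.normalize_hits(df)
    assert list(norm["strand"]) == ["+", "-"]
    assert list(norm["ref_start"]) == [100, 100]
    assert list(norm["ref_end"]) == [800, 800]


def test_partition_every_read_gets_exactly_one_fate(default_result):
    hits_df = H.normalize_hits(default_result.hit_table)
    accepted, rejected = H.place_reads({"20": hits_df})
    all_reads = set(hits_df["read_id"])
    fates = set(accepted["read_id"]) | set(rejected["read_id"])
    assert fates == all_reads
    assert not (set(accepted["read_id"]) & set(rejected["read_id"]))
    assert accepted["read_id"].is_unique


def test_filtering_is_idempotent(default_result):
    accepted = default_result.placements
    refiltered, rejected = H.filter_hit_table(
        accepted.assign(bitscore=0.0))
    assert rejected.empty
    assert sorted(refiltered["read_id"]) == sorted(accepted["read_id"])


class TestIncremental:
    def table(self, rows):
        return H.normalize_hits(pd.DataFrame(rows, columns=BLAST_COLUMNS))

    def test_earlier_round_acceptance_wins(self):
        r20 = self.table([["r1", "chr01", 98, 700, 5, 0, 1, 700, 101, 800,
                           1e-50, 100]])
        r15 = self.table([["r1", "chr02", 98, 700, 5, 0, 1, 700, 901, 1600,
                           1e-60, 100]])
        accepted, rejected = H.incremental_accept({"20": r20, "15": r15})
        assert len(accepted) == 1
        assert accepted.iloc[0]["round"] == "20"
        assert accepted.iloc[0]["chromosome"] == "chr01"

    def test_rejected_everywhere_reports_last_reason(self):
        r20 = self.table([["r1", "chr01", 98, 700, 5, 0, 1, 700, 101, 800,
                           1e-3, 100]])
        r15 = self.table([["r1", "chr01", 98, 700, 5, 0, 1, 700, 101, 800,
                           1e-6, 100],
                          ["r1", "chr02", 98, 700, 5, 0, 1, 700, 101, 800,
                           1e-6, 90]])
        accepted, rejected = H.incremental_accept({"20": r20, "15": r15})
        assert accepted.empty
        assert rejected.iloc[0]["reason"] == "ambiguous"

    def test_empty_schedule_accepts_nothing(self):
        accepted, rejected = H.incremental_accept({}, schedule=[])
        assert accepted.empty and rejected.empty

    def test_later_round_rescues_read(self):
        r20 = self.table([["r1", "chr01", 98, 700, 5, 0, 1, 700, 101, 800,
                           1e-3, 100]])
        r7 = self.table([["r1", "chr01", 98, 700, 5, 0, 1, 700, 101, 800,
                          1e-30, 100]])
        accepted, _ = H.incremental_accept({"20": r20, "7": r7})
        assert accepted.iloc[0]["round"] == "7"


class TestAnchoring:
    def contig_hit_plus(self):
        # contig span [0, 5000) aligned to ref [10000, 15000), + strand
        return AlignmentHit("ctg1", "chr01", 10_000, 15_000, "+", 1e-80,
                            500.0, query_start=0, query_end=5_000)

    def contig_hit_minus(self):
        return AlignmentHit("ctg1", "chr01", 10_000, 15_000, "-", 1e-80,
                            500.0, query_start=0, query_end=5_000)

    def test_plus_strand_lift_composes_offsets(self):
        anchor = AnchorRecord("r1", "ctg1", 1_200, "+",
                              (self.contig_hit_plus(),), read_length=700)
        lifted = H.lift_through_anchor(anchor, self.contig_hit_plus())
        assert (lifted.ref_start, lifted.ref_end) == (11_200, 11_900)
        assert lifted.strand == "+"
        assert lifted.stringency_round == "anchored"

    def test_minus_strand_lift_lands_at_reference_end(self):
        anchor = AnchorRecord("r1", "ctg1", 0, "+",
                              (self.contig_hit_minus(),), read_length=700)
        lifted = H.lift_through_anchor(anchor, self.contig_hit_minus())
        assert lifted.ref_end == 15_000  # contig base 0 maps to the ref end
        assert lifted.ref_start == 14_300
        assert lifted.strand == "-"

    def test_offset_outside_aligned_span_fails(self):
        anchor = AnchorRecord("r1", "ctg1", 4_800, "+",
                              (self.contig_hit_plus(),), read_length=700)
        with pytest.raises(LiftError):
            H.lift_through_anchor(anchor, self.contig_hit_plus())

    def test_anchoring_never_decreases_placements(self):
        # one read with no direct hits, placeable only through its contig
        table = H.normalize_hits(pd.DataFrame(
            [["r0", "chr01", 98, 700, 5, 0, 1, 700, 101, 800, 1e-50, 100]],
            columns=BLAST_COLUMNS))
        anchor = AnchorRecord("r1", "ctg1", 100, "+",
                              (self.contig_hit_plus(),), read_length=700)
        base, _ = H.place_reads({"20": table})
        more, _ = H.place_reads({"20": table}, anchors=[anchor])
        assert len(more) == len(base) + 1
        assert "anchored" in set(more["round"])

    def test_direct_hit_wins_over_anchor(self):
        table = H.normalize_hits(pd.DataFrame(
            [["r1", "chr02", 98, 700, 5, 0, 1, 700, 101, 800, 1e-50, 100]],
            columns=BLAST_COLUMNS))
        anchor = AnchorRecord("r1", "ctg1", 100, "+",
                              (self.contig_hit_plus(),), read_length=700)
        accepted, _ = H.place_reads({"20": table}, anchors=[anchor])
        assert len(accepted) == 1
        assert accepted.iloc[0]["chromosome"] == "chr02"

    def test_failed_lift_reports_lift_failure(self):
        anchor = AnchorRecord("r1", "ctg1", 4_900, "+",
                              (self.contig_hit_plus(),), read_length=700)
        accepted, rejected = H.place_reads(
            {"20": H.normalize_hits(pd.DataFrame(columns=BLAST_COLUMNS))},
            anchors=[anchor])
        assert accepted.empty
        assert list(rejected["reason"]) == ["lift_failure"]
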