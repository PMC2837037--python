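import numpy as np
import pandas as pd
import pytest

from bacmap import rearrange as R
from bacmap.simulate import SimConfig
from bacmap.tiling import BacContig
from bacmap.workflow import confirmation_by_truth, run_experiment


def contig(cid, chrom, start, end):
    return BacContig(cid, chrom, start, end, [(cid + "_m", start, end)])


def inconsistent_row(clone_id, chrom, fwd, rev):
    return {
        "clone_id": clone_id, "class": "inconsistent_same_chr",
        "chromosome": chrom,
        "fwd_chr": chrom, "fwd_start": fwd[0], "fwd_end": fwd[1],
        "fwd_strand": "+",
        "rev_chr": chrom, "rev_start": rev[0], "rev_end": rev[1],
        "rev_strand": "+", "implied_insert": None,
    }


CONTIGS = [contig("A", "chr01", 0, 1_000_000),
           contig("B", "chr01", 5_000_000, 6_000_000)]


class TestDetect:
    def test_edge_joining_clone_is_a_candidate(self):
        cls = pd.DataFrame([inconsistent_row(
            "c1", "chr01", (999_050, 999_750), (5_000_040, 5_000_740))])
        cand = R.detect_candidates(cls, CONTIGS, edge_tolerance=150_000)
        row = cand.iloc[0]
        assert row["status"] == "candidate"
        assert (row["contig_a"], row["side_a"]) == ("A", "right")
        assert (row["contig_b"], row["side_b"]) == ("B", "left")

    def test_mid_contig_ends_are_rejected(self):
        cls = pd.DataFrame([inconsistent_row(
            "c1", "chr01", (400_000, 400_700), (5_500_000, 5_500_700))])
        cand = R.detect_candidates(cls, CONTIGS, edge_tolerance=150_000)
        assert cand.iloc[0]["status"] == "rejected_not_at_edge"

    def test_partition_of_inconsistent_clones(self, default_result):
        cand = default_result.candidates
        n_inco = (default_result.classified["class"]
                  == "inconsistent_same_chr").sum()
        assert len(cand) == n_inco
        assert set(cand["status"]) <= {"candidate",
                                       "confirmed_second_reference",
                                       "rejected_not_at_edge"}


class TestGrouping:
    def test_shared_edge_pair_is_one_breakpoint(self):
        rows = [inconsistent_row(f"c{i}", "chr01",
                                 (999_000 + i * 10, 999_700),
                                 (5_000_040, 5_000_740)) for i in range(3)]
        cand = R.detect_candidates(pd.DataFrame(rows), CONTIGS, 150_000)
        groups = R.group_candidates_by_breakpoint(cand)
        assert len(groups) == 1
        assert groups.iloc[0]["support"] == 3

    def test_distinct_edge_pairs_are_distinct_breakpoints(self):
        contigs = CONTIGS + [contig("C", "chr01", 8_000_000, 9_000_000)]
        rows = [inconsistent_row("c1", "chr01", (999_050, 999_750),
                                 (5_000_040, 5_000_740)),
                inconsistent_row("c2", "chr01", (999_050, 999_750),
                                 (8_000_040, 8_000_740))]
        cand = R.detect_candidates(pd.DataFrame(rows), contigs, 150_000)
        groups = R.group_candidates_by_breakpoint(cand)
        assert len(groups) == 2


def ortholog_row(gene, chrom, pos, alt_chr, alt_pos):
    return {"gene_id": gene, "ref_chr": chrom, "ref_start": pos,
            "ref_end": pos + 5_000, "alt_chr": alt_chr,
            "alt_start": alt_pos, "alt_end": alt_pos + 5_000}


class TestCrosscheck:
    def candidates(self):
        cls = pd.DataFrame([inconsistent_row(
            "c1", "chr01", (999_050, 999_750), (5_000_040, 5_000_740))])
        return R.detect_candidates(cls, CONTIGS, edge_tolerance=150_000)

    def test_adjacent_projections_confirm(self):
        orthologs = pd.DataFrame([
            ortholog_row("g1", "chr01", 990_000, "alt01", 2_000_000),
            ortholog_row("g2", "chr01", 5_010_000, "alt01", 2_040_000),
        ])
        out = R.crosscheck_second_reference(self.candidates(), CONTIGS,
                                            orthologs,
                                            adjacency_threshold=1_000_000)
        assert out.iloc[0]["status"] == "confirmed_second_reference"
        assert out.iloc[0]["alt_gap"] == pytest.approx(40_000)

    def test_different_second_reference_chromosomes_do_not_confirm(self):
        orthologs = pd.DataFrame([
            ortholog_row("g1", "chr01", 990_000, "alt01", 2_000_000),
            ortholog_row("g2", "chr01", 5_010_000, "alt02", 2_040_000),
        ])
        out = R.crosscheck_second_reference(self.candidates(), CONTIGS,
                                            orthologs)
        assert out.iloc[0]["verdict"] == "not_confirmed"

    def test_intervening_edge_blocks_confirmation(self):
        contigs = CONTIGS + [contig("C", "chr01", 2_000_000, 3_000_000)]
        cand = R.detect_candidates(pd.DataFrame([inconsistent_row(
            "c1", "chr01", (999_050, 999_750), (5_000_040, 5_000_740))]),
            contigs, edge_tolerance=150_000)
        orthologs = pd.DataFrame([
            ortholog_row("g1", "chr01", 990_000, "alt01", 2_000_000),
            ortholog_row("g2", "chr01", 5_010_000, "alt01", 2_040_000),
            # contig C's edges project between the candidate's edges
            ortholog_row("g3", "chr01", 2_005_000, "alt01", 2_020_000),
            ortholog_row("g4", "chr01", 2_995_000, "alt01", 2_025_000),
        ])
        out = R.crosscheck_second_reference(cand, contigs, orthologs)
        assert out.iloc[0]["verdict"] == "not_confirmed"

    def test_empty_ortholog_table_is_unevaluable(self):
        orthologs = pd.DataFrame(columns=["gene_id", "ref_chr", "ref_start",
                                          "ref_end", "alt_chr", "alt_start",
                                          "alt_end"])
        out = R.crosscheck_second_reference(self.candidates(), CONTIGS,
                                            orthologs)
        assert out.iloc[0]["verdict"] == "unevaluable"


def test_crosscheck_suppresses_chimera_artifacts():
    """With no rearrangements planted, confirmed candidates stay at or
    below 5% of the chimeric clones in the library."""
    confirmed = chimeric = 0
    for seed in (21, 22, 23):
        cfg = SimConfig(seed=seed, n_rearrangements_per_chromosome=0,
                        chimera_rate=0.05, n_clones=3000)
        res = run_experiment(cfg)
        confirmed += int((res.candidates["status"]
                          == "confirmed_second_reference").sum())
        chimeric += sum(1 for v in res.truth.clone_truth.values()
                        if v == "chimeric")
    assert chimeric > 0
    assert confirmed <= 0.05 * chimeric
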