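"""In-memory end-to-end experiment runner and truth-based evaluation.

Convenience layer over the stage functions for simulation studies: runs
simulation -> filtering -> classification -> tiling -> rearrangement
calling in one call and offers evaluation helpers that compare the result
against the simulator's ground truth (breakpoint recovery, confirmation
rates by clone truth class, genome-size ratio recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import genome_size as gs
from . import hits as hitmod
from . import pairs, rearrange, tiling
from .simulate import ReferenceLayout, SimConfig, SimTruth, simulate_experiment


@dataclass
class ExperimentResult:
    """All artifacts of one simulated mapping experiment."""

    config: SimConfig
    reference: ReferenceLayout
    truth: SimTruth
    clones: pd.DataFrame
    hit_table: pd.DataFrame
    placements: pd.DataFrame
    rejected: pd.DataFrame
    classified: pd.DataFrame
    contigs: list[tiling.BacContig]
    statistics: pd.DataFrame
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)
    breakpoint_groups: pd.DataFrame = field(default_factory=pd.DataFrame)
    edge_tolerance: float = 0.0


def run_experiment(config: SimConfig,
                   policy: pairs.ConsistencyPolicy | None = None,
                   edge_tolerance: float | None = None,
                   adjacency_threshold: float = rearrange.DEFAULT_ADJACENCY_THRESHOLD,
                   flank_window: float = rearrange.DEFAULT_FLANK_WINDOW,
                   crosscheck: bool = True) -> ExperimentResult:
    """Simulate one experiment and run the full analysis on it."""
    reference, truth, clones, hit_table = simulate_experiment(config)
    accepted, rejected = hitmod.place_reads(
        {"20": hitmod.normalize_hits(hit_table)})
    if policy is None:
        policy = pairs.ConsistencyPolicy.default(config.insert_mean)
    classified = pairs.classify_clones(clones, accepted, policy)
    lengths = reference.chromosome_lengths()
    contigs = tiling.build_contigs(pairs.clone_intervals(classified), lengths)
    counts = (classified.groupby("chromosome")["class"]
              .value_counts().unstack(fill_value=0).reset_index()
              .rename(columns={pairs.CLASS_CONSISTENT: "n_consistent",
                               pairs.CLASS_ONE_END: "n_one_end",
                               pairs.CLASS_INCONSISTENT: "n_inconsistent"}))
    stats = tiling.map_statistics(contigs, lengths, reference.genes, counts)
    if edge_tolerance is None:
        edge_tolerance = rearrange.default_edge_tolerance(
            config.insert_mean, config.inflation_factor)
    candidates = rearrange.detect_candidates(classified, contigs,
                                             edge_tolerance)
    if crosscheck:
        candidates = rearrange.crosscheck_second_reference(
            candidates, contigs, truth.orthologs, adjacency_threshold,
            flank_window)
    groups = rearrange.group_candidates_by_breakpoint(candidates)
    return ExperimentResult(config, reference, truth, clones, hit_table,
                            accepted, rejected, classified, contigs, stats,
                            candidates, groups, edge_tolerance)


def breakpoint_recovery(result: ExperimentResult) -> float:
    """Fraction of planted breakpoints matched by a detected candidate.

    A breakpoint is recovered when some non-rejected candidate on its
    chromosome has its two edges within the edge tolerance of the two
    joined reference coordinates.
    """
    tol = result.edge_tolerance
    cand = result.candidates
    cand = cand[cand["status"] != rearrange.STATUS_REJECTED]
    if not result.truth.breakpoints:
        return float("nan")
    hits = 0
    for chrom, a, b in result.truth.breakpoints:
        sub = cand[cand["chromosome"] == chrom]
        ok = any(
            (abs(r["coord_a"] - a) <= tol and abs(r["coord_b"] - b) <= tol)
            or (abs(r["coord_a"] - b) <= tol and abs(r["coord_b"] - a) <= tol)
            for _, r in sub.iterrows())
        hits += ok
    return hits / len(result.truth.breakpoints)


def confirmation_by_truth(result: ExperimentResult) -> pd.DataFrame:
    """Candidate and confirmation counts per ground-truth clone class."""
    truth = pd.Series(result.truth.clone_truth, name="truth")
    m = result.candidates.merge(truth, left_on="clone_id", right_index=True)
    cand = m[m["status"] != rearrange.STATUS_REJECTED]
    rows = []
    for cls, sub in cand.groupby("truth"):
        confirmed = int((sub["status"] == rearrange.STATUS_CONFIRMED).sum())
        rows.append({"truth": cls, "candidates": len(sub),
                     "confirmed": confirmed,
                     "rate": confirmed / len(sub)})
    return pd.DataFrame(rows)


def recovered_size_ratio(result: ExperimentResult,
                         bin_width: int = pairs.DEFAULT_BIN_WIDTH
                         ) -> gs.GenomeSizeEstimate:
    """Mode-ratio genome-size estimate from a simulated experiment.

    The library mode comes from the simulated clones' true insert lengths
    (the library QC distribution), the mapped mode from the implied
    reference-projected inserts of consistent clones.
    """
    mapped = result.classified["implied_insert"].dropna()
    _, _, mapped_mode = pairs.insert_size_distribution(mapped, bin_width)
    library = list(result.truth.clone_inserts.values())
    _, _, library_mode = pairs.insert_size_distribution(library, bin_width)
    reference_size = float(result.reference.chromosomes["length"].sum())
    return gs.estimate_genome_size(mapped_mode, library_mode, reference_size)
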