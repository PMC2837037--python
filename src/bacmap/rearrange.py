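"""Intra-chromosomal rearrangement detection and second-reference checks.

A clone whose two ends align to the same chromosome but violate the
pair-consistency criteria may span a rearrangement breakpoint: in that
case each of its ends lies near the boundary (edge) of a BAC-contig, and
the clone "arcs" between two contig edges. Candidates whose ends are not
near contig edges are rejected (the chromosome-internal equivalent of
removing arcs that do not start at contig edges).

Because clone libraries harbour chimeric clones that produce identical
arc signatures, candidates are cross-checked on a second reference genome
through the ortholog table: each contig edge is projected to the second
reference via its nearest flanking ortholog gene, and a candidate is
confirmed only when its two projected edges are mutually adjacent there.
A true rearrangement relative to the reference is expected to look
"un-rearranged" on an outgroup that shares the target's arrangement,
while a chimeric junction projects to two unrelated loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pairs import CLASS_INCONSISTENT
from .tiling import BacContig

STATUS_CANDIDATE = "candidate"
STATUS_CONFIRMED = "confirmed_second_reference"
STATUS_REJECTED = "rejected_not_at_edge"

VERDICT_CONFIRMED = "confirmed"
VERDICT_NOT_CONFIRMED = "not_confirmed"
VERDICT_UNEVALUABLE = "unevaluable"

DEFAULT_ADJACENCY_THRESHOLD = 1_000_000
DEFAULT_FLANK_WINDOW = 500_000


@dataclass(frozen=True)
class Edge:
    """One side of a BAC-contig."""

    contig_id: str
    side: str  # {left, right}
    chromosome: str
    coordinate: int

    @property
    def key(self) -> tuple[str, str]:
        return (self.contig_id, self.side)


def contig_edges(contigs: list[BacContig]) -> list[Edge]:
    edges = []
    for c in contigs:
        edges.append(Edge(c.contig_id, "left", c.chromosome, c.start))
        edges.append(Edge(c.contig_id, "right", c.chromosome, c.end))
    return edges


def default_edge_tolerance(insert_mean: float = 164_000.0,
                           inflation_estimate: float = 1.0) -> float:
    """About one reference-projected clone length: a breakpoint-spanning
    clone's ends cannot lie farther than one insert from the break."""
    return insert_mean / inflation_estimate


def _end_edge_distance(start: int, end: int, coord: int) -> int:
    if start <= coord <= end:
        return 0
    return min(abs(start - coord), abs(end - coord))


CANDIDATE_COLUMNS = ["clone_id", "chromosome", "status",
                     "contig_a", "side_a", "coord_a", "dist_a",
                     "contig_b", "side_b", "coord_b", "dist_b"]


def detect_candidates(classified: pd.DataFrame, contigs: list[BacContig],
                      edge_tolerance: float) -> pd.DataFrame:
    """Screen inconsistent same-chromosome clones for edge-to-edge arcs.

    Every inconsistent clone receives exactly one status: ``candidate``
    when each end lies within ``edge_tolerance`` of a contig edge and the
    two edges differ, else ``rejected_not_at_edge``. The reported edge
    pair is ordered by coordinate.
    """
    edges_by_chrom: dict[str, list[Edge]] = {}
    for e in contig_edges(contigs):
        edges_by_chrom.setdefault(e.chromosome, []).append(e)
    rows = []
    inco = classified[classified["class"] == CLASS_INCONSISTENT]
    for _, r in inco.iterrows():
        chrom = r["chromosome"]
        row = {"clone_id": r["clone_id"], "chromosome": chrom,
               "status": STATUS_REJECTED,
               "contig_a": None, "side_a": None, "coord_a": None,
               "dist_a": None, "contig_b": None, "side_b": None,
               "coord_b": None, "dist_b": None}
        edges = edges_by_chrom.get(chrom, [])
        if edges:
            picks = []
            for prefix in ("fwd", "rev"):
                s, e = int(r[f"{prefix}_start"]), int(r[f"{prefix}_end"])
                dists = [_end_edge_distance(s, e, edge.coordinate)
                         for edge in edges]
                i = int(np.argmin(dists))
                picks.append((edges[i], dists[i]))
            (ea, da), (eb, db) = sorted(picks,
                                        key=lambda p: p[0].coordinate)
            if da <= edge_tolerance and db <= edge_tolerance and ea.key != eb.key:
                row.update({
                    "status": STATUS_CANDIDATE,
                    "contig_a": ea.contig_id, "side_a": ea.side,
                    "coord_a": ea.coordinate, "dist_a": da,
                    "contig_b": eb.contig_id, "side_b": eb.side,
                    "coord_b": eb.coordinate, "dist_b": db,
                })
        rows.append(row)
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def project_edges(contigs: list[BacContig], orthologs: pd.DataFrame,
                  flank_window: float = DEFAULT_FLANK_WINDOW
                  ) -> pd.DataFrame:
    """Project every contig edge onto the second reference genome.

    Each edge takes the second-reference position of its nearest flanking
    ortholog gene (gene midpoint distance, within ``flank_window``); edges
    with no gene nearby stay unprojected (NaN).
    """
    rows = []
    by_chrom = {c: sub for c, sub in orthologs.groupby("ref_chr")}
    for edge in contig_edges(contigs):
        sub = by_chrom.get(edge.chromosome)
        alt_chr, alt_pos = None, np.nan
        if sub is not None and len(sub):
            mids = ((sub["ref_start"] + sub["ref_end"]) / 2.0).to_numpy()
            d = np.abs(mids - edge.coordinate)
            i = int(np.argmin(d))
            if d[i] <= flank_window:
                alt_chr = sub["alt_chr"].iloc[i]
                alt_pos = float((sub["alt_start"].iloc[i]
                                 + sub["alt_end"].iloc[i]) / 2.0)
        rows.append({
            "contig_id": edge.contig_id, "side": edge.side,
            "chromosome": edge.chromosome, "coordinate": edge.coordinate,
            "alt_chr": alt_chr, "alt_pos": alt_pos,
        })
    return pd.DataFrame(rows)


def crosscheck_second_reference(candidates: pd.DataFrame,
                                contigs: list[BacContig],
                                orthologs: pd.DataFrame,
                                adjacency_threshold: float = DEFAULT_ADJACENCY_THRESHOLD,
                                flank_window: float = DEFAULT_FLANK_WINDOW
                                ) -> pd.DataFrame:
    """Attach a second-reference verdict to every candidate.

    A candidate is confirmed when its two projected edges land on the same
    second-reference chromosome, within ``adjacency_threshold`` of each
    other, with no other projected edge strictly between them. Candidates
    with an unprojected edge are unevaluable.
    """
    proj = project_edges(contigs, orthologs, flank_window)
    lookup = {(r["contig_id"], r["side"]): (r["alt_chr"], r["alt_pos"])
              for _, r in proj.iterrows()}
    out = candidates.copy()
    verdicts, statuses, gaps = [], [], []
    projected = proj.dropna(subset=["alt_pos"])
    for _, r in out.iterrows():
        if r["status"] != STATUS_CANDIDATE:
            verdicts.append(None)
            statuses.append(r["status"])
            gaps.append(np.nan)
            continue
        a = lookup.get((r["contig_a"], r["side_a"]), (None, np.nan))
        b = lookup.get((r["contig_b"], r["side_b"]), (None, np.nan))
        if a[0] is None or b[0] is None:
            verdicts.append(VERDICT_UNEVALUABLE)
            statuses.append(STATUS_CANDIDATE)
            gaps.append(np.nan)
            continue
        gap = abs(a[1] - b[1])
        ok = a[0] == b[0] and gap <= adjacency_threshold
        if ok:
            lo, hi = sorted((a[1], b[1]))
            same_chr = projected[projected["alt_chr"] == a[0]]
            between = same_chr[(same_chr["alt_pos"] > lo)
                               & (same_chr["alt_pos"] < hi)]
            between = between[~(
                ((between["contig_id"] == r["contig_a"])
                 & (between["side"] == r["side_a"]))
                | ((between["contig_id"] == r["contig_b"])
                   & (between["side"] == r["side_b"])))]
            ok = between.empty
        verdicts.append(VERDICT_CONFIRMED if ok else VERDICT_NOT_CONFIRMED)
        statuses.append(STATUS_CONFIRMED if ok else STATUS_CANDIDATE)
        gaps.append(gap)
    out["verdict"] = verdicts
    out["status"] = statuses
    out["alt_gap"] = gaps
    return out


def group_candidates_by_breakpoint(candidates: pd.DataFrame) -> pd.DataFrame:
    """Cluster candidates sharing the same ordered edge pair into
    breakpoints with supporting-clone counts."""
    cand = candidates[candidates["status"].isin(
        [STATUS_CANDIDATE, STATUS_CONFIRMED])]
    if cand.empty:
        return pd.DataFrame(columns=["chromosome", "contig_a", "side_a",
                                     "coord_a", "contig_b", "side_b",
                                     "coord_b", "support", "n_confirmed",
                                     "clones"])
    grouped = cand.groupby(["chromosome", "contig_a", "side_a", "coord_a",
                            "contig_b", "side_b", "coord_b"], sort=True)
    rows = []
    for key, sub in grouped:
        rows.append(dict(zip(
            ["chromosome", "contig_a", "side_a", "coord_a",
             "contig_b", "side_b", "coord_b"], key),
            support=len(sub),
            n_confirmed=int((sub["status"] == STATUS_CONFIRMED).sum()),
            clones=",".join(sorted(sub["clone_id"]))))
    return pd.DataFrame(rows)
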