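"""BAC-contig construction, minimal tiling paths and map statistics.

A BAC-contig is a connected component of the clone interval-overlap graph
on one reference chromosome (overlap means a shared base pair; intervals
that merely abut belong to different contigs). Its minimal tiling path is
the smallest subset of member clones whose union still covers the contig
span, found by the classic greedy interval-cover rule: start at the contig
left edge and repeatedly extend with the overlapping clone that reaches
farthest right. For interval covering this greedy choice is optimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass
class BacContig:
    """A maximal run of overlapping consistent clones on one chromosome."""

    contig_id: str
    chromosome: str
    start: int
    end: int
    members: list[tuple[str, int, int]]  # (clone_id, start, end)
    tiling_path: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def build_contigs(intervals: pd.DataFrame,
                  chromosome_lengths: dict[str, int] | None = None
                  ) -> list[BacContig]:
    """Group clone intervals (clone_id, chromosome, start, end) into
    contigs and compute each contig's minimal tiling path.

    Contigs are numbered per chromosome in coordinate order.
    """
    contigs: list[BacContig] = []
    for chrom, sub in intervals.groupby("chromosome", sort=True):
        if chromosome_lengths is not None:
            limit = chromosome_lengths.get(chrom)
            if limit is None:
                raise InputError(f"unknown chromosome {chrom!r}")
            if (sub["end"] > limit).any() or (sub["start"] < 0).any():
                raise InputError(
                    f"clone interval beyond chromosome {chrom} length {limit}")
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        current: list[tuple[str, int, int]] = []
        cur_end = None
        k = 0
        for cid, s, e in zip(sub["clone_id"], sub["start"], sub["end"]):
            s, e = int(s), int(e)
            if cur_end is not None and s < cur_end:
                current.append((cid, s, e))
                cur_end = max(cur_end, e)
            else:
                if current:
                    contigs.append(_finish_contig(chrom, k, current))
                    k += 1
                current = [(cid, s, e)]
                cur_end = e
        if current:
            contigs.append(_finish_contig(chrom, k, current))
    return contigs


def _finish_contig(chrom: str, k: int,
                   members: list[tuple[str, int, int]]) -> BacContig:
    start = min(m[1] for m in members)
    end = max(m[2] for m in members)
    contig = BacContig(f"{chrom}_ctg{k:04d}", chrom, start, end, members)
    contig.tiling_path = minimal_tiling_path(contig)
    return contig


def minimal_tiling_path(contig: BacContig) -> list[str]:
    """Greedy minimum-cardinality cover of the contig span by its members.

    Seed: the clone starting at the contig left edge (ties broken toward
    the larger right end, then the lexicographically smaller clone id).
    Step: among clones overlapping the covered prefix, take the one with
    the maximal right end (same tie-breaks). Contig connectivity guarantees
    progress until the right edge is reached.
    """
    members = sorted(contig.members, key=lambda m: (m[1], -m[2], m[0]))
    starters = [m for m in members if m[1] == contig.start]
    seed = min(starters, key=lambda m: (-m[2], m[0]))
    path = [seed]
    covered = seed[2]
    while covered < contig.end:
        candidates = [m for m in members
                      if m[1] < covered and m[2] > covered and m not in path]
        nxt = min(candidates, key=lambda m: (-m[2], m[0]))
        path.append(nxt)
        covered = nxt[2]
    return [m[0] for m in path]


def covered_length(contigs: list[BacContig], chromosome: str | None = None
                   ) -> int:
    return sum(c.length for c in contigs
               if chromosome is None or c.chromosome == chromosome)


def n50(contig_lengths, reference_length: float) -> tuple[int, int]:
    """N50 contig size and count against a reference length denominator.

    Size S of the contig at which descending-size contigs cumulatively
    reach >= 50% of ``reference_length``, and the number of contigs in that
    prefix. Returns (0, 0) when total coverage never reaches half the
    reference.
    """
    sizes = np.sort(np.asarray(list(contig_lengths)))[::-1]
    cum = np.cumsum(sizes)
    half = reference_length / 2.0
    hit = np.nonzero(cum >= half)[0]
    if hit.size == 0:
        return 0, 0
    i = int(hit[0])
    return int(sizes[i]), i + 1


def genes_covered(contigs: list[BacContig], genes: pd.DataFrame
                  ) -> pd.Series:
    """Boolean per gene: fully contained in some contig span."""
    flags = np.zeros(len(genes), dtype=bool)
    by_chrom: dict[str, list[BacContig]] = {}
    for c in contigs:
        by_chrom.setdefault(c.chromosome, []).append(c)
    for chrom, group in by_chrom.items():
        spans = sorted((c.start, c.end) for c in group)
        starts = np.array([s for s, _ in spans])
        ends = np.array([e for _, e in spans])
        mask = (genes["chromosome"] == chrom).to_numpy()
        if not mask.any():
            continue
        gs = genes.loc[mask, "start"].to_numpy()
        ge = genes.loc[mask, "end"].to_numpy()
        idx = np.searchsorted(starts, gs, side="right") - 1
        ok = (idx >= 0) & (ge <= ends[np.clip(idx, 0, None)])
        flags[np.nonzero(mask)[0]] = ok
    return pd.Series(flags, index=genes.index, name="covered")


STAT_COLUMNS = ["chromosome", "chromosome_bp", "n_contigs",
                "largest_contig_bp", "covered_bp", "pct_covered",
                "n_tiling_clones", "n_consistent", "n_one_end",
                "n_inconsistent", "n50_bp", "n50_count", "n_genes",
                "genes_covered", "pct_genes_covered"]


def map_statistics(contigs: list[BacContig],
                   chromosome_lengths: dict[str, int],
                   genes: pd.DataFrame | None = None,
                   class_counts_by_chrom: pd.DataFrame | None = None
                   ) -> pd.DataFrame:
    """Per-chromosome map statistics (one row per reference chromosome).

    ``class_counts_by_chrom`` optionally carries columns chromosome /
    n_consistent / n_one_end / n_inconsistent from the classification
    stage; N50 uses the chromosome length as denominator.
    """
    gene_cov = None
    if genes is not None and len(genes):
        gene_cov = genes.assign(covered=genes_covered(contigs, genes))
    counts = {}
    if class_counts_by_chrom is not None:
        counts = class_counts_by_chrom.set_index("chromosome").to_dict("index")
    rows = []
    for chrom in sorted(chromosome_lengths):
        length = chromosome_lengths[chrom]
        mine = [c for c in contigs if c.chromosome == chrom]
        cov = covered_length(mine)
        size50, count50 = n50([c.length for c in mine], length)
        if gene_cov is not None:
            g = gene_cov[gene_cov["chromosome"] == chrom]
            n_genes, n_cov = len(g), int(g["covered"].sum())
        else:
            n_genes, n_cov = 0, 0
        cc = counts.get(chrom, {})
        rows.append({
            "chromosome": chrom,
            "chromosome_bp": length,
            "n_contigs": len(mine),
            "largest_contig_bp": max((c.length for c in mine), default=0),
            "covered_bp": cov,
            "pct_covered": 100.0 * cov / length,
            "n_tiling_clones": sum(len(c.tiling_path) for c in mine),
            "n_consistent": int(cc.get("n_consistent", 0)),
            "n_one_end": int(cc.get("n_one_end", 0)),
            "n_inconsistent": int(cc.get("n_inconsistent", 0)),
            "n50_bp": size50,
            "n50_count": count50,
            "n_genes": n_genes,
            "genes_covered": n_cov,
            "pct_genes_covered": (100.0 * n_cov / n_genes) if n_genes else 0.0,
        })
    return pd.DataFrame(rows, columns=STAT_COLUMNS)


def contigs_to_frame(contigs: list[BacContig]) -> pd.DataFrame:
    rows = [{
        "contig_id": c.contig_id, "chromosome": c.chromosome,
        "start": c.start, "end": c.end, "n_members": len(c.members),
        "n_tiling": len(c.tiling_path),
        "members": ",".join(m[0] for m in c.members),
        "tiling_path": ",".join(c.tiling_path),
    } for c in contigs]
    return pd.DataFrame(rows, columns=["contig_id", "chromosome", "start",
                                       "end", "n_members", "n_tiling",
                                       "members", "tiling_path"])
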