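"""Report aggregation, browser-track export and improvement comparison."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InputError
from .pairs import CLASS_CONSISTENT
from .tiling import BacContig, n50

UNDEFINED = "undefined"


def aggregate(per_chromosome: pd.DataFrame,
              contig_lengths=None) -> pd.Series:
    """Fold per-chromosome map statistics into the genome-wide ALL row.

    Counts are summed, the largest contig is the maximum, and percentages
    are re-derived from summed numerators and denominators (never averaged
    across chromosomes). The genome-wide N50 is recomputed from
    ``contig_lengths`` against the summed reference length when provided.
    """
    if per_chromosome["chromosome"].duplicated().any():
        raise InputError("duplicate chromosome rows in statistics table")
    s = per_chromosome
    total_bp = int(s["chromosome_bp"].sum())
    covered = float(s["covered_bp"].sum())
    out = {
        "chromosome": "ALL",
        "chromosome_bp": total_bp,
        "n_contigs": int(s["n_contigs"].sum()),
        "largest_contig_bp": int(s["largest_contig_bp"].max())
        if len(s) else 0,
        "covered_bp": covered,
        "pct_covered": 100.0 * covered / total_bp if total_bp else 0.0,
        "n_tiling_clones": int(s["n_tiling_clones"].sum()),
        "n_consistent": int(s["n_consistent"].sum()),
        "n_one_end": int(s["n_one_end"].sum()),
        "n_inconsistent": int(s["n_inconsistent"].sum()),
        "n_genes": int(s["n_genes"].sum()),
        "genes_covered": int(s["genes_covered"].sum()),
    }
    out["pct_genes_covered"] = (100.0 * out["genes_covered"] / out["n_genes"]
                                if out["n_genes"] else 0.0)
    if contig_lengths is not None:
        size50, count50 = n50(contig_lengths, total_bp)
        out["n50_bp"], out["n50_count"] = size50, count50
    return pd.Series(out)


def improvement_report(before, after) -> dict[str, object]:
    """Relative change per metric, (after - before)/before x 100, rounded
    to an integer percent; a zero baseline reports 'undefined'."""
    keys = [k for k in before if k in after]
    out = {}
    for k in keys:
        b, a = before[k], after[k]
        if not isinstance(b, (int, float)) or not isinstance(a, (int, float)):
            continue
        if b == 0:
            out[k] = UNDEFINED
        else:
            out[k] = int(round((a - b) / b * 100.0))
    return out


# ---------------------------------------------------------------------------
# GFF3 track export / import

GFF_SOURCE = "bacmap"
TYPE_CLONE = "BAC_clone"
TYPE_CONTIG = "match"


def export_gff(contigs: list[BacContig], classified: pd.DataFrame,
               path) -> None:
    """Write the comparative map as a GFF3 browser track.

    One feature per consistently mapped clone (type BAC_clone, strand of
    the forward end read) and one per contig (type match); clones on a
    minimal tiling path carry ``tiling_path=true``. GFF3 coordinates are
    1-based inclusive.
    """
    tiling = {cid for c in contigs for cid in c.tiling_path}
    lines = ["##gff-version 3"]
    for c in contigs:
        attrs = f"ID={c.contig_id};Name={c.contig_id}"
        lines.append("\t".join([
            c.chromosome, GFF_SOURCE, TYPE_CONTIG, str(c.start + 1),
            str(c.end), ".", ".", ".", attrs]))
    cons = classified[classified["class"] == CLASS_CONSISTENT]
    for _, r in cons.iterrows():
        start = int(min(r["fwd_start"], r["rev_start"]))
        end = int(max(r["fwd_end"], r["rev_end"]))
        attrs = f"ID={r['clone_id']};Name={r['clone_id']}"
        if r["clone_id"] in tiling:
            attrs += ";tiling_path=true"
        lines.append("\t".join([
            str(r["chromosome"]), GFF_SOURCE, TYPE_CLONE, str(start + 1),
            str(end), ".", str(r["fwd_strand"]), ".", attrs]))
    Path(path).write_text("\n".join(lines) + "\n")


def import_gff(path) -> pd.DataFrame:
    """Parse a track written by :func:`export_gff` back into a frame with
    0-based half-open coordinates (round-trip partner of the exporter)."""
    from gffutils.iterators import DataIterator

    rows = []
    for f in DataIterator(str(path)):
        rows.append({
            "id": f.attributes.get("ID", [None])[0],
            "type": f.featuretype,
            "chromosome": f.seqid,
            "start": f.start - 1,
            "end": f.end,
            "strand": f.strand,
            "tiling_path": f.attributes.get("tiling_path", ["false"])[0]
            == "true",
        })
    return pd.DataFrame(rows, columns=["id", "type", "chromosome", "start",
                                       "end", "strand", "tiling_path"])
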