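"""Hit-table processing: parsing, uniqueness filtering and contig anchoring.

Input is the 12-column BLAST tabular dialect (outfmt 6). Coordinates are
normalized at parse time to 0-based half-open intervals with an explicit
strand (the tabular dialect encodes the minus strand as subject start >
subject end, 1-based inclusive).

A read is accepted only when its best alignment clears the e-value cutoff
*and* is unique: the second-best alignment must have an e-value at least
``ratio_threshold``-fold larger than the best. Reads whose direct
alignments fail can still be placed by lifting them through an assembled
WGS contig that contains them (the contig aligns where the short read
cannot), correcting the contig's match coordinates by the read's offset in
the contig.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, LiftError
from .simulate import BLAST_COLUMNS

#: substitute for reported e-values of exactly zero, so the uniqueness
#: ratio test stays well-defined (and conservative)
EVALUE_FLOOR = 1e-180

DEFAULT_EVALUE_CUTOFF = 1e-5
DEFAULT_RATIO_THRESHOLD = 1e5

REASON_NO_HITS = "no_hits"
REASON_ABOVE_CUTOFF = "above_cutoff"
REASON_AMBIGUOUS = "ambiguous"
REASON_LIFT_FAILURE = "lift_failure"

PLACEMENT_COLUMNS = ["read_id", "chromosome", "ref_start", "ref_end",
                     "strand", "evalue", "round"]


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a read (or contig) against the reference."""

    read_id: str
    chromosome: str
    ref_start: int
    ref_end: int
    strand: str
    evalue: float
    bitscore: float = 0.0
    stringency_round: str = "20"
    query_start: int = 0  # 0-based half-open span on the query sequence
    query_end: int = 0

    def __post_init__(self):
        if self.ref_start >= self.ref_end:
            raise InputError(
                f"hit for {self.read_id}: ref_start must be < ref_end")
        if self.evalue < 0:
            raise InputError(f"hit for {self.read_id}: negative e-value")


def read_hit_table(path, round_label: str = "20") -> pd.DataFrame:
    """Read a 12-column BLAST tabular file and normalize coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_COLUMNS)
    return normalize_hits(df, round_label=round_label)


def normalize_hits(df: pd.DataFrame, round_label: str = "20") -> pd.DataFrame:
    """Normalize a BLAST tabular frame to 0-based half-open + strand."""
    out = df.copy()
    minus = out["sstart"] > out["send"]
    lo = np.minimum(out["sstart"], out["send"])
    hi = np.maximum(out["sstart"], out["send"])
    out["strand"] = np.where(minus, "-", "+")
    out["ref_start"] = lo - 1
    out["ref_end"] = hi
    out["read_id"] = out["qseqid"]
    out["chromosome"] = out["sseqid"]
    out["round"] = round_label
    return out


def _floored(evalue: float) -> float:
    return max(float(evalue), EVALUE_FLOOR)


def filter_unique(hits: Sequence[AlignmentHit],
                  evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                  ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
                  ) -> tuple[AlignmentHit | None, str | None]:
    """Apply the cutoff + best-vs-second-best uniqueness filter to the hits
    of a single read.

    Returns ``(accepted_hit, None)`` or ``(None, reason)`` with reason in
    ``{no_hits, above_cutoff, ambiguous}``. Tied best e-values are
    ambiguous by construction (the ratio cannot hold).
    """
    hits = list(hits)
    if not hits:
        return None, REASON_NO_HITS
    if len({h.read_id for h in hits}) > 1:
        raise InputError("filter_unique called with mixed read ids")
    ranked = sorted(hits, key=lambda h: (_floored(h.evalue), -h.bitscore))
    best = ranked[0]
    if best.evalue > evalue_cutoff:
        return None, REASON_ABOVE_CUTOFF
    if len(ranked) > 1:
        second = ranked[1]
        if _floored(second.evalue) < ratio_threshold * _floored(best.evalue):
            return None, REASON_AMBIGUOUS
    return best, None


def filter_hit_table(df: pd.DataFrame,
                     evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                     ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized uniqueness filter over a normalized hit table.

    Returns ``(accepted, rejected)``; accepted has PLACEMENT_COLUMNS,
    rejected has read_id + reason.
    """
    if df.empty:
        return (pd.DataFrame(columns=PLACEMENT_COLUMNS),
                pd.DataFrame(columns=["read_id", "reason"]))
    d = df.copy()
    d["_ev"] = d["evalue"].clip(lower=EVALUE_FLOOR)
    d = d.sort_values(["read_id", "_ev", "bitscore"],
                      ascending=[True, True, False], kind="mergesort")
    rank = d.groupby("read_id", sort=False).cumcount()
    best = d[rank == 0].set_index("read_id")
    second = d[rank == 1].set_index("read_id")
    second_ev = second["_ev"].reindex(best.index)
    above = best["evalue"] > evalue_cutoff
    ambiguous = (~above) & (second_ev.notna()) & \
        (second_ev < ratio_threshold * best["_ev"])
    ok = ~(above | ambiguous)
    accepted = best[ok].reset_index()[
        ["read_id", "chromosome", "ref_start", "ref_end", "strand",
         "evalue", "round"]]
    reasons = pd.Series(np.where(above, REASON_ABOVE_CUTOFF, REASON_AMBIGUOUS),
                        index=best.index)[~ok]
    rejected = reasons.rename("reason").reset_index()
    return accepted, rejected


def incremental_accept(tables_by_round: Mapping[str, pd.DataFrame],
                       schedule: Sequence[str] | None = None,
                       evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                       ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the uniqueness filter over successive stringency rounds.

    ``schedule`` orders the rounds from most to least stringent (defaults
    to the mapping's own order, e.g. word sizes "20", "15", "11", "7"). A
    read accepted at an earlier round is never re-evaluated later; a read
    rejected everywhere appears in the rejected table with its last reason.
    """
    if schedule is None:
        schedule = list(tables_by_round)
    accepted_frames: list[pd.DataFrame] = []
    last_reason: dict[str, str] = {}
    done: set[str] = set()
    for label in schedule:
        table = tables_by_round[label]
        if "ref_start" not in table.columns:
            table = normalize_hits(table, round_label=label)
        else:
            table = table.assign(round=label)
        table = table[~table["read_id"].isin(done)]
        acc, rej = filter_hit_table(table, evalue_cutoff, ratio_threshold)
        accepted_frames.append(acc)
        done.update(acc["read_id"])
        for rid, reason in zip(rej["read_id"], rej["reason"]):
            last_reason[rid] = reason
    accepted_frames = [f for f in accepted_frames if not f.empty]
    accepted = (pd.concat(accepted_frames, ignore_index=True)
                if accepted_frames else pd.DataFrame(columns=PLACEMENT_COLUMNS))
    pending = {r: why for r, why in last_reason.items() if r not in done}
    rejected = pd.DataFrame(sorted(pending.items()),
                            columns=["read_id", "reason"])
    return accepted, rejected


@dataclass(frozen=True)
class AnchorRecord:
    """A read anchored inside an assembled WGS contig.

    ``offset_in_contig`` is the 0-based position of the read's first base in
    the contig; ``read_strand_in_contig`` its orientation there;
    ``contig_hits`` the contig's own alignments against the reference.
    """

    read_id: str
    contig_id: str
    offset_in_contig: int
    read_strand_in_contig: str
    contig_hits: tuple[AlignmentHit, ...]
    read_length: int


def lift_through_anchor(anchor: AnchorRecord,
                        contig_hit: AlignmentHit) -> AlignmentHit:
    """Place a read on the reference through its contig's accepted hit.

    The contig hit maps contig span [query_start, query_end) onto reference
    span [ref_start, ref_end); the read at ``offset_in_contig`` is shifted
    accordingly, composing orientations (read strand on reference = contig
    hit strand x read strand in contig). Raises LiftError when the read
    falls outside the aligned contig span.
    """
    o = anchor.offset_in_contig
    ln = anchor.read_length
    if o < contig_hit.query_start or o + ln > contig_hit.query_end:
        raise LiftError(
            f"read {anchor.read_id} at contig offset {o} lies outside the "
            f"aligned span [{contig_hit.query_start}, {contig_hit.query_end})")
    if contig_hit.strand == "+":
        start = contig_hit.ref_start + (o - contig_hit.query_start)
        end = start + ln
    else:
        end = contig_hit.ref_end - (o - contig_hit.query_start)
        start = end - ln
    same = contig_hit.strand == anchor.read_strand_in_contig
    strand = "+" if same else "-"
    return AlignmentHit(anchor.read_id, contig_hit.chromosome, start, end,
                        strand, contig_hit.evalue, contig_hit.bitscore,
                        stringency_round="anchored")


def _anchor_placement(anchor: AnchorRecord, evalue_cutoff: float,
                      ratio_threshold: float
                      ) -> tuple[AlignmentHit | None, str]:
    best, reason = filter_unique(anchor.contig_hits, evalue_cutoff,
                                 ratio_threshold)
    if best is None:
        return None, reason
    try:
        return lift_through_anchor(anchor, best), ""
    except LiftError:
        return None, REASON_LIFT_FAILURE


def place_reads(tables_by_round: Mapping[str, pd.DataFrame],
                anchors: Iterable[AnchorRecord] = (),
                schedule: Sequence[str] | None = None,
                evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full placement: incremental direct acceptance, then anchored lifts.

    A direct hit always wins over an anchored lift for the same read; the
    lift only rescues reads with no accepted direct alignment. Every read
    seen in the input ends in exactly one of accepted / above_cutoff /
    ambiguous / no_hits / lift_failure.
    """
    accepted, rejected = incremental_accept(tables_by_round, schedule,
                                            evalue_cutoff, ratio_threshold)
    placed = set(accepted["read_id"])
    reasons = dict(zip(rejected["read_id"], rejected["reason"]))
    extra_rows = []
    for anchor in anchors:
        if anchor.read_id in placed:
            continue
        hit, reason = _anchor_placement(anchor, evalue_cutoff, ratio_threshold)
        if hit is not None:
            extra_rows.append({
                "read_id": hit.read_id, "chromosome": hit.chromosome,
                "ref_start": hit.ref_start, "ref_end": hit.ref_end,
                "strand": hit.strand, "evalue": hit.evalue,
                "round": "anchored",
            })
            placed.add(anchor.read_id)
            reasons.pop(anchor.read_id, None)
        elif reason == REASON_LIFT_FAILURE:
            reasons[anchor.read_id] = REASON_LIFT_FAILURE
    if extra_rows:
        accepted = pd.concat([accepted, pd.DataFrame(extra_rows)],
                             ignore_index=True)
    rejected = pd.DataFrame(sorted(reasons.items()),
                            columns=["read_id", "reason"])
    return accepted, rejected
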