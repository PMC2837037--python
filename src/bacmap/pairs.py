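"""Paired-end clone classification.

A clone is *consistent* when both end reads are placed on the same
reference chromosome, on opposite strands facing inward (the plus-strand
read upstream of the minus-strand read), and the outermost coordinate span
— the implied insert size on the reference — lies within the configured
distance bounds. Clones violating orientation or distance on one
chromosome are candidate rearrangement spanners; clones hitting two
chromosomes are excluded; clones with a single placed end are kept as
one-end evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyDistributionError, InputError

CLASS_CONSISTENT = "consistent"
CLASS_INCONSISTENT = "inconsistent_same_chr"
CLASS_DIFFERENT_CHR = "different_chr_excluded"
CLASS_ONE_END = "one_end"
CLASS_UNMAPPED = "unmapped"
ALL_CLASSES = [CLASS_CONSISTENT, CLASS_INCONSISTENT, CLASS_DIFFERENT_CHR,
               CLASS_ONE_END, CLASS_UNMAPPED]

DEFAULT_BIN_WIDTH = 5_000


@dataclass(frozen=True)
class ConsistencyPolicy:
    """Distance bounds for a consistent pair (orientation is always the
    inward-facing rule)."""

    min_insert: float
    max_insert: float

    def __post_init__(self):
        if not (0 < self.min_insert < self.max_insert):
            raise InputError("require 0 < min_insert < max_insert")

    @classmethod
    def default(cls, insert_mean: float = 164_000.0,
                inflation_guess: float = 1.0) -> "ConsistencyPolicy":
        """Wide first-pass bounds around the library mean projected onto
        the reference: [0.3, 2.5] x mean / inflation_guess."""
        centre = insert_mean / inflation_guess
        return cls(0.3 * centre, 2.5 * centre)


@dataclass
class ClonePlacement:
    """A clone's classified placement on the reference."""

    clone_id: str
    clone_class: str
    chromosome: str | None = None
    fwd: tuple | None = None  # (chromosome, start, end, strand)
    rev: tuple | None = None
    implied_insert: float | None = None


def classify_clone(clone_id: str, fwd, rev,
                   policy: ConsistencyPolicy) -> ClonePlacement:
    """Classify one clone from its (at most one per end) placements.

    ``fwd`` / ``rev`` are ``(chromosome, start, end, strand)`` tuples or
    None for an unplaced end.
    """
    if fwd is None and rev is None:
        return ClonePlacement(clone_id, CLASS_UNMAPPED)
    if fwd is None or rev is None:
        placed = fwd if fwd is not None else rev
        return ClonePlacement(clone_id, CLASS_ONE_END, placed[0],
                              fwd=fwd, rev=rev)
    if fwd[0] != rev[0]:
        return ClonePlacement(clone_id, CLASS_DIFFERENT_CHR, None, fwd, rev)
    chrom = fwd[0]
    if fwd[3] == rev[3]:
        return ClonePlacement(clone_id, CLASS_INCONSISTENT, chrom, fwd, rev)
    plus, minus = (fwd, rev) if fwd[3] == "+" else (rev, fwd)
    inward = plus[1] <= minus[1] and plus[2] <= minus[2]
    span = minus[2] - plus[1]
    if inward and policy.min_insert <= span <= policy.max_insert:
        return ClonePlacement(clone_id, CLASS_CONSISTENT, chrom, fwd, rev,
                              implied_insert=float(span))
    return ClonePlacement(clone_id, CLASS_INCONSISTENT, chrom, fwd, rev)


def classify_clones(clones: pd.DataFrame, placements: pd.DataFrame,
                    policy: ConsistencyPolicy) -> pd.DataFrame:
    """Classify every clone in the clone table.

    ``placements`` is the accepted-placement table (one row per read at
    most); duplicated read ids violate the uniqueness filter's contract.
    Returns one row per clone with class, chromosome, end coordinates and
    implied insert.
    """
    if placements["read_id"].duplicated().any():
        raise InputError("placements contain more than one row per read")
    lookup = {
        rid: (chrom, int(s), int(e), strand)
        for rid, chrom, s, e, strand in zip(
            placements["read_id"], placements["chromosome"],
            placements["ref_start"], placements["ref_end"],
            placements["strand"])
    }
    rows = []
    for clone_id, fwd_id, rev_id in zip(clones["clone_id"],
                                        clones["fwd_read_id"],
                                        clones["rev_read_id"]):
        fwd = lookup.get(fwd_id)
        rev = lookup.get(rev_id)
        cp = classify_clone(clone_id, fwd, rev, policy)
        rows.append({
            "clone_id": clone_id,
            "class": cp.clone_class,
            "chromosome": cp.chromosome,
            "fwd_chr": fwd[0] if fwd else None,
            "fwd_start": fwd[1] if fwd else None,
            "fwd_end": fwd[2] if fwd else None,
            "fwd_strand": fwd[3] if fwd else None,
            "rev_chr": rev[0] if rev else None,
            "rev_start": rev[1] if rev else None,
            "rev_end": rev[2] if rev else None,
            "rev_strand": rev[3] if rev else None,
            "implied_insert": cp.implied_insert,
        })
    return pd.DataFrame(rows)


def clone_intervals(classified: pd.DataFrame) -> pd.DataFrame:
    """Outermost reference intervals of consistent clones
    (clone_id, chromosome, start, end)."""
    cons = classified[classified["class"] == CLASS_CONSISTENT]
    start = np.minimum(cons["fwd_start"], cons["rev_start"]).astype(int)
    end = np.maximum(cons["fwd_end"], cons["rev_end"]).astype(int)
    return pd.DataFrame({
        "clone_id": cons["clone_id"].to_numpy(),
        "chromosome": cons["chromosome"].to_numpy(),
        "start": start.to_numpy(),
        "end": end.to_numpy(),
    })


def insert_size_distribution(inserts, bin_width: int = DEFAULT_BIN_WIDTH
                             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of insert sizes with fixed-width bins anchored at zero.

    Returns ``(bin_centers, counts, mode)`` where the mode is the center of
    the maximal bin, ties broken toward the smaller bin.
    """
    values = np.asarray(inserts, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise EmptyDistributionError("no insert sizes to bin")
    # bin centers on the grid anchored at the smallest value, so a lone
    # value is the center (and mode) of its own bin
    lo = values.min()
    n_bins = int(np.floor((values.max() - lo) / bin_width + 0.5)) + 1
    edges = lo - bin_width / 2.0 + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    centers = edges[:-1] + bin_width / 2.0
    mode = float(centers[int(np.argmax(counts))])  # argmax takes first max
    return centers, counts, mode


def class_counts(classified: pd.DataFrame) -> dict[str, int]:
    counts = classified["class"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in ALL_CLASSES}
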