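"""Coordinate-level simulator for comparative BAC-end mapping experiments.

The simulator emulates the situation of mapping a large-insert (BAC) clone
library of a *target* species against the assembled genome of a related
*reference* species:

* a reference genome of ~20 chromosomes with non-overlapping gene annotations
  and an ortholog table linking each gene to a position on a *second*
  reference genome (the cross-validation species);
* a target genome derived from the reference by a uniform size inflation of
  the intergenic space (genes keep their length, mirroring the observation
  that teleost genomes accumulate indels mostly outside genes while gene
  synteny is conserved) plus planted intra-chromosomal rearrangements
  (segment inversions and transpositions);
* a clone library with Gaussian-like insert sizes placed uniformly on the
  target genome, inward-facing end reads, chimeric clones, unmappable ends
  and ambiguous (repeat-like) decoy hits.

Everything is simulated at the coordinate level: the output is the set of
tables a real experiment would produce after alignment (a BLAST-style
tabular hit table, a clone table, chromosome sizes, gene BED, ortholog
table) together with a ground-truth record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

# fixed sub-stream offsets so each generation step has its own stream
# derived from the single user-facing seed
_STREAM_REFERENCE = 1
_STREAM_TARGET = 2
_STREAM_LIBRARY = 3
_STREAM_ORTHOLOG = 4

#: 12-column BLAST tabular (outfmt 6) header used for all hit tables.
BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

# synthetic e-values: the primary hit is always overwhelmingly significant;
# decoys either keep the best hit 1e10-fold ahead (uniqueness ratio holds)
# or sit only 1e2-fold behind it (uniqueness ratio violated -> ambiguous)
PRIMARY_EVALUE = 1e-50
DECOY_EVALUE_PASS = 1e-40
DECOY_EVALUE_FAIL = 1e-48


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated mapping experiment.

    Defaults model a BAC library with 164 kbp mean inserts and ~670 bp end
    reads mapped onto a 21-chromosome reference at 1/10 linear scale, with
    the target genome 1.3-fold larger than the reference.
    """

    n_chromosomes: int = 21
    chromosome_length_range: tuple[int, int] = (3_000_000, 4_500_000)
    inflation_factor: float = 1.3
    n_rearrangements_per_chromosome: int = 2
    rearrangement_kind_weights: Mapping[str, float] = field(
        default_factory=lambda: {"inversion": 0.7, "transposition": 0.3}
    )
    n_clones: int = 6000
    insert_mean: float = 164_000.0
    insert_sd: float = 16_400.0
    end_read_length: int = 670
    chimera_rate: float = 0.02
    unmappable_end_rate: float = 0.15
    ambiguous_hit_rate: float = 0.10
    n_genes_per_chromosome: int = 60
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    n_ortholog_shuffles_per_chromosome: int = 0
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes", "must be >= 1")
        lo, hi = self.chromosome_length_range
        if not (0 < lo <= hi):
            raise ConfigError("chromosome_length_range", "need 0 < low <= high")
        if not (1.0 <= self.inflation_factor <= 3.0):
            raise ConfigError("inflation_factor", "must be in [1, 3]")
        if self.n_rearrangements_per_chromosome < 0:
            raise ConfigError("n_rearrangements_per_chromosome", "must be >= 0")
        weights = dict(self.rearrangement_kind_weights)
        if set(weights) - {"inversion", "transposition"} or any(
            w < 0 for w in weights.values()
        ):
            raise ConfigError(
                "rearrangement_kind_weights",
                "keys must be {inversion, transposition} with weights >= 0",
            )
        if self.n_rearrangements_per_chromosome > 0 and sum(weights.values()) <= 0:
            raise ConfigError("rearrangement_kind_weights", "weights sum to zero")
        if self.n_clones < 0:
            raise ConfigError("n_clones", "must be >= 0")
        if self.insert_mean <= 2 * self.end_read_length:
            raise ConfigError("insert_mean", "must exceed 2 x end_read_length")
        if self.insert_sd <= 0:
            raise ConfigError("insert_sd", "must be > 0")
        for name in ("chimera_rate", "unmappable_end_rate", "ambiguous_hit_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(name, "must be a probability in [0, 1]")
        if self.n_genes_per_chromosome < 0:
            raise ConfigError("n_genes_per_chromosome", "must be >= 0")
        glo, ghi = self.gene_length_range
        if not (0 < glo <= ghi):
            raise ConfigError("gene_length_range", "need 0 < low <= high")
        if self.n_genes_per_chromosome * ghi >= lo:
            raise ConfigError(
                "n_genes_per_chromosome",
                "genes cannot exceed the shortest chromosome",
            )
        return self


@dataclass
class ReferenceLayout:
    """Reference genome layout: chromosome sizes, genes and ortholog table.

    Coordinates are 0-based half-open throughout.
    """

    chromosomes: pd.DataFrame  # columns: chromosome, length
    genes: pd.DataFrame  # columns: chromosome, start, end, gene_id
    orthologs: pd.DataFrame  # gene_id, ref_chr, ref_start, ref_end, alt_chr, alt_start, alt_end

    def chromosome_lengths(self) -> dict[str, int]:
        return dict(zip(self.chromosomes["chromosome"], self.chromosomes["length"]))


@dataclass
class Block:
    """One piece of a target chromosome, taken from the reference.

    ``[t_start, t_end)`` on the target maps to ``[r_start, r_end)`` on the
    reference chromosome; ``strand`` is '+' for co-linear and '-' for
    inverted orientation.
    """

    t_start: float
    t_end: float
    r_start: int
    r_end: int
    strand: str


class ChromosomeMap:
    """Bijective piecewise map between one target chromosome and its
    reference chromosome.

    The map composes two layers: a block permutation (planted
    rearrangements) and a gene-aware inflation that stretches intergenic
    gaps by a constant factor while genes keep their length.
    """

    def __init__(self, ref_chrom: str, ref_length: int,
                 gene_bounds: np.ndarray, inflation: float,
                 pieces: Sequence[tuple[int, int, str]]):
        self.ref_chrom = ref_chrom
        self.ref_length = ref_length
        # inflation map g: reference coord -> inflated coord, piecewise
        # linear with slope 1 inside genes and slope gamma in gaps, where
        # gamma is set so the whole chromosome inflates by `inflation`.
        bounds = np.concatenate(([0], gene_bounds, [ref_length])).astype(float)
        bounds = np.unique(bounds)
        seg_len = np.diff(bounds)
        is_gene = np.zeros(len(seg_len), dtype=bool)
        if gene_bounds.size:
            starts, ends = gene_bounds[0::2], gene_bounds[1::2]
            mids = (bounds[:-1] + bounds[1:]) / 2.0
            idx = np.searchsorted(starts, mids, side="right") - 1
            ok = idx >= 0
            is_gene[ok] = mids[ok] < ends[idx[ok]]
        gene_bp = seg_len[is_gene].sum()
        gap_bp = ref_length - gene_bp
        if gap_bp > 0:
            gamma = (inflation * ref_length - gene_bp) / gap_bp
        else:
            gamma = 1.0
        slopes = np.where(is_gene, 1.0, gamma)
        y = np.concatenate(([0.0], np.cumsum(seg_len * slopes)))
        self._gx = bounds
        self._gy = y

        # target blocks, in target order
        self.blocks: list[Block] = []
        t = 0.0
        for r_start, r_end, strand in pieces:
            length = self._g(r_end) - self._g(r_start)
            self.blocks.append(Block(t, t + length, int(r_start), int(r_end), strand))
            t += length
        self.target_length = t
        self._block_t_starts = np.array([b.t_start for b in self.blocks])
        # reference-ordered view for ref->target lookups
        self._ref_order = sorted(range(len(self.blocks)),
                                 key=lambda i: self.blocks[i].r_start)
        self._ref_starts = np.array([self.blocks[i].r_start for i in self._ref_order])

    def _g(self, r):
        return np.interp(r, self._gx, self._gy)

    def _g_inv(self, y):
        return np.interp(y, self._gy, self._gx)

    def block_index_at_target(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self._block_t_starts, t, side="right") - 1
        return np.clip(idx, 0, len(self.blocks) - 1)

    def target_to_ref(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map target coordinates to (reference coordinate, strand sign)."""
        t = np.asarray(t, dtype=float)
        idx = self.block_index_at_target(t)
        r = np.empty_like(t)
        sign = np.empty(len(t), dtype=int)
        for i in np.unique(idx):
            b = self.blocks[i]
            m = idx == i
            u = t[m] - b.t_start
            if b.strand == "+":
                r[m] = self._g_inv(self._g(b.r_start) + u)
                sign[m] = 1
            else:
                r[m] = self._g_inv(self._g(b.r_end) - u)
                sign[m] = -1
        return r, sign

    def ref_to_target(self, r: np.ndarray) -> np.ndarray:
        """Map reference coordinates to target coordinates (bijection)."""
        r = np.asarray(r, dtype=float)
        idx = np.searchsorted(self._ref_starts, r, side="right") - 1
        idx = np.clip(idx, 0, len(self._ref_starts) - 1)
        out = np.empty_like(r)
        for j in np.unique(idx):
            b = self.blocks[self._ref_order[j]]
            m = idx == j
            if b.strand == "+":
                out[m] = b.t_start + (self._g(r[m]) - self._g(b.r_start))
            else:
                out[m] = b.t_start + (self._g(b.r_end) - self._g(r[m]))
        return out

    def junction_targets(self) -> np.ndarray:
        """Target coordinates of non-trivial block junctions (breakpoints)."""
        coords = []
        for left, right in zip(self.blocks[:-1], self.blocks[1:]):
            if left.strand == "+" and right.strand == "+" and left.r_end == right.r_start:
                continue
            coords.append(right.t_start)
        return np.array(coords)

    def map_read(self, t_start: float, length: float, sigma: int
                 ) -> tuple[float, float, str]:
        """Map a read interval on the target to the reference.

        Reads crossing a block junction are attributed to the block holding
        their first base (the remainder is clipped), which is how a local
        aligner would place such a read.
        """
        i = int(self.block_index_at_target(np.array([t_start]))[0])
        b = self.blocks[i]
        t_end = min(t_start + length, b.t_end)
        r1 = float(self.target_to_ref(np.array([t_start]))[0][0])
        r2 = float(self.target_to_ref(np.array([t_end]))[0][0])
        lo, hi = (r1, r2) if r1 <= r2 else (r2, r1)
        block_sign = 1 if b.strand == "+" else -1
        strand = "+" if sigma * block_sign > 0 else "-"
        return lo, hi, strand


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    inflation_factor: float
    maps: dict[str, ChromosomeMap]
    breakpoints: list[tuple[str, float, float]]  # (ref chrom, joined ref coords)
    clone_truth: dict[str, str] = field(default_factory=dict)
    clone_inserts: dict[str, float] = field(default_factory=dict)
    orthologs: pd.DataFrame | None = None

    def target_lengths(self) -> dict[str, float]:
        return {c: m.target_length for c, m in self.maps.items()}

    def to_jsonable(self) -> dict:
        return {
            "inflation_factor": self.inflation_factor,
            "target_lengths": self.target_lengths(),
            "breakpoints": [
                {"chromosome": c, "coord_a": a, "coord_b": b}
                for c, a, b in self.breakpoints
            ],
            "blocks": {
                chrom: [dataclasses.asdict(b) for b in m.blocks]
                for chrom, m in self.maps.items()
            },
            "clones": {
                cid: {"class": cls, "insert": self.clone_inserts.get(cid)}
                for cid, cls in self.clone_truth.items()
            },
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_jsonable(), indent=1))


def _chrom_name(i: int) -> str:
    return f"chr{i + 1:02d}"


def _alt_chrom_name(i: int) -> str:
    return f"alt{i + 1:02d}"


def _place_genes(rng: np.random.Generator, length: int, n: int,
                 len_range: tuple[int, int]) -> np.ndarray:
    """Sample n non-overlapping gene intervals on [0, length)."""
    if n == 0:
        return np.empty((0, 2), dtype=int)
    lens = rng.integers(len_range[0], len_range[1] + 1, size=n)
    slack = length - int(lens.sum())
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    starts = offsets + np.concatenate(([0], np.cumsum(lens[:-1])))
    return np.stack([starts, starts + lens], axis=1)


def _alt_coordinates(order: Sequence[int], lengths: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Lay genes (given by index order) along a second-reference chromosome.

    Returns an (n, 2) array of alt start/end per gene, indexed like the
    input gene list, with order-preserving positions and random intergenic
    gaps.
    """
    n = len(order)
    out = np.zeros((n, 2), dtype=int)
    pos = 0
    for idx in order:
        gap = int(rng.integers(10_000, 50_000))
        pos += gap
        out[idx] = (pos, pos + int(lengths[idx]))
        pos += int(lengths[idx])
    return out


def simulate_reference(config: SimConfig) -> ReferenceLayout:
    """Generate the reference genome layout.

    Produces chromosome sizes, a non-overlapping gene annotation, and an
    ortholog table that places every gene on a second-reference chromosome
    preserving within-chromosome gene order, except for
    ``n_ortholog_shuffles_per_chromosome`` planted adjacent swaps.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_REFERENCE])
    lo, hi = config.chromosome_length_range
    chroms, gene_rows = [], []
    for i in range(config.n_chromosomes):
        name = _chrom_name(i)
        length = int(rng.integers(lo, hi + 1))
        chroms.append({"chromosome": name, "length": length})
        intervals = _place_genes(rng, length, config.n_genes_per_chromosome,
                                 config.gene_length_range)
        for k, (s, e) in enumerate(intervals):
            gene_rows.append({
                "chromosome": name, "start": int(s), "end": int(e),
                "gene_id": f"g_{name}_{k:04d}",
            })
    chrom_df = pd.DataFrame(chroms)
    genes = pd.DataFrame(gene_rows,
                         columns=["chromosome", "start", "end", "gene_id"])
    ortho_rng = np.random.default_rng([config.seed, _STREAM_ORTHOLOG])
    orthologs = _ortholog_table(genes, config, ortho_rng, target_order=None)
    return ReferenceLayout(chrom_df, genes, orthologs)


def _ortholog_table(genes: pd.DataFrame, config: SimConfig,
                    rng: np.random.Generator,
                    target_order: Mapping[str, Sequence[int]] | None
                    ) -> pd.DataFrame:
    """Build the gene-to-second-reference table.

    ``target_order`` maps each chromosome to the positional order of its
    genes (indices into the per-chromosome gene table) along the *target*
    genome; when None, reference order is used.
    """
    rows = []
    for ci, (chrom, sub) in enumerate(genes.groupby("chromosome", sort=True)):
        sub = sub.sort_values("start").reset_index(drop=True)
        lengths = (sub["end"] - sub["start"]).to_numpy()
        if target_order is None:
            order = list(range(len(sub)))
        else:
            order = list(target_order[chrom])
        for _ in range(config.n_ortholog_shuffles_per_chromosome):
            if len(order) >= 2:
                j = int(rng.integers(0, len(order) - 1))
                order[j], order[j + 1] = order[j + 1], order[j]
        alt = _alt_coordinates(order, lengths, rng)
        alt_chrom = _alt_chrom_name(int(chrom[3:]) - 1) if chrom.startswith("chr") \
            else f"alt_{chrom}"
        for i, row in sub.iterrows():
            rows.append({
                "gene_id": row["gene_id"], "ref_chr": chrom,
                "ref_start": int(row["start"]), "ref_end": int(row["end"]),
                "alt_chr": alt_chrom,
                "alt_start": int(alt[i, 0]), "alt_end": int(alt[i, 1]),
            })
    return pd.DataFrame(rows, columns=["gene_id", "ref_chr", "ref_start",
                                       "ref_end", "alt_chr", "alt_start",
                                       "alt_end"])


def _sample_rearrangements(rng: np.random.Generator, length: int,
                           config: SimConfig) -> list[tuple[int, int, str]]:
    """Choose the target block layout (reference pieces in target order).

    Rearranged segment lengths are drawn uniformly in
    ``[2 x insert_mean, length / 5]`` so every segment can be spanned by a
    clone yet never dominates the chromosome. Each rearrangement is placed
    in its own chromosome zone, and every cut point keeps at least one
    maximal clone length (mean + 4 sd) of separation from all others and
    from the chromosome ends, so a clone can straddle at most one
    junction.
    """
    n = config.n_rearrangements_per_chromosome
    if n == 0:
        return [(0, length, "+")]
    margin = int(config.insert_mean + 4 * config.insert_sd)
    # a transposition is only detectable by paired-end distance when the
    # reference-coordinate jump across each of its junctions exceeds the
    # widest plausible insert span; inversions flip orientation and are
    # detectable at any displacement
    detect_jump = max(int(2.5 * config.insert_mean), margin)
    seg_hi_global = length // 5
    zone = (length - 2 * margin) / n
    kinds_all = sorted(config.rearrangement_kind_weights)
    weights = np.array(
        [config.rearrangement_kind_weights[k] for k in kinds_all], dtype=float)
    weights = weights / weights.sum()
    kinds = [kinds_all[i] for i in rng.choice(len(kinds_all), size=n, p=weights)]

    cuts: list[int] = []
    segs: list[tuple[int, int, str]] = []  # (start, end, kind)
    inserts: dict[int, int] = {}  # segment index -> insertion cut
    for i, kind in enumerate(kinds):
        z0 = margin + i * zone
        z1 = z0 + zone - margin  # cuts confined to [z0, z1]
        if kind == "inversion":
            seg_lo, extra = max(int(2 * config.insert_mean), margin), 0
        else:
            seg_lo, extra = detect_jump, detect_jump
        max_len = min(seg_hi_global, int(z1 - z0 - extra))
        if seg_lo > max_len:
            raise ConfigError(
                "n_rearrangements_per_chromosome",
                f"cannot fit {n} rearranged segments of >= {seg_lo} bp on a "
                f"chromosome of {length} bp",
            )
        seg_len = int(rng.integers(seg_lo, max_len + 1))
        slack = (z1 - z0) - seg_len - extra
        if kind == "inversion":
            a = int(z0 + rng.uniform(0, slack))
            segs.append((a, a + seg_len, kind))
            cuts.extend([a, a + seg_len])
        else:
            u1, u2 = np.sort(rng.uniform(0, slack, size=2))
            if rng.random() < 0.5:  # insertion cut upstream of the segment
                c = int(z0 + u1)
                a = int(c + extra + (u2 - u1))
            else:
                a = int(z0 + u1)
                c = int(a + seg_len + extra + (u2 - u1))
            segs.append((a, a + seg_len, kind))
            inserts[len(segs) - 1] = c
            cuts.extend([a, a + seg_len, c])

    boundaries = sorted(set([0, length] + cuts))
    pieces = [(boundaries[i], boundaries[i + 1], "+")
              for i in range(len(boundaries) - 1)]

    def piece_at(coord):
        for i, (a, _b, _s) in enumerate(pieces):
            if a == coord:
                return i
        raise AssertionError("cut not on a piece boundary")

    # inversions: flip the matching piece in place
    for (a, b, kind) in segs:
        if kind == "inversion":
            i = piece_at(a)
            assert pieces[i][1] == b
            pieces[i] = (a, b, "-")
    # transpositions: move the piece to its insertion cut
    for si, (a, b, kind) in enumerate(segs):
        if kind != "transposition":
            continue
        piece = pieces.pop(piece_at(a))
        pieces.insert(piece_at(inserts[si]), piece)
    return pieces


def simulate_target_genome(reference: ReferenceLayout, config: SimConfig
                           ) -> SimTruth:
    """Derive the target genome from the reference.

    Each target chromosome is the corresponding reference chromosome with
    intergenic gaps inflated (total length = inflation_factor x reference
    length) and ``n_rearrangements_per_chromosome`` planted inversions /
    transpositions. Returns the ground truth, including the bijective
    segment map, the list of breakpoints (pairs of reference coordinates
    joined in the target) and the final ortholog table, whose
    second-reference gene order follows the *target* arrangement: the
    second reference shares the planted rearrangements, as expected for an
    outgroup that diverged before the reference lineage.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_TARGET])
    maps: dict[str, ChromosomeMap] = {}
    breakpoints: list[tuple[str, float, float]] = []
    target_order: dict[str, list[int]] = {}
    for _, row in reference.chromosomes.iterrows():
        chrom, length = row["chromosome"], int(row["length"])
        sub = reference.genes[reference.genes["chromosome"] == chrom]
        sub = sub.sort_values("start")
        gene_bounds = np.sort(
            np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()])
        ).astype(float) if len(sub) else np.array([])
        pieces = _sample_rearrangements(rng, length, config)
        cmap = ChromosomeMap(chrom, length, gene_bounds,
                             config.inflation_factor, pieces)
        maps[chrom] = cmap
        for left, right in zip(cmap.blocks[:-1], cmap.blocks[1:]):
            if (left.strand == "+" and right.strand == "+"
                    and left.r_end == right.r_start):
                continue
            coord_a = float(left.r_end if left.strand == "+" else left.r_start)
            coord_b = float(right.r_start if right.strand == "+" else right.r_end)
            breakpoints.append((chrom, coord_a, coord_b))
        if len(sub):
            mids = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
            tpos = cmap.ref_to_target(mids)
            target_order[chrom] = list(np.argsort(tpos, kind="stable"))
        else:
            target_order[chrom] = []
    ortho_rng = np.random.default_rng([config.seed, _STREAM_ORTHOLOG])
    orthologs = _ortholog_table(reference.genes, config, ortho_rng,
                                target_order=target_order)
    return SimTruth(config.inflation_factor, maps, breakpoints,
                    orthologs=orthologs)


def _truncated_normal_inserts(rng: np.random.Generator, config: SimConfig,
                              size: int) -> np.ndarray:
    low = 2.0 * config.end_read_length
    a = (low - config.insert_mean) / config.insert_sd
    return stats.truncnorm.rvs(a, np.inf, loc=config.insert_mean,
                               scale=config.insert_sd, size=size,
                               random_state=rng)


def simulate_library(truth: SimTruth, config: SimConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the clone library and its alignment hit table.

    Returns ``(clone_table, hit_table)``. Clone inserts are truncated-normal
    on the target genome; end reads are taken inward-facing from the insert
    extremities; each mappable end yields one primary hit placed through the
    segment map; chimeric clones take their two ends from independent
    placements; ambiguous ends carry an extra decoy hit; unmappable ends
    yield no hit. ``truth.clone_truth`` / ``truth.clone_inserts`` are
    filled in.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_LIBRARY])
    chroms = sorted(truth.maps)
    lengths = np.array([truth.maps[c].target_length for c in chroms])
    n = config.n_clones
    clone_rows, hit_rows = [], []
    if n == 0:
        return (pd.DataFrame(columns=["clone_id", "fwd_read_id", "rev_read_id"]),
                pd.DataFrame(columns=BLAST_COLUMNS))
    probs = lengths / lengths.sum()
    inserts = _truncated_normal_inserts(rng, config, n)
    chimeric = rng.random(n) < config.chimera_rate
    rl = config.end_read_length

    def _placement(insert):
        ci = rng.choice(len(chroms), p=probs)
        cmap = truth.maps[chroms[ci]]
        insert = min(insert, 0.9 * cmap.target_length)
        start = rng.uniform(0, cmap.target_length - insert)
        return chroms[ci], cmap, start, insert

    def _emit_hit(read_id, cmap, chrom, t_start, sigma):
        lo, hi, strand = cmap.map_read(t_start, rl, sigma)
        lo_i, hi_i = int(round(lo)), max(int(round(hi)), int(round(lo)) + 1)
        if strand == "+":
            sstart, send = lo_i + 1, hi_i
        else:
            sstart, send = hi_i, lo_i + 1
        hit_rows.append((read_id, chrom, 98.5, rl, 5, 0, 1, rl,
                         sstart, send, PRIMARY_EVALUE, 1200.0))

    def _emit_decoy(read_id):
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        pos = int(rng.uniform(0, truth.maps[chrom].target_length / config.inflation_factor - rl))
        ev = DECOY_EVALUE_FAIL if rng.random() < 0.5 else DECOY_EVALUE_PASS
        hit_rows.append((read_id, chrom, 90.0, rl, 40, 2, 1, rl,
                         pos + 1, pos + rl, ev, 600.0))

    for k in range(n):
        cid = f"bac{k:05d}"
        fwd_id, rev_id = f"{cid}_F", f"{cid}_R"
        clone_rows.append((cid, fwd_id, rev_id))
        chrom, cmap, start, insert = _placement(inserts[k])
        truth.clone_inserts[cid] = float(insert)
        if chimeric[k]:
            truth.clone_truth[cid] = "chimeric"
            chrom2, cmap2, start2, insert2 = _placement(
                float(_truncated_normal_inserts(rng, config, 1)[0]))
            ends = [(fwd_id, cmap, chrom, start, +1),
                    (rev_id, cmap2, chrom2, start2 + insert2 - rl, -1)]
        else:
            junc = cmap.junction_targets()
            spans = bool(np.any((junc > start) & (junc < start + insert)))
            truth.clone_truth[cid] = "spans_breakpoint" if spans else "normal"
            ends = [(fwd_id, cmap, chrom, start, +1),
                    (rev_id, cmap, chrom, start + insert - rl, -1)]
        for read_id, m, c, t0, sigma in ends:
            if rng.random() < config.unmappable_end_rate:
                continue
            _emit_hit(read_id, m, c, t0, sigma)
            if rng.random() < config.ambiguous_hit_rate:
                _emit_decoy(read_id)

    clones = pd.DataFrame(clone_rows,
                          columns=["clone_id", "fwd_read_id", "rev_read_id"])
    hits = pd.DataFrame(hit_rows, columns=BLAST_COLUMNS)
    return clones, hits


def simulate_experiment(config: SimConfig
                        ) -> tuple[ReferenceLayout, SimTruth,
                                   pd.DataFrame, pd.DataFrame]:
    """Run the three simulation stages and return all artifacts."""
    reference = simulate_reference(config)
    truth = simulate_target_genome(reference, config)
    clones, hits = simulate_library(truth, config)
    return reference, truth, clones, hits


# ---------------------------------------------------------------------------
# on-disk artifact writers (TSV / BED / BLAST tabular / JSON)

def write_reference(reference: ReferenceLayout, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference.chromosomes.to_csv(outdir / "chromosomes.tsv", sep="\t", index=False)
    reference.genes.to_csv(outdir / "genes.bed", sep="\t", index=False,
                           header=False,
                           columns=["chromosome", "start", "end", "gene_id"])
    reference.orthologs.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)


def write_library(clones: pd.DataFrame, hits: pd.DataFrame, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clones.to_csv(outdir / "clones.tsv", sep="\t", index=False)
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False, header=False)


def read_gene_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chromosome", "start", "end", "gene_id"])
    return df
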