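"""Stage functions over on-disk artifacts.

Each stage reads and writes plain TSV/BED/JSON files inside one working
directory, so every step is independently runnable and re-runnable; the
CLI and the analysis drivers are thin wrappers around these functions.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import genome_size as gs
from . import hits as hitmod
from . import pairs, rearrange, report, simulate, tiling
from .errors import MissingInputError

log = logging.getLogger("bacmap")


@dataclasses.dataclass
class RunConfig:
    """Pipeline-wide thresholds (defaults are the standard filter settings:
    e-value cutoff 1e-5, uniqueness ratio 1e5)."""

    evalue_cutoff: float = hitmod.DEFAULT_EVALUE_CUTOFF
    ratio_threshold: float = hitmod.DEFAULT_RATIO_THRESHOLD
    min_insert: float | None = None
    max_insert: float | None = None
    bin_width: int = pairs.DEFAULT_BIN_WIDTH
    edge_tolerance: float | None = None
    adjacency_threshold: float = rearrange.DEFAULT_ADJACENCY_THRESHOLD
    flank_window: float = rearrange.DEFAULT_FLANK_WINDOW
    sim: simulate.SimConfig = dataclasses.field(default_factory=simulate.SimConfig)

    def policy(self) -> pairs.ConsistencyPolicy:
        if self.min_insert is not None and self.max_insert is not None:
            return pairs.ConsistencyPolicy(self.min_insert, self.max_insert)
        return pairs.ConsistencyPolicy.default(self.sim.insert_mean)

    def resolved_edge_tolerance(self) -> float:
        if self.edge_tolerance is not None:
            return self.edge_tolerance
        return rearrange.default_edge_tolerance(self.sim.insert_mean)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = simulate.SimConfig(**raw.pop("sim", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        return cls(sim=sim, **{k: v for k, v in raw.items() if k in known})


def _require(path: Path) -> Path:
    if not path.exists():
        raise MissingInputError(path)
    return path


def run_simulate(config: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    reference, truth, clones, hits = simulate.simulate_experiment(config.sim)
    simulate.write_reference(reference, outdir)
    truth.orthologs.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
    simulate.write_library(clones, hits, outdir)
    truth.save(outdir / "truth.json")
    log.info("simulated %d clones, %d hit rows on %d chromosomes",
             len(clones), len(hits), config.sim.n_chromosomes)


def run_filter(config: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    table = hitmod.read_hit_table(_require(outdir / "hits.tsv"))
    accepted, rejected = hitmod.place_reads(
        {"20": table}, evalue_cutoff=config.evalue_cutoff,
        ratio_threshold=config.ratio_threshold)
    accepted.to_csv(outdir / "placements.tsv", sep="\t", index=False)
    rejected.to_csv(outdir / "rejected.tsv", sep="\t", index=False)
    log.info("filter: %d hits in, %d reads accepted, %d rejected",
             len(table), len(accepted), len(rejected))


def run_classify(config: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    clones = pd.read_csv(_require(outdir / "clones.tsv"), sep="\t")
    placements = pd.read_csv(_require(outdir / "placements.tsv"), sep="\t")
    classified = pairs.classify_clones(clones, placements, config.policy())
    classified.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    log.info("classify: %s", pairs.class_counts(classified))


def run_tile(config: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    classified = pd.read_csv(_require(outdir / "classification.tsv"), sep="\t")
    chroms = pd.read_csv(_require(outdir / "chromosomes.tsv"), sep="\t")
    genes = simulate.read_gene_bed(_require(outdir / "genes.bed"))
    lengths = dict(zip(chroms["chromosome"], chroms["length"]))
    contigs = tiling.build_contigs(pairs.clone_intervals(classified), lengths)
    counts = (classified.groupby("chromosome")["class"]
              .value_counts().unstack(fill_value=0).reset_index())
    counts = counts.rename(columns={
        pairs.CLASS_CONSISTENT: "n_consistent",
        pairs.CLASS_ONE_END: "n_one_end",
        pairs.CLASS_INCONSISTENT: "n_inconsistent"})
    stats = tiling.map_statistics(contigs, lengths, genes, counts)
    tiling.contigs_to_frame(contigs).to_csv(outdir / "contigs.tsv",
                                            sep="\t", index=False)
    all_row = report.aggregate(stats, [c.length for c in contigs])
    stats_out = pd.concat([stats, all_row.to_frame().T], ignore_index=True)
    stats_out.to_csv(outdir / "chromosome_stats.tsv", sep="\t", index=False)
    log.info("tile: %d contigs, %.1f%% covered",
             len(contigs), all_row["pct_covered"])


def run_size(config: RunConfig, outdir) -> None:
    import json

    outdir = Path(outdir)
    classified = pd.read_csv(_require(outdir / "classification.tsv"), sep="\t")
    chroms = pd.read_csv(_require(outdir / "chromosomes.tsv"), sep="\t")
    truth = json.loads(_require(outdir / "truth.json").read_text())
    mapped = classified["implied_insert"].dropna()
    _, _, mapped_mode = pairs.insert_size_distribution(mapped, config.bin_width)
    library = [c["insert"] for c in truth["clones"].values()
               if c["insert"] is not None]
    _, _, library_mode = pairs.insert_size_distribution(library,
                                                        config.bin_width)
    est = gs.estimate_genome_size(mapped_mode, library_mode,
                                  float(chroms["length"].sum()))
    pd.DataFrame([{
        "mapped_mode": est.mapped_mode, "library_mode": est.library_mode,
        "ratio": est.ratio, "reference_size": est.reference_size,
        "estimated_size": est.estimated_size,
        "estimated_size_rounded": gs.round_genome_size(est.estimated_size),
    }]).to_csv(outdir / "genome_size.tsv", sep="\t", index=False)
    log.info("size: ratio %.3f, estimate %.0f bp", est.ratio,
             est.estimated_size)


def _load_contigs(outdir: Path) -> list[tiling.BacContig]:
    frame = pd.read_csv(_require(outdir / "contigs.tsv"), sep="\t")
    classified = pd.read_csv(_require(outdir / "classification.tsv"), sep="\t")
    intervals = pairs.clone_intervals(classified)
    coords = {r["clone_id"]: (int(r["start"]), int(r["end"]))
              for _, r in intervals.iterrows()}
    contigs = []
    for _, r in frame.iterrows():
        members = [(cid, *coords[cid]) for cid in r["members"].split(",")]
        c = tiling.BacContig(r["contig_id"], r["chromosome"], int(r["start"]),
                             int(r["end"]), members,
                             r["tiling_path"].split(","))
        contigs.append(c)
    return contigs


def run_rearrange(config: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    classified = pd.read_csv(_require(outdir / "classification.tsv"), sep="\t")
    contigs = _load_contigs(outdir)
    cand = rearrange.detect_candidates(classified, contigs,
                                       config.resolved_edge_tolerance())
    cand.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    log.info("rearrange: %d candidates / %d inconsistent clones",
             int((cand["status"] == rearrange.STATUS_CANDIDATE).sum()),
             len(cand))


def run_crosscheck(config: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    cand = pd.read_csv(_require(outdir / "candidates.tsv"), sep="\t")
    orthologs = pd.read_csv(_require(outdir / "orthologs.tsv"), sep="\t")
    contigs = _load_contigs(outdir)
    checked = rearrange.crosscheck_second_reference(
        cand, contigs, orthologs, config.adjacency_threshold,
        config.flank_window)
    checked.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    groups = rearrange.group_candidates_by_breakpoint(checked)
    groups.to_csv(outdir / "breakpoints.tsv", sep="\t", index=False)
    log.info("crosscheck: %d breakpoints, %d confirmed candidates",
             len(groups),
             int((checked["status"] == rearrange.STATUS_CONFIRMED).sum()))


def run_report(config: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    classified = pd.read_csv(_require(outdir / "classification.tsv"), sep="\t")
    contigs = _load_contigs(outdir)
    report.export_gff(contigs, classified, outdir / "map.gff3")
    log.info("report: wrote %s", outdir / "map.gff3")


STAGES = {
    "simulate": run_simulate,
    "filter": run_filter,
    "classify": run_classify,
    "tile": run_tile,
    "size": run_size,
    "rearrange": run_rearrange,
    "crosscheck": run_crosscheck,
    "report": run_report,
}
STAGE_ORDER = list(STAGES)


def run_all(config: RunConfig, outdir) -> None:
    for name in STAGE_ORDER:
        STAGES[name](config, outdir)
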