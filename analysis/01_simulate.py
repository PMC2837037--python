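#!/usr/bin/env python
"""Simulate the study dataset: a 21-chromosome reference genome, a target
genome 1.3-fold larger with two planted intra-chromosomal rearrangements
per chromosome, and a ~9.6x BAC library with end-read alignment hits.

Writes the input tables (chromosomes.tsv, genes.bed, orthologs.tsv,
clones.tsv, hits.tsv) and the ground-truth record into results/run/.
"""

import argparse
import json
from pathlib import Path

from bacmap.pipeline import RunConfig, run_simulate
from bacmap.simulate import SimConfig

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results/run"))
args = ap.parse_args()

cfg = RunConfig(sim=SimConfig(seed=args.seed))
args.outdir.mkdir(parents=True, exist_ok=True)
run_simulate(cfg, args.outdir)

truth = json.loads((args.outdir / "truth.json").read_text())
n_bp = len(truth["breakpoints"])
total_target = sum(truth["target_lengths"].values())
print(f"simulated {cfg.sim.n_clones} clones on a "
      f"{total_target / 1e6:.1f} Mbp target genome "
      f"({cfg.sim.inflation_factor}x the reference), "
      f"{n_bp} planted breakpoints")
print(f"artifacts in {args.outdir}/")
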