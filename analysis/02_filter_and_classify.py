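#!/usr/bin/env python
"""Filter the hit table (e-value cutoff 1e-5, best/second-best uniqueness
ratio 1e5) and classify every clone by paired-end consistency.

Reads the simulation artifacts from results/run/, writes placements.tsv,
rejected.tsv and classification.tsv there, and prints the clone-class
breakdown (the shape of the published campaign's consistency screen).
"""

import argparse
from pathlib import Path

import pandas as pd

from bacmap.pairs import class_counts
from bacmap.pipeline import RunConfig, run_classify, run_filter

ap = argparse.ArgumentParser()
ap.add_argument("--outdir", type=Path, default=Path("results/run"))
args = ap.parse_args()

cfg = RunConfig()
run_filter(cfg, args.outdir)
run_classify(cfg, args.outdir)

classified = pd.read_csv(args.outdir / "classification.tsv", sep="\t")
counts = class_counts(classified)
print("clone classification:")
for cls, n in counts.items():
    print(f"  {cls:24s} {n:6d}")
rej = pd.read_csv(args.outdir / "rejected.tsv", sep="\t")
print("read rejections:", rej["reason"].value_counts().to_dict())
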