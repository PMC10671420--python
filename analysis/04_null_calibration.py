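"""Calibration of the enrichment test under a permutation null.

Shuffles module labels 200 times over a 400-gene universe with three
module-sized label groups and three gene sets, recomputes Fisher's exact
test for every (module, set) pair, and reports the empirical type-I
error rate at raw p < 0.05 together with the Benjamini-Hochberg false
positive count.  Writes results/null_calibration.tsv.

Usage: python analysis/04_null_calibration.py [--seed N]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pmscoex import fisher_enrichment
from pmscoex.genesets import GeneSet, build_annotation
from pmscoex.modules import ModulePartition

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=2024)
parser.add_argument("--reps", type=int, default=200)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

rng = np.random.default_rng(args.seed)
genes = [f"G{i:03d}" for i in range(400)]
annotation = build_annotation(
    [
        GeneSet("A", frozenset(rng.choice(genes, 80, replace=False))),
        GeneSet("B", frozenset(rng.choice(genes, 50, replace=False))),
        GeneSet("C", frozenset(rng.choice(genes, 120, replace=False))),
    ]
)
base = np.array([1] * 80 + [2] * 80 + [3] * 80 + [0] * 160)

raw_hits = bh_hits = total = 0
per_rep = []
for rep in range(args.reps):
    part = ModulePartition(pd.Series(rng.permutation(base), index=genes))
    res = fisher_enrichment(part, annotation)
    r = int((res.table["p"] < 0.05).sum())
    q = int((res.table["q"] < 0.05).sum())
    raw_hits += r
    bh_hits += q
    total += len(res.table)
    per_rep.append({"rep": rep, "raw_p_lt_05": r, "bh_q_lt_05": q})

rate = raw_hits / total
pd.DataFrame(per_rep).to_csv(args.out / "null_calibration.tsv", sep="\t", index=False)
print(f"{args.reps} label permutations, {total} (module, set) tests")
print(f"raw p < 0.05 rate: {rate:.4f} (nominal 0.05; exact-test discreteness "
      "keeps it at or below nominal)")
print(f"BH q < 0.05 false positives: {bh_hits}/{total}")
print(f"wrote {args.out}/null_calibration.tsv")
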