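"""Score the pipeline run against the planted ground truth.

Compares the recovered module partition with the generator's truth
(adjusted Rand index, per-module best-match Jaccard), checks that every
planted (module, gene set) pair out-ranks all non-planted pairs in its
enrichment column, and verifies that the planted high-loading region
hub heads the ASD candidate list.  Writes results/recovery_summary.tsv
and results/planted_enrichment_ranks.tsv.

Usage (after 01 and 02): python analysis/03_evaluate_recovery.py
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pmscoex import score_recovery
from pmscoex.modules import GREY_LABEL, ModulePartition
from pmscoex.simulate import PlantedTruth

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--pipeline", type=Path, default=Path("results/pipeline"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

truth_raw = json.loads((args.data / "truth.json").read_text())
module_of = pd.Series(truth_raw["module_of"], name="module")
truth = PlantedTruth(
    module_of=module_of,
    loadings=pd.Series(truth_raw["loadings"], dtype=float),
    factors=pd.DataFrame(),
    planted_sets=truth_raw["planted_sets"],
)

assignments = pd.read_csv(args.pipeline / "module_assignments.tsv", sep="\t", index_col="gene")
part = ModulePartition(labels=assignments["module"])
part.colors.update(
    {int(m): c for m, c in zip(assignments["module"], assignments["module_color"]) if int(m) != GREY_LABEL}
)
score = score_recovery(truth, part)

enrich = pd.read_csv(args.pipeline / "enrichment.tsv", sep="\t")
rank_rows = []
for set_name, planted in truth.planted_sets.items():
    sub = enrich[enrich["set"] == set_name].sort_values("p").reset_index(drop=True)
    for m in planted:
        genes = set(truth.module_genes(m))
        jac = {
            mod: len(genes & set(part.members(mod))) / len(genes | set(part.members(mod)))
            for mod in part.module_ids
        }
        rec = max(jac, key=jac.get)
        rank = int(sub.index[sub["module"] == rec][0]) + 1
        rank_rows.append(
            {
                "set": set_name,
                "planted_module": m,
                "recovered_module": part.color_of_module(rec),
                "jaccard": round(jac[rec], 4),
                "enrichment_rank": rank,
                "p": sub.loc[rank - 1, "p"],
            }
        )
ranks = pd.DataFrame(rank_rows)
ranks.to_csv(args.out / "planted_enrichment_ranks.tsv", sep="\t", index=False)

candidates = pd.read_csv(args.pipeline / "candidate_table.tsv", sep="\t")
asd = candidates.query("phenotype == 'ASD'").reset_index(drop=True)
hub_rank = int(asd.index[asd["gene"] == "M1HUB1"][0]) + 1 if "M1HUB1" in set(asd["gene"]) else None

summary = pd.DataFrame(
    [
        {"metric": "adjusted_rand_index", "value": round(score.ari, 4)},
        {"metric": "mean_best_match_jaccard", "value": round(float(score.jaccard.mean()), 4)},
        {"metric": "n_planted_pairs_top_ranked", "value": int((ranks["enrichment_rank"] == 1).sum())},
        {"metric": "n_planted_pairs", "value": len(ranks)},
        {"metric": "hub_rank_in_asd_candidates", "value": hub_rank},
        {"metric": "n_candidates_total", "value": len(candidates)},
    ]
)
summary.to_csv(args.out / "recovery_summary.tsv", sep="\t", index=False)

print(f"module recovery: ARI = {score.ari:.3f}, "
      f"mean best-match Jaccard = {score.jaccard.mean():.3f}")
print(f"planted enrichment pairs ranked first in their column: "
      f"{(ranks['enrichment_rank'] == 1).sum()}/{len(ranks)}")
print(f"planted hub rank in ASD candidate list: {hub_rank}")
print(f"wrote {args.out}/recovery_summary.tsv and planted_enrichment_ranks.tsv")
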