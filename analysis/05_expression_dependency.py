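#!/usr/bin/env python
"""Knockdown dependency analysis and integration with peak-assigned genes.

Applies the strict 1.5-fold filter to each factor knockdown, intersects
the down-regulated sets with the SRF-dependent set, and splits each
dependency set into direct (peak-assigned) and indirect targets.  Writes
gene lists and a JSON summary under results/expression/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from srfpipe.config import PipelineConfig
from srfpipe.expression import (
    ExpressionTable,
    GeneSet,
    classify_direct_targets,
    dependent_genes,
    intersect_sets,
    write_gene_set,
)
from srfpipe.simulate import GroundTruth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--anndir", type=Path, default=Path("results/annotation"))
    ap.add_argument("--outdir", type=Path, default=Path("results/expression"))
    args = ap.parse_args()
    c = PipelineConfig()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = ExpressionTable.from_tsv(args.simdir / "expression.tsv")
    truth = GroundTruth.from_json(args.simdir / "ground_truth.json")
    peak_factor = {"SRF": "SRF", "MKL12": "MKL1", "ELK4": "ELK4"}

    summary = {}
    down_sets = {}
    for factor in ("SRF", "MKL12", "ELK4"):
        down = dependent_genes(table, f"{factor}_kd", "NS", c.fc_cutoff, "down",
                               f"{factor}_down")
        up = dependent_genes(table, f"{factor}_kd", "NS", c.fc_cutoff, "up",
                             f"{factor}_up")
        down_sets[factor] = down
        write_gene_set(down, args.outdir / f"{factor}_down.txt")
        write_gene_set(up, args.outdir / f"{factor}_up.txt")
        planted = {g.upper() for g in truth.dependent[factor]["down"]}
        tp = len(down.genes & planted)
        print(f"{factor}: {len(down)} down / {len(up)} up at >{c.fc_cutoff}-fold "
              f"({tp}/{len(planted)} planted down-genes recovered)")
        summary[factor] = {"down": len(down), "up": len(up),
                           "planted_recovered": tp, "planted": len(planted)}

    for factor in ("MKL12", "ELK4"):
        inter = intersect_sets(down_sets["SRF"], down_sets[factor])
        summary[f"SRF&{factor}"] = len(inter)
        print(f"SRF & {factor}: {len(inter)} shared down-regulated genes")

    for factor, pf in peak_factor.items():
        ann = pd.read_csv(args.anndir / f"annotated_{pf}.tsv", sep="\t")
        peak_genes = GeneSet.from_symbols(
            f"{pf}_peak_genes", [g for g in ann["gene"] if g != "."]
        )
        direct, indirect = classify_direct_targets(down_sets[factor], peak_genes)
        summary[f"{factor}_direct"] = {"direct": len(direct), "indirect": len(indirect)}
        print(f"{factor}: {len(direct)} direct targets (peak-assigned), "
              f"{len(indirect)} indirect")

    with open(args.outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)


if __name__ == "__main__":
    main()
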