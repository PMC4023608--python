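#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes gene models (BED12), ncRNA annotation (BED6+class), tag libraries
for SRF, MKL1, ELK4 and the SRF-knockout background (BED6 with a depth
header), the knockdown expression table (TSV) and the ground-truth JSON
under results/sim/.
"""

import argparse
from pathlib import Path

from srfpipe.simulate import (
    SimulationParams,
    simulate_expression,
    simulate_genome,
    simulate_tags,
)
from srfpipe.tags import write_tags


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    params = SimulationParams()
    genome = simulate_genome(params, args.seed)
    paths = genome.write(args.outdir)
    print(f"genome: {len(genome.genes)} genes, {len(genome.ncrnas)} ncRNAs "
          f"on {params.n_chroms} x {params.chrom_length/1e6:.0f} Mb chromosomes")
    for factor in list(params.n_sites) + ["SRF_KO"]:
        lib = simulate_tags(genome.truth, params, factor, args.seed)
        out = args.outdir / f"tags_{factor}.bed"
        write_tags(lib, out, params.read_len)
        n_sites = len(genome.truth.sites.get("SRF" if factor == "SRF_KO" else factor, []))
        print(f"{factor}: {lib.n_stored} tags in the modeled window "
              f"(library depth {lib.total_tags:.0e}), {n_sites} planted sites -> {out}")
    expr = simulate_expression(genome.truth, params, args.seed)
    expr.to_tsv(args.outdir / "expression.tsv")
    n_dep = {f: len(d["down"]) for f, d in genome.truth.dependent.items()}
    print(f"expression: {len(expr.genes)} genes x {len(expr.conditions)} conditions, "
          f"planted down-regulated genes per factor: {n_dep}")
    print(f"ground truth -> {paths['truth']}")


if __name__ == "__main__":
    main()
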