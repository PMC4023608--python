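#!/usr/bin/env python
"""Annotate called peaks: nearest gene, genomic location class, and ncRNA
association of intergenic SRF peaks.

Writes per-factor annotated peak tables (TSV), the location-class
distributions and the ncRNA association report under results/annotation/.
"""

import argparse
import json
from pathlib import Path

from srfpipe.annotation import build_index, read_gene_models, read_ncrnas
from srfpipe.annotate import annotate_peaks, associate_ncrnas
from srfpipe.config import PipelineConfig
from srfpipe.overlap import location_distribution
from srfpipe.peaks import read_peaks_bed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--peakdir", type=Path, default=Path("results/peaks"))
    ap.add_argument("--outdir", type=Path, default=Path("results/annotation"))
    args = ap.parse_args()
    c = PipelineConfig()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genes = read_gene_models(args.simdir / "genes.bed12", "bed12")
    ncrnas = read_ncrnas(args.simdir / "ncrnas.bed")
    index = build_index(genes, ncrnas, c.promoter_window)

    dists = {}
    for factor in ("SRF", "MKL1", "ELK4"):
        peaks = read_peaks_bed(args.peakdir / f"peaks_{factor}.bed", factor)
        table = annotate_peaks(peaks, index, c.promoter_window)
        table.to_csv(args.outdir / f"annotated_{factor}.tsv", sep="\t", index=False)
        counts, fractions = location_distribution(list(table["location"]))
        dists[factor] = {"counts": counts, "fractions": fractions}
        pretty = ", ".join(f"{k} {100 * v:.1f}%" for k, v in fractions.items())
        print(f"{factor}: {len(peaks)} peaks -> {pretty}")
        if factor == "SRF":
            intergenic = [p for p, loc in zip(peaks, table["location"])
                          if loc == "intergenic"]
            rep = associate_ncrnas(intergenic, index, c.ncrna_window)
            with open(args.outdir / "srf_ncrna_report.json", "w") as fh:
                json.dump(rep.to_dict(), fh, indent=1)
            print(f"  {rep.n_associated} of {rep.n_peaks} intergenic SRF peaks "
                  f"({100 * rep.associated_fraction:.2f}%) lie within "
                  f"{c.ncrna_window / 1000:.0f} kb of an ncRNA; "
                  f"{len(rep.unique_ncrnas)} unique ncRNAs "
                  f"({rep.class_counts})")
    with open(args.outdir / "location_distributions.json", "w") as fh:
        json.dump(dists, fh, indent=1)


if __name__ == "__main__":
    main()
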