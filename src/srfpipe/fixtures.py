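"""Deterministic fixtures realizing the study's printed summary counts.

The underlying genome-wide data were never deposited, so these fixtures are
synthetic: peak sets and gene lists constructed to have exactly the
published totals and overlaps, used to exercise the overlap, association
and intersection machinery at full published scale.

* Peak sets: 5025 SRF, 1140 MKL1 and 783 ELK4 peaks, with 781 SRF peaks
  overlapped by MKL1, 350 by ELK4 and 104 by both.
* Intergenic set: 1827 SRF intergenic peaks with ncRNAs planted within
  20 kb of 199 of them (199 is the integer whose fraction of 1827 rounds
  to the published 10.89%); 316 unique ncRNAs typed 267 lncRNA / 44 miRNA
  / 5 other (5 = 316 - 267 - 44).
* Gene lists: 264 SRF-, 309 MKL1/2- and 265 ELK4-dependent downregulated
  symbols with intersections of exactly 60 (SRF with MKL1/2) and 24 (SRF
  with ELK4); the two intersections are disjoint, and no MKL1/2-ELK4
  overlap is introduced outside SRF since no such count was published.

Every object is built arithmetically — no randomness — so the fixtures are
byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .annotation import NcRNARecord, write_ncrnas
from .expression import GeneSet, write_gene_set
from .peaks import Peak, write_peaks_bed

__all__ = ["PaperFixtures", "make_paper_fixtures"]

_SLOT = 10_000  # peak slot pitch on the Venn chromosome
_PEAK_LEN = 200


def _peak(factor: str, chrom: str, slot: int, pitch: int = _SLOT) -> Peak:
    start = slot * pitch
    return Peak(
        factor=factor,
        chrom=chrom,
        start=start,
        end=start + _PEAK_LEN,
        summit=start + _PEAK_LEN // 2,
        raw_count=100,
        norm_count=100.0,
    )


@dataclass
class PaperFixtures:
    peak_sets: dict = field(default_factory=dict)  # factor -> list[Peak]
    intergenic_peaks: list = field(default_factory=list)
    ncrnas: list = field(default_factory=list)
    gene_sets: dict = field(default_factory=dict)  # label -> GeneSet
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for factor, peaks in self.peak_sets.items():
            write_peaks_bed(peaks, outdir / f"peaks_{factor}.bed")
        write_peaks_bed(self.intergenic_peaks, outdir / "peaks_SRF_intergenic.bed")
        write_ncrnas(self.ncrnas, outdir / "ncrnas.bed")
        for label, gs in self.gene_sets.items():
            write_gene_set(gs, outdir / f"genes_{label}.txt")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


def make_paper_fixtures() -> PaperFixtures:
    fx = PaperFixtures()

    # --- three-factor peak sets on one chromosome --------------------------
    # SRF occupies slots 0..5024.  Slot layout for the others:
    #   0..103       shared by all three factors            (104 triple)
    #   104..780     SRF+MKL1                               (677)
    #   781..1026    SRF+ELK4                               (246)
    #   6000..6358   MKL1 only                              (359)
    #   7000..7432   ELK4 only                              (433)
    chrom = "chrV"
    srf = [_peak("SRF", chrom, i) for i in range(5025)]
    mkl1 = [_peak("MKL1", chrom, i) for i in range(781)]
    mkl1 += [_peak("MKL1", chrom, i) for i in range(6000, 6359)]
    elk4 = [_peak("ELK4", chrom, i) for i in range(104)]
    elk4 += [_peak("ELK4", chrom, i) for i in range(781, 1027)]
    elk4 += [_peak("ELK4", chrom, i) for i in range(7000, 7433)]
    fx.peak_sets = {"SRF": srf, "MKL1": mkl1, "ELK4": elk4}

    # --- intergenic peaks with nearby ncRNAs --------------------------------
    # 316 ncRNAs over 199 associated peaks: the first 117 peaks carry two
    # ncRNAs each, the next 82 carry one (117*2 + 82 = 316).
    nchrom = "chrI"
    pitch = 100_000
    fx.intergenic_peaks = [
        _peak("SRF", nchrom, i, pitch=pitch) for i in range(1827)
    ]
    ncrnas: list[NcRNARecord] = []
    nc_positions = []
    for i in range(199):
        end = i * pitch + _PEAK_LEN
        nc_positions.append((i, end + 5_000))
        if i < 117:
            nc_positions.append((i, end + 9_000))
    # class labels over the 316 unique ncRNAs: 267 lncRNA, 44 miRNA, 5 other
    for k, (_i, start) in enumerate(nc_positions):
        if k < 267:
            cls = "lncRNA"
        elif k < 267 + 44:
            cls = "miRNA"
        else:
            cls = "other"
        ncrnas.append(NcRNARecord(f"FNC{k + 1:04d}", cls, nchrom, start, start + 500))
    fx.ncrnas = ncrnas

    # --- dependent gene lists ----------------------------------------------
    shared_mkl = [f"SHMKL{i:03d}" for i in range(60)]
    shared_elk = [f"SHELK{i:03d}" for i in range(24)]
    srf_only = [f"SRFDN{i:03d}" for i in range(264 - 60 - 24)]
    mkl_only = [f"MKLDN{i:03d}" for i in range(309 - 60)]
    elk_only = [f"ELKDN{i:03d}" for i in range(265 - 24)]
    fx.gene_sets = {
        "SRF_down": GeneSet.from_symbols("SRF_down", shared_mkl + shared_elk + srf_only),
        "MKL12_down": GeneSet.from_symbols("MKL12_down", shared_mkl + mkl_only),
        "ELK4_down": GeneSet.from_symbols("ELK4_down", shared_elk + elk_only),
    }

    fx.manifest = {
        "peak_totals": {"SRF": 5025, "MKL1": 1140, "ELK4": 783},
        "srf_overlaps": {"MKL1": 781, "ELK4": 350, "both": 104},
        "intergenic_peaks": 1827,
        "associated_peaks": 199,
        "associated_peaks_note": (
            "199 derived by integer search: 199/1827 = 10.892%, the unique "
            "count whose 2-dp rounding matches the published 10.89%"
        ),
        "unique_ncrnas": {"total": 316, "lncRNA": 267, "miRNA": 44, "other": 5},
        "other_ncrnas_note": "5 = 316 - 267 - 44 (complement of published counts)",
        "gene_set_sizes": {"SRF_down": 264, "MKL12_down": 309, "ELK4_down": 265},
        "gene_set_intersections": {"SRF&MKL12": 60, "SRF&ELK4": 24},
        "gene_set_note": (
            "MKL12-ELK4 overlap outside SRF set to 0; no such count was published"
        ),
        "synthetic": True,
    }
    return fx
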