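"""Peak annotation: nearest-gene assignment, genomic location classes,
ncRNA association and CArG-box scanning.

A peak is classified by its summit into exactly one of four classes —
promoter (within +/-1000 bp of any transcription start site, inclusive),
exon, intron, intergenic — with precedence promoter > exon > intron, so
the classes partition any peak set.  Intergenic peaks are associated with
annotated ncRNAs lying within 20 kb (interval-to-interval gap, inclusive).
The CArG box is the SRF consensus CC(A/T)6GG; the consensus class equals
its own reverse complement, so one strand is scanned and each site counted
once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotation import GenomeIndex, NCRNA_CLASSES
from .peaks import Peak

__all__ = [
    "GeneAssignment",
    "NcRNAAssociationReport",
    "LOCATION_CLASSES",
    "assign_nearest_gene",
    "classify_location",
    "associate_ncrnas",
    "scan_carg",
    "annotate_peaks",
]

LOCATION_CLASSES = ("promoter", "exon", "intron", "intergenic")

_W = frozenset("AT")


@dataclass(frozen=True)
class GeneAssignment:
    """Nearest-TSS assignment of one peak.

    ``distance`` is signed in the assigned gene's orientation (negative =
    upstream of the TSS); ``gene_id`` is None when the peak's chromosome
    carries no annotation.
    """

    peak: Peak
    gene_id: str | None
    distance: int | None


@dataclass
class NcRNAAssociationReport:
    """Association of intergenic peaks with nearby ncRNAs."""

    n_peaks: int
    per_peak: list[list[str]]
    n_associated: int
    associated_fraction: float
    unique_ncrnas: list[str]
    class_counts: dict[str, int]
    class_fractions: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_peaks": self.n_peaks,
            "n_associated": self.n_associated,
            "associated_fraction": self.associated_fraction,
            "n_unique_ncrnas": len(self.unique_ncrnas),
            "class_counts": self.class_counts,
            "class_fractions": self.class_fractions,
        }


def assign_nearest_gene(peak: Peak, index: GenomeIndex) -> GeneAssignment:
    """Assign a peak to the gene with the TSS nearest its summit.

    Ties in |summit - TSS| are broken by the smaller TSS coordinate, then
    the lexicographically smaller gene symbol.
    """
    hit = index.nearest_tss(peak.chrom, peak.summit)
    if hit is None:
        return GeneAssignment(peak, None, None)
    gene_id, dist, _strand = hit
    return GeneAssignment(peak, gene_id, dist)


def classify_location(
    peak: Peak, index: GenomeIndex, promoter_window: int = 1000
) -> str:
    """Classify the peak summit: promoter > exon > intron > intergenic."""
    d = index.min_tss_distance(peak.chrom, peak.summit)
    if d is not None and d <= promoter_window:
        return "promoter"
    if index.exons_at(peak.chrom, peak.summit):
        return "exon"
    if index.gene_bodies_at(peak.chrom, peak.summit):
        return "intron"
    return "intergenic"


def associate_ncrnas(
    peaks: Sequence[Peak], index: GenomeIndex, window: int = 20_000
) -> NcRNAAssociationReport:
    """Associate (intergenic) peaks with ncRNAs within ``window`` bp.

    Distance is measured interval-to-interval (gap; 0 when overlapping) and
    the window bound is inclusive.  The report carries the per-peak
    association lists, the fraction of peaks with at least one associated
    ncRNA, the deduplicated ncRNA list, and the class breakdown of the
    unique ncRNAs.
    """
    per_peak: list[list[str]] = []
    unique: dict[str, str] = {}  # id -> class
    n_assoc = 0
    for p in peaks:
        hits = index.ncrnas_near(p.chrom, p.start, p.end, window)
        per_peak.append([r.ncrna_id for r in hits])
        if hits:
            n_assoc += 1
        for r in hits:
            unique[r.ncrna_id] = r.ncrna_class
    n_peaks = len(peaks)
    counts = {c: 0 for c in NCRNA_CLASSES}
    for cls in unique.values():
        counts[cls] += 1
    total_unique = len(unique)
    fractions = {
        c: (counts[c] / total_unique if total_unique else 0.0) for c in NCRNA_CLASSES
    }
    return NcRNAAssociationReport(
        n_peaks=n_peaks,
        per_peak=per_peak,
        n_associated=n_assoc,
        associated_fraction=(n_assoc / n_peaks if n_peaks else 0.0),
        unique_ncrnas=sorted(unique),
        class_counts=counts,
        class_fractions=fractions,
    )


def scan_carg(seq: str) -> list[int]:
    """All 0-based offsets where the 10-mer CArG consensus CCWWWWWWGG matches.

    W = A or T.  The consensus class is its own reverse complement, so a
    single-strand scan finds every site exactly once.  Characters outside
    the match alphabet (including N) never match.
    """
    s = seq.upper()
    out: list[int] = []
    for i in range(len(s) - 9):
        if (
            s[i] == "C"
            and s[i + 1] == "C"
            and s[i + 8] == "G"
            and s[i + 9] == "G"
            and all(s[i + j] in _W for j in range(2, 8))
        ):
            out.append(i)
    return out


def annotate_peaks(
    peaks: Sequence[Peak],
    index: GenomeIndex,
    promoter_window: int = 1000,
) -> pd.DataFrame:
    """Per-peak annotation table: BED fields + nearest gene, signed TSS
    distance and genomic location class."""
    rows = []
    for p in peaks:
        ga = assign_nearest_gene(p, index)
        rows.append(
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "summit": p.summit,
                "factor": p.factor,
                "norm_count": p.norm_count,
                "gene": ga.gene_id if ga.gene_id is not None else ".",
                "tss_distance": ga.distance,
                "location": classify_location(p, index, promoter_window),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "summit",
            "factor",
            "norm_count",
            "gene",
            "tss_distance",
            "location",
        ],
    )
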