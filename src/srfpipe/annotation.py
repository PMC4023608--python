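"""Gene and ncRNA annotation: parsing, TSS lookup and interval indexing.

All internal coordinates are 0-based half-open; dialect conversion (GFF3 is
1-based closed) happens only at the I/O boundary.  The transcription start
site of a minus-strand transcript is ``tx_end - 1``, the 5'-most transcribed
base in internal coordinates.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "NcRNARecord",
    "GenomeIndex",
    "tss_of",
    "read_gene_models",
    "write_bed12",
    "read_ncrnas",
    "write_ncrnas",
    "build_index",
]

NCRNA_CLASSES = ("lncRNA", "miRNA", "other")


class AnnotationParseError(ValueError):
    """Raised for malformed annotation lines; message names the line number."""


@dataclass(frozen=True)
class GeneModel:
    """One transcript: symbol, strand, body and exon structure.

    ``exons`` are sorted, non-overlapping half-open intervals contained in
    ``[tx_start, tx_end)``; introns are the gaps between them.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError("tx_start must be < tx_end")
        if not self.exons:
            raise ValueError("at least one exon is required")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"exon ({s},{e}) outside transcript body")
            if prev_end is not None and s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        gaps = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                gaps.append((e1, s2))
        return tuple(gaps)

    @property
    def tss(self) -> int:
        return tss_of(self)


@dataclass(frozen=True)
class NcRNARecord:
    ncrna_id: str
    ncrna_class: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.ncrna_class not in NCRNA_CLASSES:
            raise ValueError(
                f"ncrna_class must be one of {NCRNA_CLASSES}, got {self.ncrna_class!r}"
            )
        if not self.start < self.end:
            raise ValueError("start must be < end")


def tss_of(model: GeneModel) -> int:
    """Transcription start site: the 5'-most transcribed base."""
    return model.tx_start if model.strand == "+" else model.tx_end - 1


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_bed12(lines: Iterable[str]) -> list[GeneModel]:
    models = []
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) < 12:
            raise AnnotationParseError(f"line {i}: BED12 needs 12 fields, got {len(f)}")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise AnnotationParseError(f"line {i}: {exc}") from exc
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise AnnotationParseError(f"line {i}: block count mismatch")
        exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
        try:
            models.append(GeneModel(name, chrom, strand, start, end, exons))
        except ValueError as exc:
            raise AnnotationParseError(f"line {i}: {exc}") from exc
    return models


def _parse_refflat(lines: Iterable[str]) -> list[GeneModel]:
    models = []
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) < 11:
            raise AnnotationParseError(f"line {i}: refFlat needs 11 fields, got {len(f)}")
        try:
            gene, chrom, strand = f[0], f[2], f[3]
            tx_start, tx_end = int(f[4]), int(f[5])
            n_ex = int(f[8])
            ex_starts = [int(x) for x in f[9].rstrip(",").split(",")]
            ex_ends = [int(x) for x in f[10].rstrip(",").split(",")]
        except ValueError as exc:
            raise AnnotationParseError(f"line {i}: {exc}") from exc
        if len(ex_starts) != n_ex or len(ex_ends) != n_ex:
            raise AnnotationParseError(f"line {i}: exon count mismatch")
        try:
            models.append(
                GeneModel(gene, chrom, strand, tx_start, tx_end,
                          tuple(zip(ex_starts, ex_ends)))
            )
        except ValueError as exc:
            raise AnnotationParseError(f"line {i}: {exc}") from exc
    return models


def _parse_gff3(lines: Iterable[str]) -> list[GeneModel]:
    # Group exon features by Parent (falling back to transcript_id / ID);
    # transcript bounds are the min/max over its exons.
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise AnnotationParseError(f"line {i}: GFF3 needs 9 fields, got {len(f)}")
        chrom, _src, ftype, start, end, _score, strand, _frame, attrs = f
        if ftype.lower() != "exon":
            continue
        try:
            s, e = int(start) - 1, int(end)  # 1-based closed -> half-open
        except ValueError as exc:
            raise AnnotationParseError(f"line {i}: {exc}") from exc
        attr = {}
        for kv in attrs.rstrip(";").split(";"):
            if "=" in kv:
                k, v = kv.split("=", 1)
                attr[k.strip()] = v.strip()
        parent = attr.get("Parent") or attr.get("transcript_id") or attr.get("ID")
        if parent is None:
            raise AnnotationParseError(f"line {i}: exon without Parent attribute")
        exons.setdefault(parent, []).append((s, e))
        prev = meta.setdefault(parent, (chrom, strand))
        if prev != (chrom, strand):
            raise AnnotationParseError(f"line {i}: inconsistent chrom/strand for {parent}")
    models = []
    for parent in sorted(exons):
        ex = sorted(exons[parent])
        chrom, strand = meta[parent]
        models.append(GeneModel(parent, chrom, strand, ex[0][0], ex[-1][1], tuple(ex)))
    return models


_PARSERS = {"bed12": _parse_bed12, "gff3": _parse_gff3, "refflat": _parse_refflat}


def read_gene_models(path: str | Path, fmt: str = "bed12") -> list[GeneModel]:
    """Read transcript models from BED12, GFF3 or refFlat."""
    if fmt not in _PARSERS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {sorted(_PARSERS)}")
    with open(path) as fh:
        return _PARSERS[fmt](fh)


def write_bed12(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - m.tx_start) for s, _ in m.exons)
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(m.tx_start),
                        str(m.tx_end),
                        m.gene_id,
                        "0",
                        m.strand,
                        str(m.tx_start),
                        str(m.tx_end),
                        "0",
                        str(len(m.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_ncrnas(path: str | Path) -> list[NcRNARecord]:
    """BED6+1: chrom start end id score strand class."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 7:
                raise AnnotationParseError(f"line {i}: ncRNA BED needs 7 fields")
            try:
                records.append(NcRNARecord(f[3], f[6], f[0], int(f[1]), int(f[2])))
            except ValueError as exc:
                raise AnnotationParseError(f"line {i}: {exc}") from exc
    return records


def write_ncrnas(records: Sequence[NcRNARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.ncrna_id}\t0\t.\t{r.ncrna_class}\n"
            )


def write_bed6(intervals: Sequence[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (chrom, start, end, name) tuples as BED6 with '.' strand."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t.\n")


# ---------------------------------------------------------------------------
# index
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Per-chromosome interval structures over gene bodies, exons and ncRNAs,
    plus sorted TSS lists for nearest-TSS lookup.

    Query results are defined to be identical to a linear scan over the
    source records; the trees are purely an acceleration structure.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        ncrnas: Sequence[NcRNARecord] = (),
        promoter_window: int = 1000,
    ) -> None:
        self.genes = list(genes)
        self.ncrnas = list(ncrnas)
        self.promoter_window = int(promoter_window)
        self._body: dict[str, IntervalTree] = {}
        self._exon: dict[str, IntervalTree] = {}
        self._nc: dict[str, IntervalTree] = {}
        # per chrom: list of (tss, gene_id, strand), sorted
        self._tss: dict[str, list[tuple[int, str, str]]] = {}
        for m in self.genes:
            self._body.setdefault(m.chrom, IntervalTree()).addi(
                m.tx_start, m.tx_end, m.gene_id
            )
            for s, e in m.exons:
                self._exon.setdefault(m.chrom, IntervalTree()).addi(s, e, m.gene_id)
            self._tss.setdefault(m.chrom, []).append((tss_of(m), m.gene_id, m.strand))
        for entries in self._tss.values():
            entries.sort()
        for r in self.ncrnas:
            self._nc.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)

    # -- point queries ------------------------------------------------------

    def exons_at(self, chrom: str, pos: int) -> list[str]:
        tree = self._exon.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))

    def gene_bodies_at(self, chrom: str, pos: int) -> list[str]:
        tree = self._body.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))

    def nearest_tss(self, chrom: str, pos: int) -> tuple[str, int, str] | None:
        """(gene_id, signed distance, strand) of the nearest TSS, or None.

        The distance is signed in the gene's orientation: negative means the
        query lies upstream of the TSS.  Ties in |distance| go to the
        smaller TSS coordinate, then the lexicographically smaller gene_id.
        """
        entries = self._tss.get(chrom)
        if not entries:
            return None
        positions = [t for t, _, _ in entries]
        i = bisect.bisect_left(positions, pos)
        # candidate TSS coordinates: nearest on each side
        cand_pos = []
        if i > 0:
            cand_pos.append(positions[i - 1])
        if i < len(positions):
            cand_pos.append(positions[i])
        best_pos = min(cand_pos, key=lambda t: (abs(pos - t), t))
        # lexicographically smallest gene at that coordinate
        j = bisect.bisect_left(positions, best_pos)
        best = entries[j]  # entries sorted by (pos, gene_id, strand)
        tss, gene_id, strand = best
        dist = pos - tss if strand == "+" else tss - pos
        return gene_id, dist, strand

    def min_tss_distance(self, chrom: str, pos: int) -> int | None:
        """Unsigned distance to the nearest TSS, or None if no annotation."""
        entries = self._tss.get(chrom)
        if not entries:
            return None
        positions = [t for t, _, _ in entries]
        i = bisect.bisect_left(positions, pos)
        best = None
        if i > 0:
            best = abs(pos - positions[i - 1])
        if i < len(positions):
            d = abs(pos - positions[i])
            best = d if best is None else min(best, d)
        return best

    # -- interval queries ---------------------------------------------------

    def ncrnas_near(self, chrom: str, start: int, end: int, window: int) -> list[NcRNARecord]:
        """ncRNAs whose interval gap to [start, end) is <= window (0 if overlapping)."""
        tree = self._nc.get(chrom)
        if tree is None:
            return []
        # widen by 1 on each side: tree overlap is exclusive at interval ends,
        # but a gap of exactly `window` still counts as associated
        hits = tree.overlap(start - window - 1, end + window + 1)
        out = []
        for iv in hits:
            r: NcRNARecord = iv.data
            gap = max(r.start - end, start - r.end, 0)
            if gap <= window:
                out.append(r)
        return sorted(out, key=lambda r: (r.start, r.end, r.ncrna_id))


def build_index(
    genes: Sequence[GeneModel],
    ncrnas: Sequence[NcRNARecord] = (),
    promoter_window: int = 1000,
) -> GenomeIndex:
    return GenomeIndex(genes, ncrnas, promoter_window)
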