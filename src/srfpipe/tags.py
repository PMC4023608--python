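"""Mapped ChIP tags: BED input, depth normalization and window counting.

A *tag* is the mapped 5' end of a sequenced ChIP read.  Tag counts are made
comparable across libraries by rescaling to a common depth of 10^7
specifically mapped tags.  For counting, each tag is shifted half a fragment
length toward its 3' side — to the midpoint of the sequenced chromatin
fragment — and assigned to the fixed, non-overlapping 200 bp window
containing that midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "TagLibrary",
    "WindowTrack",
    "read_tags",
    "write_tags",
    "norm_factor",
    "window_counts",
    "write_bedgraph",
]


@dataclass
class TagLibrary:
    """Strand-aware 5' tag positions per chromosome for one ChIP library.

    ``total_tags`` is the number of specifically mapped tags in the whole
    library.  When the library was read from a genome-wide BED file this
    equals the number of stored tags; a library representing a genomic
    window extracted from a deeper sequencing run may carry a larger
    ``total_tags``, which is the quantity depth normalization must use.
    """

    label: str
    chroms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    total_tags: int = 0

    @property
    def n_stored(self) -> int:
        return sum(len(pos) for pos, _ in self.chroms.values())

    def add(self, chrom: str, positions: np.ndarray, is_reverse: np.ndarray) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        is_reverse = np.asarray(is_reverse, dtype=bool)
        if positions.shape != is_reverse.shape:
            raise ValueError("positions and strands must have equal length")
        if len(positions) and positions.min() < 0:
            raise ValueError("tag positions must be non-negative")
        if chrom in self.chroms:
            old_pos, old_rev = self.chroms[chrom]
            positions = np.concatenate([old_pos, positions])
            is_reverse = np.concatenate([old_rev, is_reverse])
        self.chroms[chrom] = (positions, is_reverse)

    def validate(self) -> None:
        if self.total_tags < self.n_stored:
            raise ValueError("total_tags cannot be smaller than stored tag count")


@dataclass
class WindowTrack:
    """Raw tag counts in fixed non-overlapping windows, per chromosome."""

    window_size: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def read_tags(path: str | Path, label: str = "") -> TagLibrary:
    """Read mapped tags from BED6 (strand required).

    The 5' position of a forward tag is the BED start; of a reverse tag the
    BED end minus one (the last covered base, half-open convention).
    """
    per_chrom: dict[str, tuple[list[int], list[bool]]] = {}
    n = 0
    declared_total: int | None = None
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("# total_tags="):
                declared_total = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 6:
                raise ValueError(f"line {i}: BED6 with strand required, got {len(f)} fields")
            chrom, start, end, strand = f[0], int(f[1]), int(f[2]), f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"line {i}: strand must be '+' or '-', got {strand!r}")
            rev = strand == "-"
            pos = end - 1 if rev else start
            bucket = per_chrom.setdefault(chrom, ([], []))
            bucket[0].append(pos)
            bucket[1].append(rev)
            n += 1
    total = max(declared_total, n) if declared_total is not None else n
    lib = TagLibrary(label=label or Path(path).stem, total_tags=total)
    for chrom, (positions, revs) in per_chrom.items():
        lib.add(chrom, np.array(positions, dtype=np.int64), np.array(revs, dtype=bool))
    return lib


def write_tags(lib: TagLibrary, path: str | Path, read_len: int = 25) -> None:
    """Write a tag library as BED6, reconstructing read intervals.

    The library-wide mapped-tag total is recorded in a header comment so a
    regional extract of a deeper library keeps its normalization depth when
    read back.
    """
    with open(path, "w") as fh:
        fh.write(f"# total_tags={lib.total_tags}\n")
        for chrom in sorted(lib.chroms):
            pos, rev = lib.chroms[chrom]
            order = np.argsort(pos, kind="stable")
            for k, i in enumerate(order):
                p = int(pos[i])
                if rev[i]:
                    fh.write(f"{chrom}\t{max(p - read_len + 1, 0)}\t{p + 1}\t{lib.label}_{k}\t0\t-\n")
                else:
                    fh.write(f"{chrom}\t{p}\t{p + read_len}\t{lib.label}_{k}\t0\t+\n")


def norm_factor(total_tags: int, target: float = 1e7) -> float:
    """Scale factor that rescales a library to `target` mapped tags."""
    if total_tags <= 0:
        raise ValueError("cannot normalize an empty library (total_tags must be > 0)")
    return target / total_tags


def window_counts(
    lib: TagLibrary,
    window_size: int = 200,
    fragment_len: int = 200,
    chrom_sizes: Mapping[str, int] | None = None,
) -> WindowTrack:
    """Count fragment midpoints in fixed windows.

    Each tag is shifted ``fragment_len // 2`` toward its 3' side (strand
    aware) to its fragment midpoint, clipped at zero, and assigned to the
    window containing the midpoint.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if fragment_len <= 0:
        raise ValueError("fragment_len must be positive")
    shift = fragment_len // 2
    track = WindowTrack(window_size=window_size)
    for chrom, (pos, rev) in lib.chroms.items():
        mid = np.where(rev, pos - shift, pos + shift)
        np.clip(mid, 0, None, out=mid)
        idx = mid // window_size
        if chrom_sizes is not None and chrom in chrom_sizes:
            n_win = int(np.ceil(chrom_sizes[chrom] / window_size))
            n_win = max(n_win, int(idx.max()) + 1 if len(idx) else 0)
        else:
            n_win = int(idx.max()) + 1 if len(idx) else 0
        track.counts[chrom] = np.bincount(idx, minlength=n_win).astype(np.int64)
    return track


def write_bedgraph(
    track: WindowTrack,
    path: str | Path,
    scale: float = 1.0,
    name: str = "track",
) -> None:
    """Write non-zero windows as bedGraph with a UCSC track line."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom in sorted(track.counts):
            counts = track.counts[chrom]
            (nz,) = np.nonzero(counts)
            for i in nz:
                s = int(i) * track.window_size
                fh.write(f"{chrom}\t{s}\t{s + track.window_size}\t{counts[i] * scale:g}\n")
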