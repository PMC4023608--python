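"""Threshold peak calling with knockout-background filtering and empirical FDR.

A window is peak-positive when its depth-normalized tag count strictly
exceeds the threshold (default 20 normalized tags); runs of adjacent
positive windows merge into one peak whose score is the maximum merged
window count.  Peaks are then kept only where the signal is at least
``bg_ratio``-fold (default 4, inclusive) the normalized count of a
background library — a ChIP performed in knockout cells — over the same
interval.  The empirical false discovery rate of the threshold is estimated
by repositioning tags uniformly at random and re-calling peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .tags import TagLibrary, WindowTrack, norm_factor, window_counts

__all__ = [
    "Peak",
    "call_peaks",
    "background_filter",
    "estimate_fdr",
    "write_peaks_bed",
    "read_peaks_bed",
]


@dataclass(frozen=True)
class Peak:
    """A called binding interval.

    ``norm_count`` is the maximum depth-normalized window count over the
    merged windows; ``summit`` is the center of the maximal window.
    """

    factor: str
    chrom: str
    start: int
    end: int
    summit: int
    raw_count: int
    norm_count: float
    bg_norm_count: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("start must be < end")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie in [start, end)")

    @property
    def ratio(self) -> float | None:
        """Signal/background ratio; infinite over a zero background."""
        if self.bg_norm_count is None:
            return None
        if self.bg_norm_count == 0:
            return float("inf")
        return self.norm_count / self.bg_norm_count


def call_peaks(
    track: WindowTrack,
    factor_norm: float,
    threshold: float = 20.0,
    factor: str = "",
) -> list[Peak]:
    """Call peaks: merge adjacent windows whose normalized count > threshold.

    The inequality is strict ("more than 20").  The peak summit is the
    center of the maximal raw-count window (first such window on ties), and
    the peak score is the maximum, not the sum, over merged windows.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ws = track.window_size
    peaks: list[Peak] = []
    for chrom in sorted(track.counts):
        raw = track.counts[chrom]
        positive = raw * factor_norm > threshold
        if not positive.any():
            continue
        # run boundaries of consecutive positive windows
        padded = np.concatenate([[False], positive, [False]])
        d = np.diff(padded.astype(np.int8))
        run_starts = np.nonzero(d == 1)[0]
        run_ends = np.nonzero(d == -1)[0]
        for a, b in zip(run_starts, run_ends):
            seg = raw[a:b]
            k = int(np.argmax(seg))
            peaks.append(
                Peak(
                    factor=factor,
                    chrom=chrom,
                    start=int(a) * ws,
                    end=int(b) * ws,
                    summit=(int(a) + k) * ws + ws // 2,
                    raw_count=int(seg[k]),
                    norm_count=float(seg[k] * factor_norm),
                )
            )
    return peaks


def background_filter(
    peaks: Sequence[Peak],
    bg: WindowTrack,
    bg_norm: float,
    min_ratio: float = 4.0,
    pseudocount: float = 1.0,
) -> list[Peak]:
    """Keep peaks at least ``min_ratio``-fold (inclusive) above background.

    The background score of a peak is the maximum normalized background
    window count within the peak interval; zero-background intervals are
    floored at ``pseudocount`` normalized tags so the ratio is always
    defined.
    """
    kept: list[Peak] = []
    for p in peaks:
        if p.start % bg.window_size or p.end % bg.window_size:
            raise ValueError(
                f"peak {p.chrom}:{p.start}-{p.end} is not aligned to the "
                f"background window scheme (window_size={bg.window_size})"
            )
        a = p.start // bg.window_size
        b = p.end // bg.window_size
        counts = bg.counts.get(p.chrom)
        if counts is None:
            bg_raw = 0
        else:
            seg = counts[a : min(b, len(counts))]
            bg_raw = int(seg.max()) if len(seg) else 0
        bg_val = bg_raw * bg_norm
        q = replace(p, bg_norm_count=bg_val)
        if p.norm_count / max(bg_val, pseudocount) >= min_ratio:
            kept.append(q)
    return kept


def estimate_fdr(
    lib: TagLibrary,
    chrom_sizes: Mapping[str, int],
    threshold: float = 20.0,
    n_shuffles: int = 10,
    seed: int = 0,
    window_size: int = 200,
    fragment_len: int = 200,
    norm_target: float = 1e7,
) -> float:
    """Empirical FDR of threshold peak calling by uniform tag randomization.

    Tags are repositioned uniformly at random per chromosome (seeded,
    strands preserved) and peaks are re-called at the same threshold; the
    estimate is the mean shuffled peak count divided by the observed peak
    count.  Returns NaN when the observed library yields no peaks ("no
    peaks" sentinel).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    f = norm_factor(lib.total_tags, norm_target)
    observed = len(
        call_peaks(window_counts(lib, window_size, fragment_len, chrom_sizes), f, threshold)
    )
    if observed == 0:
        return float("nan")
    rng = np.random.default_rng(seed)
    shuffled_counts = []
    for _ in range(n_shuffles):
        null = TagLibrary(label=f"{lib.label}_shuffled", total_tags=lib.total_tags)
        for chrom, (pos, rev) in lib.chroms.items():
            size = chrom_sizes[chrom]
            null.add(chrom, rng.integers(0, size, size=len(pos)), rev.copy())
        track = window_counts(null, window_size, fragment_len, chrom_sizes)
        shuffled_counts.append(len(call_peaks(track, f, threshold)))
    return float(np.mean(shuffled_counts) / observed)


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """BED6+3: name, normalized count as score column, then raw count,
    background normalized count, signal/background ratio."""
    with open(path, "w") as fh:
        for i, p in enumerate(
            sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
        ):
            bg = "" if p.bg_norm_count is None else f"{p.bg_norm_count:.4f}"
            ratio = "" if p.ratio is None else f"{p.ratio:.4f}"
            name = f"{p.factor or 'peak'}_{i + 1}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.norm_count:.4f}\t.\t"
                f"{p.raw_count}\t{bg}\t{ratio}\t{p.summit}\n"
            )


def read_peaks_bed(path: str | Path, factor: str = "") -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            norm = float(f[4]) if len(f) > 4 and f[4] else 0.0
            raw = int(f[6]) if len(f) > 6 and f[6] else 0
            bg = float(f[7]) if len(f) > 7 and f[7] else None
            summit = int(f[9]) if len(f) > 9 and f[9] else (start + end) // 2
            peaks.append(
                Peak(
                    factor=factor,
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=summit,
                    raw_count=raw,
                    norm_count=norm,
                    bg_norm_count=bg,
                )
            )
    return peaks
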