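"""Factor co-occupancy: peak-set overlaps, Venn regions and location
distributions.

Overlap is defined as >= ``min_bp`` bases of interval intersection
(default 1 bp), counted on a declared reference set: "reference peaks
overlapped by the query".  Peaks within one set are merged before
cross-set comparison so adjacent merged windows are not double counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .peaks import Peak

__all__ = [
    "merge_peaks",
    "overlap_peaks",
    "VennReport",
    "venn_counts",
    "location_distribution",
]


def merge_peaks(peaks: Sequence[Peak]) -> list[Peak]:
    """Merge overlapping (>=1 bp) peaks within one set; adjacency (shared
    boundary under half-open coordinates) does not merge."""
    out: list[Peak] = []
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        current = group[0]
        for p in group[1:]:
            if p.start < current.end:  # strict: touching intervals stay apart
                best = current if current.norm_count >= p.norm_count else p
                current = Peak(
                    factor=current.factor,
                    chrom=chrom,
                    start=current.start,
                    end=max(current.end, p.end),
                    summit=best.summit,
                    raw_count=max(current.raw_count, p.raw_count),
                    norm_count=max(current.norm_count, p.norm_count),
                )
            else:
                out.append(current)
                current = p
        out.append(current)
    return out


def overlap_peaks(
    reference: Sequence[Peak], query: Sequence[Peak], min_bp: int = 1
) -> np.ndarray:
    """Boolean flag per reference peak: does >= min_bp of it intersect any
    query peak?  Output order follows the reference order."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    tmp: dict[str, list[tuple[int, int]]] = {}
    for p in merge_peaks(list(query)) if query else []:
        tmp.setdefault(p.chrom, []).append((p.start, p.end))
    q_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in tmp.items():
        ivs.sort()
        q_by_chrom[chrom] = (
            np.array([s for s, _ in ivs], dtype=np.int64),
            np.array([e for _, e in ivs], dtype=np.int64),
        )
    flags = np.zeros(len(reference), dtype=bool)
    for i, p in enumerate(reference):
        if p.chrom not in q_by_chrom:
            continue
        starts, ends = q_by_chrom[p.chrom]
        # merged query intervals are disjoint and sorted, so candidates are a
        # contiguous run ending just before the first start >= reference end
        j = int(np.searchsorted(starts, p.end, side="left"))
        best = 0
        for k in range(j - 1, -1, -1):
            if ends[k] <= p.start:
                break  # earlier disjoint intervals end even sooner
            ov = min(p.end, int(ends[k])) - max(p.start, int(starts[k]))
            best = max(best, ov)
        if best >= min_bp:
            flags[i] = True
    return flags


@dataclass
class VennReport:
    """Peak-set overlap report counted on a declared reference set.

    ``region_counts`` maps a sorted tuple of other-set labels to the number
    of reference peaks overlapped by exactly that combination (the empty
    tuple is "reference only"); ``with_counts`` gives, per other set, the
    reference peaks it overlaps regardless of the rest.
    """

    reference: str
    totals: dict[str, int]
    with_counts: dict[str, int]
    region_counts: dict[tuple[str, ...], int]
    fractions: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "totals": self.totals,
            "with_counts": self.with_counts,
            "region_counts": {"+".join(k) if k else "none": v for k, v in self.region_counts.items()},
            "fractions": self.fractions,
        }


def venn_counts(
    sets: Mapping[str, Sequence[Peak]], reference_label: str, min_bp: int = 1
) -> VennReport:
    """Venn regions for 2 or 3 labeled peak sets, counted on the reference.

    Each set is merged internally first; fractions are with_counts divided
    by the reference total.
    """
    if reference_label not in sets:
        raise ValueError(f"reference label {reference_label!r} not among sets")
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts supports 2 or 3 labeled sets")
    merged = {label: merge_peaks(list(ps)) if ps else [] for label, ps in sets.items()}
    ref = merged[reference_label]
    others = sorted(label for label in sets if label != reference_label)
    flags = {
        label: overlap_peaks(ref, merged[label], min_bp=min_bp) for label in others
    }
    n_ref = len(ref)
    with_counts = {label: int(flags[label].sum()) for label in others}
    region_counts: dict[tuple[str, ...], int] = {}
    for r in range(len(others) + 1):
        for combo in combinations(others, r):
            mask = np.ones(n_ref, dtype=bool)
            for label in others:
                mask &= flags[label] if label in combo else ~flags[label]
            region_counts[combo] = int(mask.sum())
    fractions = {
        label: (with_counts[label] / n_ref if n_ref else 0.0) for label in others
    }
    return VennReport(
        reference=reference_label,
        totals={label: len(ps) for label, ps in merged.items()},
        with_counts=with_counts,
        region_counts=region_counts,
        fractions=fractions,
    )


def plot_venn(report: VennReport, path) -> None:
    """Schematic 2/3-circle Venn figure for a VennReport (counts from the
    report; circle placement is fixed, not area-proportional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    others = sorted(report.with_counts)
    fig, ax = plt.subplots(figsize=(5, 5))
    centers = {report.reference: (0.0, 0.0)}
    if len(others) == 1:
        centers[others[0]] = (0.9, 0.0)
    else:
        centers[others[0]] = (0.9, 0.0)
        centers[others[1]] = (0.45, 0.8)
    for label, (x, y) in centers.items():
        ax.add_patch(plt.Circle((x, y), 0.75, fill=False, lw=1.5))
        ax.annotate(f"{label} ({report.totals[label]})", (x, y - 0.85),
                    ha="center", fontsize=9)
    lines = [f"{report.reference} with {o}: {report.with_counts[o]}" for o in others]
    for combo, count in report.region_counts.items():
        if len(combo) == len(others) and others:
            lines.append(f"{report.reference} with all: {count}")
    ax.annotate("\n".join(lines), (0.45, 1.9), ha="center", fontsize=9)
    ax.set_xlim(-1.2, 2.1)
    ax.set_ylim(-1.8, 2.3)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def location_distribution(
    classes: Sequence[str],
) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and fractions over {promoter, exon, intron, intergenic}."""
    from .annotate import LOCATION_CLASSES

    counts = {c: 0 for c in LOCATION_CLASSES}
    for c in classes:
        if c not in counts:
            raise ValueError(f"unknown location class {c!r}")
        counts[c] += 1
    n = len(classes)
    fractions = {c: (counts[c] / n if n else 0.0) for c in LOCATION_CLASSES}
    return counts, fractions
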