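"""Knockdown expression analysis: fold changes, 1.5-fold dependency sets,
set intersections and direct/indirect target labeling.

A gene is factor-dependent ("down") when its mean expression in the
non-specific siRNA control exceeds its mean under factor knockdown by
strictly more than the cutoff (default 1.5-fold); "up" uses the reciprocal
ratio.  Fold changes are ratios of linear-scale replicate means.  Gene
identity is the upper-cased symbol string, so intersections are
deterministic and case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression_stats import fold_change_ttest  # noqa: F401  (re-export)

__all__ = [
    "ExpressionTable",
    "GeneSet",
    "fold_change",
    "dependent_genes",
    "intersect_sets",
    "classify_direct_targets",
    "read_gene_set",
    "write_gene_set",
]


@dataclass(frozen=True)
class GeneSet:
    """A labeled set of unique, upper-cased gene symbols."""

    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        for g in self.genes:
            if not g or g != g.upper():
                raise ValueError(f"gene symbols must be non-empty and upper-cased: {g!r}")

    @classmethod
    def from_symbols(cls, label: str, symbols: Iterable[str]) -> "GeneSet":
        return cls(label, frozenset(s.strip().upper() for s in symbols if s.strip()))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.genes


class ExpressionTable:
    """Long-format expression values: gene x condition x replicate.

    All values must be strictly positive so linear-scale fold-change ratios
    are always defined.
    """

    REQUIRED = ("gene", "condition", "replicate", "value")

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"expression table missing columns: {missing}")
        if (df["value"] <= 0).any():
            raise ValueError("expression values must be strictly positive")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.df["condition"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    def condition_means(self, condition: str) -> pd.Series:
        """Per-gene mean over replicates of one condition."""
        sub = self.df[self.df["condition"] == condition]
        if sub.empty:
            raise KeyError(f"condition {condition!r} not present")
        return sub.groupby("gene")["value"].mean()

    def values(self, gene: str, condition: str) -> np.ndarray:
        sub = self.df[(self.df["gene"] == gene) & (self.df["condition"] == condition)]
        if sub.empty:
            raise KeyError(f"no values for gene {gene!r} in condition {condition!r}")
        return sub["value"].to_numpy()


def fold_change(
    table: ExpressionTable, gene: str, cond_a: str, cond_b: str
) -> float:
    """mean(cond_a) / mean(cond_b) for one gene, on the linear scale."""
    return float(table.values(gene, cond_a).mean() / table.values(gene, cond_b).mean())


def dependent_genes(
    table: ExpressionTable,
    factor_kd_condition: str,
    ns_condition: str,
    cutoff: float = 1.5,
    direction: str = "down",
    label: str | None = None,
) -> GeneSet:
    """Genes whose expression changes strictly more than ``cutoff``-fold
    under factor knockdown relative to the non-specific control.

    direction "down": NS/KD > cutoff (expression reduced by knockdown);
    direction "up": KD/NS > cutoff.  Symbols are deduplicated after
    upper-casing ("non-redundant" sets).
    """
    if cutoff <= 1:
        raise ValueError("cutoff must exceed 1")
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    ns = table.condition_means(ns_condition)
    kd = table.condition_means(factor_kd_condition)
    common = ns.index.intersection(kd.index)
    ratio = (ns[common] / kd[common]) if direction == "down" else (kd[common] / ns[common])
    hits = ratio[ratio > cutoff].index
    if label is None:
        label = f"{factor_kd_condition}_{direction}"
    return GeneSet.from_symbols(label, hits)


def intersect_sets(a: GeneSet, b: GeneSet) -> GeneSet:
    """Case-insensitive symbol intersection; the label records parentage."""
    return GeneSet(f"({a.label})&({b.label})", a.genes & b.genes)


def classify_direct_targets(
    dependent: GeneSet, peak_genes: GeneSet
) -> tuple[GeneSet, GeneSet]:
    """Partition a dependency set into direct (also peak-assigned) and
    indirect (dependent but without an assigned peak) targets."""
    direct = dependent.genes & peak_genes.genes
    indirect = dependent.genes - peak_genes.genes
    return (
        GeneSet(f"{dependent.label}_direct", direct),
        GeneSet(f"{dependent.label}_indirect", indirect),
    )


def read_gene_set(path: str | Path, label: str | None = None) -> GeneSet:
    """One symbol per line."""
    with open(path) as fh:
        symbols = [line.strip() for line in fh if line.strip()]
    return GeneSet.from_symbols(label or Path(path).stem, symbols)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(gene_set.genes):
            fh.write(g + "\n")
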