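"""Seeded synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a factor ChIP-seq
experiment with a knockout background and siRNA knockdown arrays:

* a small multi-chromosome genome carrying non-overlapping gene models
  with exon/intron structure and intergenic ncRNA loci;
* planted binding sites per factor (SRF plus cofactors co-occupying a
  configurable fraction of SRF sites), some at gene promoters and some
  intergenic, a subset of the intergenic ones flanked by ncRNAs;
* tag libraries with a uniform Poisson background (``lambda_bg`` tags/bp)
  plus Poisson(``lambda_sig``) tags per planted site whose 5' ends sit half
  a fragment length to either side of the site center on opposite strands,
  mimicking ChIP fragment geometry; the knockout library retains a residual
  fraction of the SRF site signal;
* knockdown expression tables with planted fold-change reductions (and
  inductions) under multiplicative log-normal noise.

The modeled chromosomes represent a genomic window from a library
sequenced to ``library_depth`` specifically mapped tags (default 10^7), so
depth normalization behaves as it does on a full-genome library.
Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, NcRNARecord, write_bed12, write_ncrnas
from .expression import ExpressionTable
from .tags import TagLibrary

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_tags",
    "simulate_expression",
]

_FACTOR_STREAMS = {"SRF": 1, "MKL1": 2, "ELK4": 3, "SRF_KO": 4}


@dataclass
class SimulationParams:
    """Knobs of the synthetic study, with defaults chosen to mirror the
    modeled experiment (rates, co-occupancy and knockdown effect sizes)."""

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 200
    exons_per_gene: int = 4
    gene_length_range: tuple[int, int] = (5_000, 20_000)
    n_ncrnas: int = 60
    ncrna_class_props: dict = field(
        default_factory=lambda: {"lncRNA": 0.7, "miRNA": 0.2, "other": 0.1}
    )
    ncrna_near_site_fraction: float = 0.5
    ncrna_length_range: tuple[int, int] = (200, 2_000)
    n_sites: dict = field(default_factory=lambda: {"SRF": 200, "MKL1": 100, "ELK4": 80})
    co_occupancy: dict = field(default_factory=lambda: {"MKL1": 0.685, "ELK4": 0.447})
    promoter_site_fraction: float = 0.4
    min_site_spacing: int = 2_000
    lambda_sig: float = 60.0
    lambda_bg: float = 5e-4
    knockout_residual: float = 0.1
    library_depth: int = 10_000_000
    fragment_len: int = 200
    read_len: int = 25
    n_down: int = 40
    n_up: int = 25
    true_fc: float = 2.0
    log2_noise_sd: float = 0.1
    n_replicates: int = 3
    dependent_with_peak_fraction: float = 0.75
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_sig < 0 or self.lambda_bg < 0:
            raise ValueError("rates must be non-negative")
        for name in ("ncrna_near_site_fraction", "promoter_site_fraction",
                     "knockout_residual", "dependent_with_peak_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for f, frac in self.co_occupancy.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"co-occupancy fraction for {f} must lie in [0, 1]")
        if self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("genome dimensions must be positive")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    chrom_sizes: dict
    gene_symbols: list  # every simulated gene symbol
    sites: dict  # factor -> list of (chrom, center)
    shared_with_srf: dict  # cofactor -> list of bool, aligned with sites
    site_kind: dict  # factor -> list of {"promoter", "intergenic"}
    ncrna_adjacent_sites: list  # (chrom, center) of SRF intergenic sites with ncRNAs planted nearby
    dependent: dict  # factor -> {"down": [...], "up": [...]}
    dependent_with_peak: dict  # factor -> genes from its down-set with a planted promoter site

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["sites"] = {k: [tuple(x) for x in v] for k, v in d["sites"].items()}
        d["ncrna_adjacent_sites"] = [tuple(x) for x in d["ncrna_adjacent_sites"]]
        return cls(**d)


@dataclass
class SimulatedGenome:
    genes: list
    ncrnas: list
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.bed12",
            "ncrnas": outdir / "ncrnas.bed",
            "truth": outdir / "ground_truth.json",
            "chrom_sizes": outdir / "chrom.sizes",
        }
        write_bed12(self.genes, paths["genes"])
        write_ncrnas(self.ncrnas, paths["ncrnas"])
        self.truth.to_json(paths["truth"])
        with open(paths["chrom_sizes"], "w") as fh:
            for chrom in sorted(self.truth.chrom_sizes):
                fh.write(f"{chrom}\t{self.truth.chrom_sizes[chrom]}\n")
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _partition_lengths(rng, total: int, n_parts: int, minimum: int) -> list[int]:
    """Split `total` into n_parts parts each >= minimum, Dirichlet-weighted."""
    leftover = total - n_parts * minimum
    if leftover < 0:
        raise ValueError("infeasible packing: not enough space")
    w = rng.dirichlet(np.ones(n_parts))
    extra = np.floor(w * leftover).astype(int)
    parts = (minimum + extra).tolist()
    parts[-1] += total - sum(parts)
    return parts


def _make_exons(rng, start: int, end: int, n_exons: int) -> tuple[tuple[int, int], ...]:
    n_segments = 2 * n_exons - 1  # exon, intron, exon, ...
    seg = _partition_lengths(rng, end - start, n_segments, 60)
    exons = []
    pos = start
    for i, length in enumerate(seg):
        if i % 2 == 0:
            exons.append((pos, pos + length))
        pos += length
    return tuple(exons)


class _FreeSpace:
    """Sampling positions uniformly from a union of allowed intervals,
    rejecting positions too close to already-accepted sites."""

    def __init__(self, intervals: list[tuple[str, int, int]]):
        self.intervals = [iv for iv in intervals if iv[2] > iv[1]]
        lengths = [e - s for _, s, e in self.intervals]
        self.cum = np.cumsum(lengths)
        self.total = int(self.cum[-1]) if len(self.cum) else 0
        self.accepted: dict[str, list[int]] = {}

    def note(self, chrom: str, pos: int) -> None:
        bisect.insort(self.accepted.setdefault(chrom, []), pos)

    def _clear(self, chrom: str, pos: int, spacing: int) -> bool:
        lst = self.accepted.get(chrom, [])
        i = bisect.bisect_left(lst, pos)
        if i > 0 and pos - lst[i - 1] < spacing:
            return False
        if i < len(lst) and lst[i] - pos < spacing:
            return False
        return True

    def sample(self, rng, spacing: int, max_tries: int = 20_000) -> tuple[str, int]:
        if self.total == 0:
            raise ValueError("no intergenic space available for site placement")
        for _ in range(max_tries):
            x = int(rng.integers(0, self.total))
            k = int(np.searchsorted(self.cum, x, side="right"))
            chrom, s, _e = self.intervals[k]
            offset = x - (int(self.cum[k - 1]) if k else 0)
            pos = s + offset
            if self._clear(chrom, pos, spacing):
                self.note(chrom, pos)
                return chrom, pos
        raise ValueError("could not place site: intergenic space too crowded")


def simulate_genome(params: SimulationParams, seed: int | None = None) -> SimulatedGenome:
    """Generate gene models, ncRNAs, planted sites and dependent gene lists.

    Deterministic per seed; raises on infeasible packing.
    """
    if seed is None:
        seed = params.rng_seed
    rng = np.random.default_rng([int(seed), 11])
    chrom_sizes = {f"chr{i + 1}": params.chrom_length for i in range(params.n_chroms)}
    chroms = sorted(chrom_sizes)

    # --- genes, packed without overlap, generous intergenic gaps -----------
    genes: list[GeneModel] = []
    per_chrom = [params.n_genes // params.n_chroms] * params.n_chroms
    for i in range(params.n_genes % params.n_chroms):
        per_chrom[i] += 1
    gid = 0
    min_gap = 3 * params.min_site_spacing
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        lo, hi = params.gene_length_range
        lengths = rng.integers(lo, hi + 1, size=n)
        gap_total = params.chrom_length - int(lengths.sum())
        gaps = _partition_lengths(rng, gap_total, n + 1, min_gap)
        cursor = 0
        for k in range(n):
            cursor += gaps[k]
            start, end = cursor, cursor + int(lengths[k])
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"GENE{gid:04d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=_make_exons(rng, start, end, params.exons_per_gene),
                )
            )
            cursor = end
    gene_by_id = {g.gene_id: g for g in genes}
    symbols = [g.gene_id for g in genes]

    # --- dependent gene lists per factor -----------------------------------
    dependent: dict[str, dict[str, list[str]]] = {}
    for factor in ("SRF", "MKL12", "ELK4"):
        picked = rng.choice(len(symbols), size=params.n_down + params.n_up, replace=False)
        down = sorted(symbols[i] for i in picked[: params.n_down])
        up = sorted(symbols[i] for i in picked[params.n_down :])
        dependent[factor] = {"down": down, "up": up}

    # --- free intergenic space (clear of gene bodies +/- promoter slop) ----
    margin = params.min_site_spacing
    free: list[tuple[str, int, int]] = []
    for chrom in chroms:
        bodies = sorted(
            (g.tx_start, g.tx_end) for g in genes if g.chrom == chrom
        )
        cursor = margin
        for s, e in bodies:
            if s - margin > cursor:
                free.append((chrom, cursor, s - margin))
            cursor = max(cursor, e + margin)
        if chrom_sizes[chrom] - margin > cursor:
            free.append((chrom, cursor, chrom_sizes[chrom] - margin))
    space = _FreeSpace(free)

    # --- planted sites ------------------------------------------------------
    sites: dict[str, list[tuple[str, int]]] = {}
    site_kind: dict[str, list[str]] = {}
    shared_with_srf: dict[str, list[bool]] = {}
    dependent_with_peak: dict[str, list[str]] = {}

    def promoter_hosts(factor: str, n_planted: int, n_total_prom: int) -> list[str]:
        down = dependent[factor]["down"] if factor in dependent else []
        planted = list(down[:n_planted])
        pool = [s for s in symbols if s not in set(planted)]
        extra_idx = rng.choice(len(pool), size=n_total_prom - n_planted, replace=False)
        return planted + [pool[i] for i in sorted(extra_idx)]

    n_srf = params.n_sites.get("SRF", 0)
    n_prom = int(round(params.promoter_site_fraction * n_srf))
    n_planted = min(int(round(params.dependent_with_peak_fraction * params.n_down)), n_prom)
    hosts = promoter_hosts("SRF", n_planted, n_prom)
    dependent_with_peak["SRF"] = sorted(hosts[:n_planted])
    srf_sites: list[tuple[str, int]] = []
    srf_kind: list[str] = []
    for sym in hosts:
        g = gene_by_id[sym]
        srf_sites.append((g.chrom, g.tss))
        srf_kind.append("promoter")
        space.note(g.chrom, g.tss)
    for _ in range(n_srf - n_prom):
        chrom, pos = space.sample(rng, params.min_site_spacing)
        srf_sites.append((chrom, pos))
        srf_kind.append("intergenic")
    sites["SRF"] = srf_sites
    site_kind["SRF"] = srf_kind

    for factor, n_f in params.n_sites.items():
        if factor == "SRF":
            continue
        frac = params.co_occupancy.get(factor, 0.0)
        n_shared = int(round(frac * n_f))
        host_idx = sorted(rng.choice(n_srf, size=n_shared, replace=False)) if n_shared else []
        f_sites = [srf_sites[i] for i in host_idx]
        f_kind = [srf_kind[i] for i in host_idx]
        f_shared = [True] * n_shared
        n_own = n_f - n_shared
        n_own_prom = int(round(params.promoter_site_fraction * n_own))
        own_hosts: list[str] = []
        pool = list(symbols)
        tries = 0
        while len(own_hosts) < n_own_prom and tries < 10 * len(pool):
            tries += 1
            sym = pool[int(rng.integers(0, len(pool)))]
            g = gene_by_id[sym]
            if space._clear(g.chrom, g.tss, params.min_site_spacing):
                own_hosts.append(sym)
                space.note(g.chrom, g.tss)
        for sym in own_hosts:
            g = gene_by_id[sym]
            f_sites.append((g.chrom, g.tss))
            f_kind.append("promoter")
            f_shared.append(False)
        for _ in range(n_own - len(own_hosts)):
            chrom, pos = space.sample(rng, params.min_site_spacing)
            f_sites.append((chrom, pos))
            f_kind.append("intergenic")
            f_shared.append(False)
        sites[factor] = f_sites
        site_kind[factor] = f_kind
        shared_with_srf[factor] = f_shared

    # --- ncRNAs -------------------------------------------------------------
    ncrnas: list[NcRNARecord] = []
    n_near = int(round(params.ncrna_near_site_fraction * params.n_ncrnas))
    intergenic_srf = [s for s, k in zip(srf_sites, srf_kind) if k == "intergenic"]
    adjacent_sites: list[tuple[str, int]] = []
    lo_len, hi_len = params.ncrna_length_range
    body_lists = {
        chrom: sorted((g.tx_start, g.tx_end) for g in genes if g.chrom == chrom)
        for chrom in chroms
    }

    def in_gene(chrom: str, s: int, e: int) -> bool:
        for bs, be in body_lists[chrom]:
            if s < be and bs < e:
                return True
        return False

    nc_id = 0
    placed_near = 0
    site_cursor = 0
    while placed_near < n_near and site_cursor < len(intergenic_srf):
        chrom, center = intergenic_srf[site_cursor]
        site_cursor += 1
        placed_for_site = False
        for _ in range(50):
            offset = int(rng.integers(3_000, 18_000))
            sign = -1 if rng.random() < 0.5 else 1
            length = int(rng.integers(lo_len, hi_len + 1))
            s = center + sign * offset
            e = s + length
            if s < 0 or e > chrom_sizes[chrom]:
                continue
            if in_gene(chrom, s, e):
                continue
            nc_id += 1
            ncrnas.append(NcRNARecord(f"NCRNA{nc_id:04d}", "other", chrom, s, e))
            placed_near += 1
            placed_for_site = True
            break
        if placed_for_site:
            adjacent_sites.append((chrom, center))
    # far ncRNAs: at least 25 kb from every SRF site
    srf_by_chrom: dict[str, list[int]] = {}
    for chrom, pos in srf_sites:
        srf_by_chrom.setdefault(chrom, []).append(pos)
    for lst in srf_by_chrom.values():
        lst.sort()

    def far_from_srf(chrom: str, s: int, e: int, clearance: int = 25_000) -> bool:
        lst = srf_by_chrom.get(chrom, [])
        i = bisect.bisect_left(lst, s)
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(lst):
                gap = max(lst[j] - e, s - lst[j], 0)
                if gap < clearance:
                    return False
        return True

    tries = 0
    while len(ncrnas) < params.n_ncrnas and tries < 100_000:
        tries += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(lo_len, hi_len + 1))
        s = int(rng.integers(0, chrom_sizes[chrom] - length))
        e = s + length
        if in_gene(chrom, s, e) or not far_from_srf(chrom, s, e):
            continue
        nc_id += 1
        ncrnas.append(NcRNARecord(f"NCRNA{nc_id:04d}", "other", chrom, s, e))
    if len(ncrnas) < params.n_ncrnas:
        raise ValueError("could not place all ncRNAs: genome too crowded")
    # class labels by largest-remainder apportionment, then shuffled
    classes = []
    props = params.ncrna_class_props
    counts = {c: int(np.floor(p * len(ncrnas))) for c, p in props.items()}
    order = sorted(props, key=lambda c: -(props[c] * len(ncrnas) - counts[c]))
    i = 0
    while sum(counts.values()) < len(ncrnas):
        counts[order[i % len(order)]] += 1
        i += 1
    for c in sorted(counts):
        classes += [c] * counts[c]
    classes = [classes[i] for i in rng.permutation(len(classes))]
    ncrnas = [
        NcRNARecord(r.ncrna_id, cls, r.chrom, r.start, r.end)
        for r, cls in zip(ncrnas, classes)
    ]

    truth = GroundTruth(
        chrom_sizes=chrom_sizes,
        gene_symbols=list(symbols),
        sites=sites,
        shared_with_srf=shared_with_srf,
        site_kind=site_kind,
        ncrna_adjacent_sites=adjacent_sites,
        dependent=dependent,
        dependent_with_peak=dependent_with_peak,
    )
    return SimulatedGenome(genes=genes, ncrnas=ncrnas, truth=truth)


# ---------------------------------------------------------------------------
# tags
# ---------------------------------------------------------------------------

def simulate_tags(
    truth: GroundTruth,
    params: SimulationParams,
    factor: str,
    seed: int | None = None,
) -> TagLibrary:
    """Simulate one tag library: Poisson background plus planted-site signal.

    ``factor`` may be any key of ``truth.sites`` or ``"SRF_KO"`` for the
    knockout background (SRF sites at ``knockout_residual`` of the signal
    rate).  Tag 5' positions sit half a fragment length to either side of
    the site center on opposite strands, with read-scale jitter.
    """
    if seed is None:
        seed = params.rng_seed
    stream = _FACTOR_STREAMS.get(factor, 97 + sum(ord(c) for c in factor) % 100)
    rng = np.random.default_rng([int(seed), stream])
    if factor == "SRF_KO":
        site_list = truth.sites.get("SRF", [])
        rate = params.lambda_sig * params.knockout_residual
    else:
        site_list = truth.sites.get(factor, [])
        rate = params.lambda_sig
    lib = TagLibrary(label=factor)
    half = params.fragment_len // 2
    jitter_half = params.read_len
    stored = 0
    for chrom in sorted(truth.chrom_sizes):
        size = int(truth.chrom_sizes[chrom])
        n_bg = int(rng.poisson(params.lambda_bg * size))
        pos_parts = [rng.integers(0, size, size=n_bg)]
        rev_parts = [rng.random(n_bg) < 0.5]
        for site_chrom, center in site_list:
            if site_chrom != chrom:
                continue
            n = int(rng.poisson(rate))
            if n == 0:
                continue
            rev = rng.random(n) < 0.5
            jitter = rng.integers(-jitter_half, jitter_half + 1, size=n)
            pos = np.where(rev, center + half - 1, center - half) + jitter
            np.clip(pos, 0, size - 1, out=pos)
            pos_parts.append(pos)
            rev_parts.append(rev)
        pos_all = np.concatenate(pos_parts)
        rev_all = np.concatenate(rev_parts)
        order = np.argsort(pos_all, kind="stable")
        lib.add(chrom, pos_all[order], rev_all[order])
        stored += len(pos_all)
    lib.total_tags = max(int(params.library_depth), stored)
    lib.validate()
    return lib


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    truth: GroundTruth,
    params: SimulationParams,
    seed: int | None = None,
    genes: list[str] | None = None,
) -> ExpressionTable:
    """Simulate the knockdown expression table.

    Baseline abundance per gene is log-normal; each factor-knockdown
    condition divides its planted "down" genes by ``true_fc`` (and
    multiplies "up" genes by it); every measurement carries multiplicative
    noise 2**N(0, log2_noise_sd**2).  Conditions: NS plus one per factor.
    """
    if seed is None:
        seed = params.rng_seed
    rng = np.random.default_rng([int(seed), 23])
    if genes is None:
        genes = truth.gene_symbols or sorted(
            {g for d in truth.dependent.values() for lst in d.values() for g in lst}
        )
    genes = sorted(genes)
    base = np.exp2(rng.normal(7.0, 1.5, size=len(genes)))
    conditions = ["NS"] + [f"{f}_kd" for f in sorted(truth.dependent)]
    rows = []
    for cond in conditions:
        factor = cond[:-3] if cond.endswith("_kd") else None
        down = set(truth.dependent.get(factor, {}).get("down", [])) if factor else set()
        up = set(truth.dependent.get(factor, {}).get("up", [])) if factor else set()
        for rep in range(1, params.n_replicates + 1):
            noise = np.exp2(rng.normal(0.0, params.log2_noise_sd, size=len(genes)))
            for i, g in enumerate(genes):
                effect = 1.0
                if g in down:
                    effect = 1.0 / params.true_fc
                elif g in up:
                    effect = params.true_fc
                rows.append(
                    {
                        "gene": g,
                        "condition": cond,
                        "replicate": rep,
                        "value": base[i] * effect * noise[i],
                        "treatment": "zymosan_1h",
                    }
                )
    return ExpressionTable(pd.DataFrame(rows))
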