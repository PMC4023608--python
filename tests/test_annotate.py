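"""Nearest-gene assignment, location classes, ncRNA association, CArG scan."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srfpipe.annotation import GeneModel, NcRNARecord, build_index
from srfpipe.annotate import (
    assign_nearest_gene,
    associate_ncrnas,
    classify_location,
    scan_carg,
)
from srfpipe.peaks import Peak


def _peak(chrom, start, end, summit=None):
    return Peak("SRF", chrom, start, end, summit if summit is not None else (start + end) // 2, 30, 60.0)


def _gene(gid, tss, strand="+", length=2_000, chrom="chr1"):
    if strand == "+":
        start, end = tss, tss + length
    else:
        start, end = tss - length + 1, tss + 1
    return GeneModel(gid, chrom, strand, start, end, ((start, end),))


def test_nearest_gene_and_signed_distance():
    idx = build_index([_gene("a", 4_000, "+"), _gene("b", 8_000, "+")])
    ga = assign_nearest_gene(_peak("chr1", 4_900, 5_100, summit=5_000), idx)
    assert ga.gene_id == "a"
    assert ga.distance == 1_000  # downstream of a + strand TSS
    idx_minus = build_index([_gene("a", 4_000, "-"), _gene("b", 8_000, "-")])
    ga = assign_nearest_gene(_peak("chr1", 4_900, 5_100, summit=5_000), idx_minus)
    assert ga.distance == -1_000  # same side is upstream in - orientation


def test_equidistant_tie_goes_to_smaller_coordinate():
    idx = build_index([_gene("far", 8_000), _gene("near", 4_000)])
    ga = assign_nearest_gene(_peak("chr1", 5_900, 6_100, summit=6_000), idx)
    assert ga.gene_id == "near"


def test_unannotated_chromosome_gives_unassigned_marker():
    idx = build_index([_gene("a", 4_000)])
    ga = assign_nearest_gene(_peak("chrX", 0, 200), idx)
    assert ga.gene_id is None and ga.distance is None


def test_nearest_gene_matches_bruteforce_oracle():
    rng = np.random.default_rng(21)
    genes = [
        _gene(f"g{i:02d}", int(rng.integers(5_000, 995_000)),
              "+" if rng.random() < 0.5 else "-")
        for i in range(50)
    ]
    idx = build_index(genes)
    for _ in range(500):
        s = int(rng.integers(0, 1_000_000))
        best = min(genes, key=lambda g: (abs(s - g.tss), g.tss, g.gene_id))
        ga = assign_nearest_gene(_peak("chr1", max(s - 100, 0), s + 100, summit=s), idx)
        assert ga.gene_id == best.gene_id
        assert abs(ga.distance) == abs(s - best.tss)


def test_nearest_distance_invariant_under_farther_genes():
    base = [_gene("a", 10_000)]
    idx1 = build_index(base)
    idx2 = build_index(base + [_gene("z", 500_000)])
    p = _peak("chr1", 11_900, 12_100, summit=12_000)
    assert assign_nearest_gene(p, idx1).distance == assign_nearest_gene(p, idx2).distance


def test_location_precedence_and_windows():
    # gene on +: TSS 10000, exon1 10000-11000, intron, exon2 14000-15000
    gene = GeneModel("g", "chr1", "+", 10_000, 15_000,
                     ((10_000, 11_000), (14_000, 15_000)))
    idx = build_index([gene], promoter_window=1000)
    # summit 500 bp upstream of the TSS: promoter
    assert classify_location(_peak("chr1", 9_400, 9_600), idx) == "promoter"
    # inclusive at exactly 1000 bp
    assert classify_location(_peak("chr1", 8_900, 9_100, summit=9_000), idx) == "promoter"
    assert classify_location(_peak("chr1", 8_898, 9_100, summit=8_999), idx) == "intergenic"
    # promoter outranks exon inside the window
    assert classify_location(_peak("chr1", 10_400, 10_600, summit=10_500), idx) == "promoter"
    # exon beyond the promoter window
    assert classify_location(_peak("chr1", 14_400, 14_600, summit=14_500), idx) == "exon"
    # intron between the exons
    assert classify_location(_peak("chr1", 12_400, 12_600, summit=12_500), idx) == "intron"
    # unannotated chromosome
    assert classify_location(_peak("chrX", 0, 200), idx) == "intergenic"


def test_location_classes_partition(small_genome, default_params):
    from srfpipe.peaks import call_peaks
    from srfpipe.simulate import simulate_tags
    from srfpipe.tags import norm_factor, window_counts

    lib = simulate_tags(small_genome.truth, default_params, "SRF", seed=7)
    track = window_counts(lib, 200, 200, small_genome.truth.chrom_sizes)
    peaks = call_peaks(track, norm_factor(lib.total_tags), 20.0, "SRF")
    idx = build_index(small_genome.genes, small_genome.ncrnas, 1000)
    classes = [classify_location(p, idx) for p in peaks]
    assert all(c in ("promoter", "exon", "intron", "intergenic") for c in classes)
    assert len(classes) == len(peaks)  # exactly one class per peak


def test_ncrna_association_window_boundaries():
    nc_in = NcRNARecord("in", "lncRNA", "chr1", 119_000, 119_500)     # gap 18800
    nc_edge = NcRNARecord("edge", "miRNA", "chr1", 120_200, 120_700)  # gap exactly 20000
    nc_out = NcRNARecord("out", "lncRNA", "chr1", 120_201, 120_701)   # gap 20001
    idx = build_index([], [nc_in, nc_edge, nc_out])
    rep = associate_ncrnas([_peak("chr1", 100_000, 100_200)], idx, window=20_000)
    assert rep.per_peak == [["in", "edge"]]
    assert rep.n_associated == 1 and rep.associated_fraction == 1.0


def test_ncrna_report_class_breakdown():
    ncrnas = [
        NcRNARecord("l1", "lncRNA", "chr1", 10_000, 10_500),
        NcRNARecord("l2", "lncRNA", "chr1", 11_000, 11_500),
        NcRNARecord("m1", "miRNA", "chr1", 12_000, 12_100),
    ]
    idx = build_index([], ncrnas)
    peaks = [_peak("chr1", 9_000, 9_200), _peak("chr1", 500_000, 500_200)]
    rep = associate_ncrnas(peaks, idx, 20_000)
    assert rep.n_peaks == 2 and rep.n_associated == 1
    assert rep.unique_ncrnas == ["l1", "l2", "m1"]
    assert rep.class_counts == {"lncRNA": 2, "miRNA": 1, "other": 0}
    assert sum(rep.class_fractions.values()) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("CCATATATGG", [0]),
        ("CCGTATATGG", []),
        ("ACCAAAAAAGGT", [1]),
        ("CCNTTTTTTGG", []),  # N never matches a W position
        ("", []),
    ],
)
def test_scan_carg_examples(seq, expected):
    assert scan_carg(seq) == expected


_CARG_RE = re.compile(r"(?=(CC[AT]{6}GG))")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=0, max_size=1_000))
def test_scan_carg_agrees_with_regex_oracle(seq):
    assert scan_carg(seq) == [m.start() for m in _CARG_RE.finditer(seq)]


_COMP = str.maketrans("ACGT", "TGCA")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=10, max_size=400))
def test_scan_carg_palindromic_under_reverse_complement(seq):
    rc = seq.translate(_COMP)[::-1]
    assert sorted(len(seq) - 10 - x for x in scan_carg(seq)) == scan_carg(rc)
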