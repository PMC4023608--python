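"""Gene-model parsing, TSS conventions and index/oracle equivalence."""

import numpy as np
import pytest

from srfpipe.annotation import (
    AnnotationParseError,
    GeneModel,
    NcRNARecord,
    build_index,
    read_gene_models,
    read_ncrnas,
    tss_of,
    write_bed12,
    write_ncrnas,
)


def test_bed12_block_semantics(tmp_path):
    # exons from block sizes/starts relative to tx_start; intron is the gap
    p = tmp_path / "g.bed"
    p.write_text("chr1\t1000\t5000\tgeneA\t0\t+\t1000\t5000\t0\t2\t200,300\t0,3700\n")
    (m,) = read_gene_models(p, "bed12")
    assert m.exons == ((1000, 1200), (4700, 5000))
    assert m.introns == ((1200, 4700),)


def test_empty_file_gives_empty_list(tmp_path):
    p = tmp_path / "empty.bed"
    p.write_text("")
    assert read_gene_models(p, "bed12") == []


def test_gff3_one_based_closed_conversion(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text(
        "chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tParent=tx1\n"
        "chr1\tsrc\texon\t1501\t2000\t.\t+\t.\tParent=tx1\n"
    )
    (m,) = read_gene_models(p, "gff3")
    assert m.exons == ((1000, 1200), (1500, 2000))
    assert (m.tx_start, m.tx_end) == (1000, 2000)


def test_refflat_parsing(tmp_path):
    p = tmp_path / "g.refflat"
    p.write_text(
        "GENEA\tNM_1\tchr2\t-\t100\t900\t100\t900\t2\t100,600,\t300,900,\n"
    )
    (m,) = read_gene_models(p, "refflat")
    assert m.strand == "-"
    assert m.exons == ((100, 300), (600, 900))


def test_malformed_line_names_line_number(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t1000\t5000\tok\t0\t+\t1000\t5000\t0\t1\t4000\t0\n"
                 "chr1\tnotanint\t5000\tbad\t0\t+\t0\t0\t0\t1\t10\t0\n")
    with pytest.raises(AnnotationParseError, match="line 2"):
        read_gene_models(p, "bed12")


def test_unknown_format_is_usage_error(tmp_path):
    p = tmp_path / "g.bed"
    p.write_text("")
    with pytest.raises(ValueError, match="unknown format"):
        read_gene_models(p, "gtf")


@pytest.mark.parametrize(
    "strand,expected", [("+", 1000), ("-", 4999)]
)
def test_tss_is_five_prime_most_base(strand, expected):
    m = GeneModel("g", "chr1", strand, 1000, 5000, ((1000, 5000),))
    assert tss_of(m) == expected


def test_gene_model_invariants_enforced():
    with pytest.raises(ValueError):
        GeneModel("g", "chr1", "+", 5000, 1000, ((1000, 2000),))
    with pytest.raises(ValueError):
        GeneModel("g", "chr1", "+", 1000, 5000, ())
    with pytest.raises(ValueError):  # exon outside body
        GeneModel("g", "chr1", "+", 1000, 5000, ((900, 1200),))
    with pytest.raises(ValueError):  # overlapping exons
        GeneModel("g", "chr1", "+", 1000, 5000, ((1000, 2000), (1500, 3000)))


def test_bed12_round_trip(tmp_path, small_genome):
    path = tmp_path / "rt.bed12"
    write_bed12(small_genome.genes, path)
    back = read_gene_models(path, "bed12")
    assert back == small_genome.genes


def test_intron_set_is_body_minus_exons(small_genome):
    for m in small_genome.genes[:50]:
        covered = set()
        for s, e in m.exons:
            covered.update(range(s, e))
        for s, e in m.introns:
            covered.update(range(s, e))
        assert covered == set(range(m.tx_start, m.tx_end))


def test_ncrna_round_trip(tmp_path, small_genome):
    path = tmp_path / "nc.bed"
    write_ncrnas(small_genome.ncrnas, path)
    assert read_ncrnas(path) == small_genome.ncrnas


def test_ncrna_class_validated():
    with pytest.raises(ValueError):
        NcRNARecord("x", "rRNA", "chr1", 0, 10)


def _random_annotation(rng, n_genes=100, span=1_000_000):
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, span - 10_000))
        length = int(rng.integers(2_000, 10_000))
        n_ex = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex - 2, replace=False)) if n_ex > 1 else np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), length]
        exons = tuple(
            (start + bounds[2 * k], start + bounds[2 * k + 1]) for k in range(n_ex)
        )
        genes.append(
            GeneModel(f"g{i:03d}", "chr1", "+" if rng.random() < 0.5 else "-",
                      start, start + length, exons)
        )
    return genes


def test_index_matches_linear_scan_oracle():
    """Point and nearest-TSS queries agree with brute force on random data."""
    rng = np.random.default_rng(123)
    genes = _random_annotation(rng)
    ncrnas = [
        NcRNARecord(f"n{i:03d}", "lncRNA", "chr1",
                    int(s := rng.integers(0, 990_000)), int(s) + int(rng.integers(100, 5_000)))
        for i in range(40)
    ]
    idx = build_index(genes, ncrnas, promoter_window=1000)
    tss = [(g.tss, g.gene_id) for g in genes]
    for _ in range(1000):
        pos = int(rng.integers(0, 1_000_000))
        in_exon = sorted(
            g.gene_id for g in genes if any(s <= pos < e for s, e in g.exons)
        )
        in_body = sorted(g.gene_id for g in genes if g.tx_start <= pos < g.tx_end)
        assert idx.exons_at("chr1", pos) == in_exon
        assert idx.gene_bodies_at("chr1", pos) == in_body
        best = min(tss, key=lambda t: (abs(pos - t[0]), t[0], t[1]))
        got = idx.nearest_tss("chr1", pos)
        assert got is not None and got[0] == best[1]
        assert idx.min_tss_distance("chr1", pos) == abs(pos - best[0])
        window = 5_000
        near = sorted(
            r.ncrna_id
            for r in ncrnas
            if max(r.start - (pos + 1), pos - r.end, 0) <= window
        )
        assert sorted(r.ncrna_id for r in idx.ncrnas_near("chr1", pos, pos + 1, window)) == near


def test_empty_annotation_queries_return_empty():
    idx = build_index([], [], 1000)
    assert idx.exons_at("chr1", 100) == []
    assert idx.gene_bodies_at("chr1", 100) == []
    assert idx.nearest_tss("chr1", 100) is None
    assert idx.ncrnas_near("chr1", 0, 200, 20_000) == []
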