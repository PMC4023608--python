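"""Synthetic-data generator: determinism, invariants and noise model."""

import numpy as np
import pytest
from scipy import stats

from srfpipe.annotation import read_gene_models, read_ncrnas
from srfpipe.expression import fold_change
from srfpipe.peaks import call_peaks
from srfpipe.simulate import (
    SimulationParams,
    simulate_expression,
    simulate_genome,
    simulate_tags,
)
from srfpipe.tags import norm_factor, window_counts, write_tags


def test_genome_defaults_satisfy_invariants(small_genome, default_params):
    g = small_genome
    assert len(g.genes) == default_params.n_genes
    assert len(g.ncrnas) == default_params.n_ncrnas
    # non-overlapping genes per chromosome
    by_chrom = {}
    for m in g.genes:
        by_chrom.setdefault(m.chrom, []).append((m.tx_start, m.tx_end))
    for ivs in by_chrom.values():
        ivs.sort()
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
    # sites exist for every factor with the configured counts
    for factor, n in default_params.n_sites.items():
        assert len(g.truth.sites[factor]) == n
    # cofactor sharing matches the configured co-occupancy
    for factor, frac in default_params.co_occupancy.items():
        shared = sum(g.truth.shared_with_srf[factor])
        assert shared == round(frac * default_params.n_sites[factor])
        srf = set(g.truth.sites["SRF"])
        for site, is_shared in zip(g.truth.sites[factor], g.truth.shared_with_srf[factor]):
            assert (site in srf) == is_shared


def test_ncrnas_land_in_intergenic_space(small_genome):
    bodies = {}
    for m in small_genome.genes:
        bodies.setdefault(m.chrom, []).append((m.tx_start, m.tx_end))
    for r in small_genome.ncrnas:
        assert not any(
            r.start < e and s < r.end for s, e in bodies.get(r.chrom, [])
        )


def test_same_seed_gives_byte_identical_files(tmp_path, default_params):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for d in (d1, d2):
        genome = simulate_genome(default_params, seed=5)
        genome.write(d)
        lib = simulate_tags(genome.truth, default_params, "SRF", seed=5)
        write_tags(lib, d / "tags.bed")
        simulate_expression(genome.truth, default_params, seed=5).to_tsv(d / "expr.tsv")
    for name in ("genes.bed12", "ncrnas.bed", "ground_truth.json", "tags.bed", "expr.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_emitted_files_reparse_into_valid_objects(tmp_path, small_genome):
    paths = small_genome.write(tmp_path)
    genes = read_gene_models(paths["genes"], "bed12")
    assert genes == small_genome.genes
    assert read_ncrnas(paths["ncrnas"]) == small_genome.ncrnas


def test_infeasible_packing_raises():
    params = SimulationParams(n_chroms=1, chrom_length=100_000, n_genes=50)
    with pytest.raises(ValueError, match="infeasible"):
        simulate_genome(params, seed=0)


def test_zero_ncrnas_supported():
    params = SimulationParams(n_ncrnas=0)
    g = simulate_genome(params, seed=1)
    assert g.ncrnas == []


def test_pure_background_yields_no_peaks(default_params):
    """With no planted signal the Poisson background never clears the
    threshold: P(window count > 20 | lambda=0.1) is ~1e-40 genome-wide."""
    params = SimulationParams(lambda_sig=0.0)
    g = simulate_genome(params, seed=3)
    lib = simulate_tags(g.truth, params, "SRF", seed=3)
    track = window_counts(lib, 200, 200, g.truth.chrom_sizes)
    peaks = call_peaks(track, norm_factor(lib.total_tags), 20.0)
    assert peaks == []


def test_background_tag_count_scales_with_rate(default_params, small_genome):
    lib1 = simulate_tags(small_genome.truth, default_params, "SRF", seed=9)
    doubled = SimulationParams(lambda_bg=2 * default_params.lambda_bg)
    lib2 = simulate_tags(small_genome.truth, doubled, "SRF", seed=9)
    genome_bp = sum(small_genome.truth.chrom_sizes.values())
    n_sites = len(small_genome.truth.sites["SRF"])
    expected1 = default_params.lambda_bg * genome_bp + n_sites * default_params.lambda_sig
    expected2 = 2 * default_params.lambda_bg * genome_bp + n_sites * default_params.lambda_sig
    for lib, expected in ((lib1, expected1), (lib2, expected2)):
        sd = np.sqrt(expected)
        assert abs(lib.n_stored - expected) < 3 * sd


def test_knockout_library_keeps_residual_signal(default_params, small_genome):
    ko = simulate_tags(small_genome.truth, default_params, "SRF_KO", seed=9)
    genome_bp = sum(small_genome.truth.chrom_sizes.values())
    n_sites = len(small_genome.truth.sites["SRF"])
    expected = (
        default_params.lambda_bg * genome_bp
        + n_sites * default_params.lambda_sig * default_params.knockout_residual
    )
    assert abs(ko.n_stored - expected) < 4 * np.sqrt(expected)


def test_noise_free_expression_recovers_exact_fold_change(small_genome):
    params = SimulationParams(log2_noise_sd=0.0)
    table = simulate_expression(small_genome.truth, params, seed=4)
    g_down = small_genome.truth.dependent["SRF"]["down"][0].upper()
    g_up = small_genome.truth.dependent["SRF"]["up"][0].upper()
    assert fold_change(table, g_down, "NS", "SRF_kd") == pytest.approx(2.0)
    assert fold_change(table, g_up, "SRF_kd", "NS") == pytest.approx(2.0)


def test_null_expression_false_positive_rate_matches_normal_tail():
    """Without planted effects, the count of genes passing the 1.5-fold
    filter matches the analytic normal-tail expectation for the noise."""
    params = SimulationParams(n_down=0, n_up=0, log2_noise_sd=0.3, n_replicates=3)
    g = simulate_genome(params, seed=6)
    from srfpipe.expression import dependent_genes

    n_hits = []
    for seed in range(10):
        table = simulate_expression(g.truth, params, seed=seed,
                                    genes=[m.gene_id for m in g.genes])
        down = dependent_genes(table, "SRF_kd", "NS", 1.5, "down")
        up = dependent_genes(table, "SRF_kd", "NS", 1.5, "up")
        n_hits.append(len(down) + len(up))
    # log2 FC of replicate means is ~ N(0, sigma*sqrt(2/3)); two-sided tail
    sd = params.log2_noise_sd * np.sqrt(2 / params.n_replicates)
    p_tail = 2 * stats.norm.sf(np.log2(1.5) / sd)
    expected = p_tail * params.n_genes
    # generous band: the linear-scale mean is only approximately log-normal
    assert 0.2 * expected <= np.mean(n_hits) <= 3.0 * expected + 1
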