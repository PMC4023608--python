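"""Threshold peak calling, background filtering and empirical FDR."""

import math

import numpy as np
import pytest

from srfpipe.peaks import (
    Peak,
    background_filter,
    call_peaks,
    estimate_fdr,
    read_peaks_bed,
    write_peaks_bed,
)
from srfpipe.tags import TagLibrary, WindowTrack


def _track(raw, window_size=200, chrom="chr1"):
    return WindowTrack(window_size=window_size, counts={chrom: np.array(raw, dtype=np.int64)})


def test_threshold_is_strict():
    # normalized 30 > 20 is a peak; normalized exactly 20 is not
    assert len(call_peaks(_track([15]), 2.0, 20.0)) == 1
    assert len(call_peaks(_track([10]), 2.0, 20.0)) == 0


def test_adjacent_positive_windows_merge():
    peaks = call_peaks(_track([0, 12, 13, 0]), 2.0, 20.0)
    assert len(peaks) == 1
    (p,) = peaks
    assert (p.start, p.end) == (200, 600)
    assert p.raw_count == 13 and p.norm_count == 26.0
    assert p.summit == 500  # center of the max window


def test_peak_invariants_on_random_tracks():
    rng = np.random.default_rng(11)
    for _ in range(50):
        raw = rng.poisson(8, size=300)
        f = float(rng.uniform(0.5, 4.0))
        for p in call_peaks(_track(raw), f, 20.0):
            assert p.start < p.end
            assert p.start <= p.summit < p.end
            assert p.norm_count > 20.0


def test_merge_matches_bruteforce_runs():
    """Peak intervals equal brute-force runs of threshold-positive windows."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        raw = rng.poisson(9, size=120)
        f = float(rng.uniform(1.0, 3.0))
        positive = [i for i, r in enumerate(raw) if r * f > 20.0]
        runs = []
        for i in positive:
            if runs and i == runs[-1][-1] + 1:
                runs[-1].append(i)
            else:
                runs.append([i])
        peaks = call_peaks(_track(raw), f, 20.0)
        assert [(p.start // 200, p.end // 200) for p in peaks] == [
            (r[0], r[-1] + 1) for r in runs
        ]


def test_threshold_raising_nests_peaks():
    """Raising the threshold shrinks the peak-positive windows: every peak
    at a higher threshold lies inside some peak at a lower threshold, and
    the covered window count never grows.  (The *number* of merged peaks is
    monotone only for sparse signal, where run-splitting cannot occur.)"""
    rng = np.random.default_rng(3)
    raw = rng.poisson(10, size=500)
    prev = None
    for t in (5, 10, 20, 40, 80):
        peaks = call_peaks(_track(raw), 2.0, t)
        covered = sum(p.end - p.start for p in peaks)
        if prev is not None:
            prev_peaks, prev_covered = prev
            assert covered <= prev_covered
            for p in peaks:
                assert any(q.start <= p.start and p.end <= q.end for q in prev_peaks)
        prev = (peaks, covered)
    # sparse signal: count monotonicity does hold
    sparse = np.zeros(500, dtype=np.int64)
    sparse[rng.choice(500, size=12, replace=False)] = rng.integers(11, 60, size=12)
    counts = [len(call_peaks(_track(sparse), 2.0, t)) for t in (5, 10, 20, 40, 80)]
    assert counts == sorted(counts, reverse=True)


def test_background_ratio_inclusive_at_four_fold():
    peaks = [Peak("SRF", "chr1", 0, 200, 100, 40, 40.0)]
    kept = background_filter(peaks, _track([10]), 1.0, min_ratio=4.0)
    assert len(kept) == 1 and kept[0].bg_norm_count == 10.0
    removed = background_filter(
        [Peak("SRF", "chr1", 0, 200, 100, 39, 39.0)], _track([10]), 1.0, 4.0
    )
    assert removed == []


def test_background_pseudocount_handles_zero_background():
    peaks = [Peak("SRF", "chr1", 0, 200, 100, 40, 40.0)]
    kept = background_filter(peaks, _track([0]), 1.0, 4.0, pseudocount=1.0)
    assert len(kept) == 1


def test_background_ratio_monotonicity():
    rng = np.random.default_rng(9)
    raw = rng.poisson(15, size=400)
    bg = rng.poisson(4, size=400)
    peaks = call_peaks(_track(raw), 2.0, 20.0)
    survivors = [
        len(background_filter(peaks, _track(bg), 1.0, r)) for r in (1, 2, 4, 8, 16)
    ]
    assert survivors == sorted(survivors, reverse=True)


def test_background_window_scheme_mismatch_errors():
    peaks = [Peak("SRF", "chr1", 0, 300, 100, 40, 40.0)]  # not aligned to 200
    with pytest.raises(ValueError, match="window scheme"):
        background_filter(peaks, _track([0, 0]), 1.0)


def test_fdr_of_self_shuffled_library_is_near_one():
    """A uniform library is its own shuffle: observed and shuffled peak
    counts follow the same law, so the FDR estimate is ~1."""
    rng = np.random.default_rng(17)
    lib = TagLibrary(label="null")
    # dense uniform tags with a tiny total so normalization lifts single
    # tags over the threshold: every occupied window is a peak
    lib.add("chr1", rng.integers(0, 1_000_000, size=5_000), rng.random(5_000) < 0.5)
    lib.total_tags = lib.n_stored
    fdr = estimate_fdr(lib, {"chr1": 1_000_000}, threshold=20.0, n_shuffles=20, seed=1)
    assert 0.9 < fdr < 1.1


def test_fdr_zero_when_shuffles_yield_no_peaks(default_params, small_genome):
    from srfpipe.simulate import simulate_tags

    lib = simulate_tags(small_genome.truth, default_params, "SRF", seed=7)
    fdr = estimate_fdr(lib, small_genome.truth.chrom_sizes, 20.0, n_shuffles=3, seed=7)
    assert fdr == 0.0


def test_fdr_undefined_without_observed_peaks():
    lib = TagLibrary(label="sparse")
    lib.add("chr1", np.array([100, 50_000]), np.array([False, False]))
    lib.total_tags = 10_000_000  # deep library: two tags can never pass 20
    assert math.isnan(estimate_fdr(lib, {"chr1": 100_000}, 20.0, 2, 0))


def test_fdr_deterministic_for_fixed_seed():
    rng = np.random.default_rng(4)
    lib = TagLibrary(label="n")
    lib.add("chr1", rng.integers(0, 500_000, size=3_000), rng.random(3_000) < 0.5)
    lib.total_tags = lib.n_stored
    a = estimate_fdr(lib, {"chr1": 500_000}, 20.0, 5, seed=42)
    b = estimate_fdr(lib, {"chr1": 500_000}, 20.0, 5, seed=42)
    assert a == b


def test_peaks_bed_round_trip(tmp_path):
    peaks = [
        Peak("SRF", "chr1", 200, 600, 500, 13, 26.0, bg_norm_count=2.0),
        Peak("SRF", "chr2", 0, 200, 100, 40, 80.0),
    ]
    path = tmp_path / "p.bed"
    write_peaks_bed(peaks, path)
    back = read_peaks_bed(path, "SRF")
    assert [(p.chrom, p.start, p.end, p.summit, p.raw_count) for p in back] == [
        (p.chrom, p.start, p.end, p.summit, p.raw_count) for p in peaks
    ]
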