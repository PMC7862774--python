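"""Resampling null, window thresholds, and region merging."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from bulkscan.significance import (
    CandidateRegion,
    NullConfig,
    RegionCriteria,
    call_regions,
    null_delta_distribution,
    threshold_for_windows,
)


def enumerate_null_bulk1_depth1():
    """Exact |Δ| distribution for bulk_size=1, depth_T=depth_S=1.

    The bulk frequency is f = dosage/2 with dosage ~ {0,1,2} at (1/4,1/2,1/4);
    the single read supports HHZ with probability f.  Enumerate the
    3x3 genotype x 2x2 read outcome space.
    """
    dosage_p = {0: 0.25, 1: 0.5, 2: 0.25}
    dist: dict[float, float] = {}
    for d_t, d_s in itertools.product(dosage_p, repeat=2):
        f_t, f_s = d_t / 2, d_s / 2
        for r_t, r_s in itertools.product((0, 1), repeat=2):
            p = (
                dosage_p[d_t]
                * dosage_p[d_s]
                * (f_t if r_t else 1 - f_t)
                * (f_s if r_s else 1 - f_s)
            )
            delta = abs(r_t - r_s)
            dist[delta] = dist.get(delta, 0.0) + p
    return dist


class TestNullDistribution:
    def test_exact_enumeration_bulk1_depth1(self):
        dist = enumerate_null_bulk1_depth1()
        # with one read per pool the index is 0 or 1, so |Δ| ∈ {0, 1}
        assert set(dist) == {0.0, 1.0}
        assert dist[1.0] == pytest.approx(0.5)
        with pytest.warns(UserWarning, match="noisy"):
            cfg = NullConfig(bulk_size=1, n_reps=4_000, confidence=(0.999,), seed=1)
        samples = null_delta_distribution(1, 1, cfg)
        assert set(np.unique(samples)) <= {0.0, 1.0}
        assert abs(samples.mean() - dist[1.0]) < 3 * math.sqrt(0.25 / cfg.n_reps)
        # any P(|Δ|=1) > 0.001 forces the 99.9% quantile to 1
        assert np.quantile(samples, 0.999, method="higher") == 1.0

    def test_deep_sequencing_leaves_only_genotype_noise(self):
        cfg = NullConfig(bulk_size=50, n_reps=20_000, confidence=(0.999,), seed=2)
        samples = null_delta_distribution(10_000, 10_000, cfg)
        assert np.quantile(samples, 0.999, method="higher") < 0.35

    def test_quantiles_monotone_in_confidence(self):
        cfg = NullConfig(bulk_size=50, n_reps=10_000, seed=3)
        samples = null_delta_distribution(57, 57, cfg)
        q50, q999 = np.quantile(samples, [0.5, 0.999], method="higher")
        assert q50 <= q999

    def test_depths_must_be_positive(self):
        cfg = NullConfig(bulk_size=50, n_reps=10_000, seed=4)
        with pytest.raises(ValueError):
            null_delta_distribution(0, 10, cfg)


def _window_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_snps", "mean_index_t", "mean_index_s",
            "mean_delta", "median_depth_t", "median_depth_s", "flagged",
        ],
    )


def _win(chrom, start, end, delta, n_snps=10, t=0.8, s=0.1, depth=57, flagged=False):
    return (chrom, start, end, n_snps, t, s, delta, depth, depth, flagged)


class TestWindowThresholds:
    def test_identical_windows_get_identical_thresholds(self):
        win = _window_frame([_win("chr1", 1, 100, 0.1), _win("chr1", 51, 150, 0.2)])
        cfg = NullConfig(bulk_size=50, n_reps=10_000, seed=5)
        thr = threshold_for_windows(win, cfg)
        assert thr["thr_0.999"].iloc[0] == thr["thr_0.999"].iloc[1]

    def test_more_snps_tighten_the_threshold(self):
        # averaging over more sites cancels more read noise
        win = _window_frame(
            [_win("chr1", 1, 100, 0.1, n_snps=50), _win("chr1", 51, 150, 0.1, n_snps=5)]
        )
        cfg = NullConfig(bulk_size=50, n_reps=50_000, seed=6)
        thr = threshold_for_windows(win, cfg)
        assert thr["thr_0.999"].iloc[0] < thr["thr_0.999"].iloc[1]

    def test_doubling_depth_does_not_raise_thresholds(self):
        base = _window_frame([_win("chr1", 1, 100, 0.1, depth=30)])
        deep = _window_frame([_win("chr1", 1, 100, 0.1, depth=60)])
        cfg = NullConfig(bulk_size=50, n_reps=50_000, seed=7)
        t_base = threshold_for_windows(base, cfg)["thr_0.999"].iloc[0]
        t_deep = threshold_for_windows(deep, cfg)["thr_0.999"].iloc[0]
        assert t_deep <= t_base + 0.01  # allow Monte-Carlo jitter at the tail

    def test_flagged_windows_get_no_threshold(self):
        win = _window_frame([_win("chr1", 1, 100, 0.1, n_snps=1, flagged=True)])
        cfg = NullConfig(bulk_size=50, n_reps=1_000, confidence=(0.95,), seed=8)
        thr = threshold_for_windows(win, cfg)
        assert np.isnan(thr["thr_0.95"].iloc[0])

    def test_independent_linkage_mode_shrinks_thresholds(self):
        win = _window_frame([_win("chr1", 1, 100, 0.1, n_snps=20)])
        shared = NullConfig(bulk_size=50, n_reps=20_000, seed=9, linkage="complete")
        indep = NullConfig(bulk_size=50, n_reps=20_000, seed=9, linkage="independent")
        t_shared = threshold_for_windows(win, shared)["thr_0.999"].iloc[0]
        t_indep = threshold_for_windows(win, indep)["thr_0.999"].iloc[0]
        assert t_indep < t_shared


def _thr_frame(win, value=0.3, level="thr_0.999"):
    t = win[["chrom", "start", "end"]].copy()
    t[level] = value
    return t


class TestCallRegions:
    def test_reported_interval_size(self):
        region = CandidateRegion(
            chrom="chr8", start=3_555_000, end=4_520_000,
            peak_delta=0.6, peak_pos=4_000_000,
            mean_index_t=0.8, mean_index_s=0.2, n_windows=10,
        )
        assert region.size_mb == pytest.approx(0.965, abs=1e-12)

    def test_no_significant_windows_returns_empty(self):
        win = _window_frame([_win("chr1", 1, 100, 0.05)])
        assert call_regions(win, _thr_frame(win), step=50) == []

    def test_pool_index_criteria_gate_significance(self):
        win = _window_frame([_win("chr1", 1, 100, 0.5, t=0.6, s=0.1)])
        assert call_regions(win, _thr_frame(win), step=50) == []
        relaxed = RegionCriteria(apply_pool_criteria=False)
        assert len(call_regions(win, _thr_frame(win), relaxed, step=50)) == 1

    def test_gap_merging_bridges_one_inert_window(self):
        rows = [
            _win("chr1", 1, 100, 0.5),
            _win("chr1", 101, 200, 0.05),  # inert: below threshold
            _win("chr1", 201, 300, 0.6),
        ]
        win = _window_frame(rows)
        merged = call_regions(win, _thr_frame(win), step=100)  # gap_max = 200
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (1, 300)
        assert merged[0].peak_delta == pytest.approx(0.6)
        assert merged[0].peak_pos == 250
        # a tighter gap limit splits the block
        tight = call_regions(
            win, _thr_frame(win), RegionCriteria(gap_max=50), step=100
        )
        assert [(r.start, r.end) for r in tight] == [(1, 100), (201, 300)]

    def test_merging_is_order_invariant_and_idempotent(self):
        rows = [
            _win("chr2", 1, 100, 0.4),
            _win("chr1", 201, 300, 0.6),
            _win("chr1", 1, 100, 0.5),
            _win("chr1", 151, 250, 0.45),
        ]
        win = _window_frame(rows)
        shuffled = win.sample(frac=1, random_state=0)
        a = call_regions(win, _thr_frame(win), step=100)
        b = call_regions(shuffled, _thr_frame(shuffled), step=100)
        assert a == b
        assert [(r.chrom, r.start, r.end) for r in a] == [
            ("chr1", 1, 300),
            ("chr2", 1, 100),
        ]

    def test_missing_threshold_column_is_an_error(self):
        win = _window_frame([_win("chr1", 1, 100, 0.5)])
        thr = _thr_frame(win, level="thr_0.95")
        with pytest.raises(ValueError, match="thr_0.999"):
            call_regions(win, thr, step=50)


class TestNullConfigValidation:
    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            NullConfig(n_reps=50)

    def test_warns_when_tail_quantile_underpowered(self):
        with pytest.warns(UserWarning, match="n_reps"):
            NullConfig(n_reps=1_000, confidence=(0.999,))
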