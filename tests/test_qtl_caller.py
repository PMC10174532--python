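"""Tests for binning, the likelihood-ratio LOD, and QTL calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import xlogy

import poolqtl as pq
from poolqtl import qtl_caller


def counts_df(pos, ref, alt, chrom="chrA"):
    return pd.DataFrame({"chrom": chrom, "pos": pos,
                         "ref_count": ref, "alt_count": alt})


class TestBinCounts:
    def test_markers_summed_within_bin(self):
        high = counts_df([50, 90], [1, 2], [3, 4])
        low = counts_df([50], [5], [5])
        b = qtl_caller.bin_counts(high, low, pq.LODParams(), {"chrA": 1000})
        assert b["chrA"]["k_high"][0] == 7
        assert b["chrA"]["n_high"][0] == 10

    def test_right_edge_inclusive(self):
        high = counts_df([100, 101], [0, 0], [3, 5])
        low = counts_df([100], [1], [1])
        b = qtl_caller.bin_counts(high, low, pq.LODParams(), {"chrA": 1000})
        assert b["chrA"]["k_high"][0] == 3   # bp 100 in the first bin
        assert b["chrA"]["k_high"][1] == 5   # bp 101 in the second

    def test_empty_chromosome_zero_bins(self):
        high = counts_df([50], [1], [1])
        low = counts_df([50], [1], [1])
        b = qtl_caller.bin_counts(high, low, pq.LODParams(),
                                  {"chrA": 1000, "chrB": 1000})
        assert b["chrB"]["n_high"].sum() == 0
        lod = qtl_caller.lod_track(b, pq.LODParams())
        assert np.all(lod.loc[lod["chrom"] == "chrB", "lod"] == 0)


class TestEffectiveCounts:
    def test_harmonic_formula(self):
        k, n = qtl_caller.effective_counts(500, 1000, 1000)
        assert (k, n) == (250.0, 500.0)

    def test_deep_sequencing_saturates_at_pool_size(self):
        _, n = qtl_caller.effective_counts(0, 1e12, 1000)
        assert n == pytest.approx(1000, rel=1e-9)

    def test_zero_depth(self):
        assert qtl_caller.effective_counts(0, 0, 1000) == (0.0, 0.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            qtl_caller.effective_counts(5, 3, 1000)

    def test_variance_matches_two_stage_sampling(self):
        # pool of N genomes, then n reads: frequency variance should match a
        # single binomial with n' = n N / (n + N) trials
        rng = np.random.default_rng(42)
        N, n, p, reps = 1000, 2000, 0.5, 200_000
        pool_af = rng.binomial(N, p, size=reps) / N
        reads = rng.binomial(n, pool_af) / n
        _, n_eff = qtl_caller.effective_counts(0, n, N)
        expected_var = p * (1 - p) / n_eff
        assert reads.var() == pytest.approx(expected_var, rel=0.05)


def brute_force_lod(k1, n1, k2, n2):
    """Independent oracle: two-stage grid maximization of both models."""
    def ll(k, n, p):
        return xlogy(k, p) + xlogy(n - k, 1.0 - p)

    def sup(fun):
        grid = np.linspace(0, 1, 1001)
        best = grid[np.argmax(fun(grid))]
        fine = np.clip(np.linspace(best - 1.5e-3, best + 1.5e-3, 3001), 0, 1)
        return np.max(fun(fine))

    causal = sup(lambda p: ll(k1, n1, p)) + sup(lambda p: ll(k2, n2, p))
    noncausal = sup(lambda p: ll(k1, n1, p) + ll(k2, n2, p))
    return (causal - noncausal) / np.log(10)


class TestLodBin:
    def test_equal_frequencies_zero(self):
        assert qtl_caller.lod_bin(10, 20, 25, 50) == 0.0
        assert qtl_caller.lod_bin(0, 0, 0, 0) == 0.0

    def test_matches_brute_force_example(self):
        lod = qtl_caller.lod_bin(18, 20, 2, 20)
        assert lod == pytest.approx(brute_force_lod(18, 20, 2, 20), abs=1e-6)

    def test_doubling_counts_increases_lod(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n1, n2 = rng.integers(2, 100, size=2)
            k1, k2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            if k1 * n2 == k2 * n1:     # equal MLE frequencies: LOD stays 0
                continue
            lod1 = qtl_caller.lod_bin(k1, n1, k2, n2)
            lod2 = qtl_caller.lod_bin(2 * k1, 2 * n1, 2 * k2, 2 * n2)
            assert lod2 > lod1

    @settings(derandomize=True, max_examples=200)
    @given(st.data())
    def test_pool_swap_symmetry_and_nonnegativity(self, data):
        # the likelihood ratio cannot favour the noncausal model, and cannot
        # depend on which pool is called "high"
        n1 = data.draw(st.integers(0, 80))
        n2 = data.draw(st.integers(0, 80))
        k1 = data.draw(st.integers(0, n1))
        k2 = data.draw(st.integers(0, n2))
        lod = float(qtl_caller.lod_bin(k1, n1, k2, n2))
        swapped = float(qtl_caller.lod_bin(k2, n2, k1, n1))
        assert lod >= 0 and np.isfinite(lod)
        assert lod == pytest.approx(swapped, abs=1e-9)

    def test_nonnegative_and_finite(self):
        rng = np.random.default_rng(8)
        n1, n2 = rng.integers(0, 60, size=(2, 500))
        k1 = rng.integers(0, n1 + 1)
        k2 = rng.integers(0, n2 + 1)
        lod = qtl_caller.lod_bin(k1, n1, k2, n2)
        assert np.all(lod >= 0) and np.all(np.isfinite(lod))


class TestLodTrack:
    def test_degenerate_kernel_recovers_per_bin_lod(self):
        rng = np.random.default_rng(9)
        params = pq.LODParams(kernel_sd_bp=0)
        n = rng.integers(10, 40, size=20)
        k = rng.integers(0, n + 1)
        binned = {"chrA": {"mid": (np.arange(20) + 0.5) * 100,
                           "k_high": k.astype(float), "n_high": n.astype(float),
                           "k_low": (n - k).astype(float), "n_low": n.astype(float)}}
        track = qtl_caller.lod_track(binned, params)
        k1, n1 = qtl_caller.effective_counts(k, n, params.n_eff)
        k2, n2 = qtl_caller.effective_counts(n - k, n, params.n_eff)
        np.testing.assert_allclose(track["lod"], qtl_caller.lod_bin(k1, n1, k2, n2))

    def test_equal_pools_score_zero(self):
        df = counts_df(np.arange(1, 100) * 100, np.full(99, 10), np.full(99, 10))
        b = qtl_caller.bin_counts(df, df.copy(), pq.LODParams(), {"chrA": 10_000})
        track = qtl_caller.lod_track(b, pq.LODParams())
        np.testing.assert_allclose(track["lod"], 0.0, atol=1e-12)


def lod_df(lod, chrom="chrA", bin_bp=100):
    pos = (np.arange(len(lod)) + 0.5) * bin_bp
    return pd.DataFrame({"chrom": chrom, "pos": pos, "lod": lod})


def daf_df(value, pos_max=20_000, chrom="chrA"):
    pos = np.linspace(100, pos_max, 50)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "delta_af": value})


class TestCallQtls:
    def test_triangular_profile_two_lod_interval(self):
        # LOD rises to 12 and falls; bounds sit where LOD first reaches 10
        lod = np.concatenate([np.linspace(0, 12, 25), np.linspace(12, 0, 25)[1:]])
        track = lod_df(lod)
        qtls = qtl_caller.call_qtls(track, daf_df(0.2), pq.LODParams(),
                                    {"chrA": 5_000})
        assert len(qtls) == 1
        q = qtls[0]
        assert q.lod == pytest.approx(12.0)
        assert track["lod"][track["pos"] == q.left].iloc[0] <= 10.0
        assert track["lod"][track["pos"] == q.right].iloc[0] <= 10.0
        # bounds are the nearest such bins around the peak
        inside = (track["pos"] > q.left) & (track["pos"] < q.right)
        assert np.all(track["lod"][inside] > 10.0)

    def test_flat_subthreshold_track_yields_nothing(self):
        qtls = qtl_caller.call_qtls(lod_df(np.full(200, 4.4)), daf_df(0.1),
                                    pq.LODParams(), {"chrA": 20_000})
        assert qtls == []

    def test_two_separated_runs_give_two_qtls(self):
        lod = np.zeros(200)
        lod[40:60] = 6.0
        lod[140:160] = 7.0
        qtls = qtl_caller.call_qtls(lod_df(lod), daf_df(-0.2), pq.LODParams(),
                                    {"chrA": 20_000})
        assert len(qtls) == 2
        assert all(q.afd < 0 for q in qtls)

    def test_interval_clipped_at_chromosome_ends(self):
        lod = np.full(100, 9.0)  # never drops 2 below the peak
        q = qtl_caller.call_qtls(lod_df(lod), daf_df(0.3), pq.LODParams(),
                                 {"chrA": 10_000})[0]
        assert q.left == 0.0 and q.right == 10_000.0


class TestConcordance:
    def make(self, chrom="chrA", peak=409_000.0, lod=28.0, afd=0.2):
        return pq.QTL(chromosome=chrom, peak_pos=peak, lod=lod, afd=afd,
                      left=peak - 20_000, right=peak + 20_000)

    def test_identical_lists_average_to_themselves(self):
        reps = [self.make(), self.make(chrom="chrB", afd=-0.1)]
        merged = pq.concordant_qtls(reps, [self.make(),
                                           self.make(chrom="chrB", afd=-0.1)])
        assert len(merged) == 2
        assert merged[0].peak_pos == 409_000.0 and merged[0].lod == 28.0

    def test_replicate_lods_averaged(self):
        merged = pq.concordant_qtls([self.make(lod=28.0)],
                                    [self.make(lod=29.48)])
        assert merged[0].lod == pytest.approx(28.74)

    def test_single_replicate_qtl_dropped(self):
        merged = pq.concordant_qtls([self.make()], [])
        assert merged == []

    def test_discordant_direction_dropped(self):
        merged = pq.concordant_qtls([self.make(afd=0.2)], [self.make(afd=-0.2)])
        assert merged == []

    def test_distant_peaks_not_paired(self):
        merged = pq.concordant_qtls([self.make(peak=100_000)],
                                    [self.make(peak=250_000)])
        assert merged == []


class TestLabelSwap:
    def test_swapping_pools_preserves_lod_and_flips_direction(self,
                                                              small_experiment,
                                                              desk_map):
        _, sim, per_rep, _ = small_experiment
        # reconstruct the first replicate's pools and swap the labels
        import poolqtl.pipeline as pipeline
        rs = np.random.SeedSequence(424242).spawn(2)[0]
        high, low = pipeline.simulate_replicate(desk_map, sim, rs)
        hc = pipeline._pool_counts(high, desk_map, "high", 1)
        lc = pipeline._pool_counts(low, desk_map, "low", 1)
        lod_fwd, daf_fwd, q_fwd = pq.qtl_scan(hc, lc, desk_map.chrom_lengths)
        lod_rev, daf_rev, q_rev = pq.qtl_scan(lc, hc, desk_map.chrom_lengths)
        np.testing.assert_allclose(lod_fwd["lod"], lod_rev["lod"], atol=1e-9)
        np.testing.assert_allclose(daf_fwd["delta_af"], -daf_rev["delta_af"],
                                   atol=1e-12)
        assert len(q_fwd) == len(q_rev)
        for a, b in zip(q_fwd, q_rev):
            assert a.peak_pos == b.peak_pos
            assert np.sign(a.afd) == -np.sign(b.afd)
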