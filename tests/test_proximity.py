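"""TSS-feature distances, window frequencies, permutation nulls, rank tests,
peak subtraction, and meta-profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from contactscape import (
    IntervalSet, SignalTrack, mann_whitney, meta_profile, nearest_distance,
    permutation_null, tissue_specific_peaks, window_frequency,
)

from _oracles import enumerate_mann_whitney, naive_nearest_distance


def gene_df(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand", "cls"])


class TestNearestDistance:
    def test_distance_to_nearest_occupied_base(self):
        feats = IntervalSet([("chr1", 880, 900), ("chr1", 1500, 1600)])
        genes = gene_df([("g", "chr1", 1000, "+", "up")])
        assert nearest_distance(genes, feats).iloc[0] == 101  # to end-1 = 899

    def test_tss_inside_interval_is_zero(self):
        feats = IntervalSet([("chr1", 900, 1100)])
        genes = gene_df([("g", "chr1", 1000, "+", "up")])
        assert nearest_distance(genes, feats).iloc[0] == 0

    def test_no_feature_on_chromosome_is_missing(self):
        feats = IntervalSet([("chr2", 0, 10)])
        genes = gene_df([("g", "chr1", 1000, "+", "up")])
        assert np.isnan(nearest_distance(genes, feats).iloc[0])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_iv = int(rng.integers(1, 200))
        ivs = []
        for _ in range(n_iv):
            s = int(rng.integers(0, 100_000))
            ivs.append(("chr1", s, s + int(rng.integers(1, 500))))
        feats = IntervalSet(ivs)
        tss = rng.integers(0, 100_000, size=int(rng.integers(1, 200)))
        genes = gene_df([(f"g{i}", "chr1", int(t), "+", "up") for i, t in enumerate(tss)])
        got = nearest_distance(genes, feats).to_numpy()
        want = [naive_nearest_distance(int(t), [(s, e) for _, s, e in ivs]) for t in tss]
        assert np.allclose(got, want)


class TestWindowFrequency:
    def make(self):
        # every up gene has a peak at its TSS; half of unchanged do
        rows, feats = [], []
        for i in range(10):
            rows.append((f"up{i}", "chr1", 10_000 + 100_000 * i, "+", "up"))
            feats.append(("chr1", 10_000 + 100_000 * i, 10_001 + 100_000 * i))
        for i in range(10):
            tss = 5_000_000 + 100_000 * i
            rows.append((f"un{i}", "chr1", tss, "+", "unchanged_expressed"))
            if i < 5:
                feats.append(("chr1", tss, tss + 1))
        return gene_df(rows), IntervalSet(feats)

    def test_relative_frequency_of_planted_fixture(self):
        genes, feats = self.make()
        out = window_frequency(genes, feats, windows=[10_000])
        by = out.set_index("cls")
        assert by.loc["unchanged_expressed", "RF"] == pytest.approx(1.0)
        assert by.loc["up", "RF"] == pytest.approx(2.0)

    def test_zero_window_counts_only_tss_overlap(self):
        genes, feats = self.make()
        out = window_frequency(genes, feats, windows=[0]).set_index("cls")
        assert out.loc["up", "F"] == pytest.approx(1.0)
        assert out.loc["unchanged_expressed", "F"] == pytest.approx(0.5)

    def test_empty_baseline_class_rejected(self):
        genes = gene_df([("g", "chr1", 100, "+", "up")])
        with pytest.raises(ValueError, match="baseline"):
            window_frequency(genes, IntervalSet([("chr1", 0, 10)]))

    def test_zero_baseline_frequency_gives_missing_rf(self, caplog):
        genes = gene_df([("u", "chr1", 1000, "+", "up"),
                         ("n", "chr2", 1000, "+", "unchanged_expressed")])
        feats = IntervalSet([("chr1", 1000, 1001)])
        with caplog.at_level("WARNING"):
            out = window_frequency(genes, feats, windows=[100]).set_index("cls")
        assert np.isnan(out.loc["up", "RF"])


class TestPermutationNull:
    def test_observed_at_null_median_gives_half_p(self):
        rng = np.random.default_rng(0)
        pool = pd.DataFrame({"v": rng.normal(size=500)})
        stat = lambda df: float(df["v"].mean())
        # a median-ish subset: draw one and use it as the observed class
        cls = pool.iloc[rng.choice(500, 40, replace=False)]
        res = permutation_null(stat, cls, pool, n_draws=5000, seed=1)
        mc_sd = 3 * np.sqrt(0.25 / 5000)
        assert abs(min(res.p_upper, res.p_lower) - 0.5) < 0.5  # sanity: in (0,1)
        assert res.p_upper + res.p_lower >= 1.0  # add-one overlap at the observed value

    def test_minimum_attainable_p(self):
        pool = pd.DataFrame({"v": np.arange(100.0)})
        cls = pool.iloc[:10]  # extreme low mean
        res = permutation_null(lambda df: float(df["v"].mean()), cls, pool,
                               n_draws=5000, seed=2)
        assert res.p_lower >= 1 / 5001
        assert res.p_lower == pytest.approx(1 / 5001, rel=0.2)

    def test_class_equal_to_pool_gives_p_one(self):
        pool = pd.DataFrame({"v": np.arange(20.0)})
        res = permutation_null(lambda df: float(df["v"].mean()), pool, pool,
                               n_draws=200, seed=3)
        assert res.p_upper == 1.0 and res.p_lower == 1.0

    def test_pool_smaller_than_class_rejected(self):
        pool = pd.DataFrame({"v": np.arange(5.0)})
        with pytest.raises(ValueError, match="larger than"):
            permutation_null(lambda df: 0.0, pd.DataFrame({"v": np.arange(6.0)}),
                             pool, n_draws=10, seed=0)

    def test_p_uniform_under_null(self):
        rng = np.random.default_rng(4)
        pool = pd.DataFrame({"v": rng.normal(size=400)})
        stat = lambda df: float(df["v"].mean())
        ps = []
        for rep in range(60):
            cls = pool.iloc[rng.choice(400, 30, replace=False)]
            ps.append(permutation_null(stat, cls, pool, n_draws=200,
                                       rng=rng).p_upper)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMannWhitney:
    def test_small_sample_exact_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n,m", [(1, 2), (2, 2), (3, 3), (4, 4), (2, 5), (5, 5), (3, 7)])
    def test_exact_branch_matches_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(5):
            pooled = rng.choice(1000, size=n + m, replace=False).astype(float)
            x, y = pooled[:n], pooled[n:]
            u, p = mann_whitney(x, y)
            u0, p0 = enumerate_mann_whitney(x, y)
            assert u == u0
            assert p == pytest.approx(p0, rel=1e-12)

    def test_exact_and_asymptotic_branches_agree(self):
        rng = np.random.default_rng(9)
        diffs = []
        for _ in range(100):
            pooled = rng.choice(10_000, size=14, replace=False).astype(float)
            x, y = pooled[:7], pooled[7:]
            _, p_exact = mann_whitney(x, y)  # 7+7 = 14 -> exact branch
            p_asym = stats.mannwhitneyu(x, y, method="asymptotic",
                                        use_continuity=True).pvalue
            diffs.append(abs(p_exact - p_asym))
        assert max(diffs) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestTissueSpecificPeaks:
    def test_overlapping_focal_intervals_removed(self):
        focal = IntervalSet([("chr1", 100, 200), ("chr1", 500, 600)], name="heart")
        others = [IntervalSet([("chr1", 150, 250)])]
        out = tissue_specific_peaks(focal, others)
        assert list(out) == [("chr1", 500, 600)]

    def test_no_others_keeps_everything(self):
        focal = IntervalSet([("chr1", 100, 200)])
        assert list(tissue_specific_peaks(focal, [])) == [("chr1", 100, 200)]

    def test_focal_subset_of_union_is_empty(self):
        focal = IntervalSet([("chr1", 100, 200)])
        others = [IntervalSet([("chr1", 0, 150)]), IntervalSet([("chr1", 140, 300)])]
        assert len(tissue_specific_peaks(focal, others)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_output_disjoint_from_merged_union(self, seed):
        rng = np.random.default_rng(seed)
        def random_set(n):
            return IntervalSet([
                ("chr1", int(s), int(s) + int(rng.integers(1, 300)))
                for s in rng.integers(0, 50_000, size=n)
            ])
        focal = random_set(100)
        others = [random_set(80), random_set(80)]
        out = tissue_specific_peaks(focal, others)
        union = IntervalSet([iv for s in others for iv in s]).merged()
        for chrom, start, end in out:
            assert not union.overlaps_any(chrom, start, end)


class TestMetaProfile:
    def g(self, gene, chrom, tss, strand, cls="up"):
        return (gene, chrom, tss, strand, cls)

    def test_constant_track_gives_flat_zero(self):
        genes = gene_df([self.g("a", "chr1", 5000, "+"),
                         self.g("b", "chr1", 9000, "-")])
        track = SignalTrack([("chr1", 0, 20_000, 3.5)])
        prof = meta_profile(genes, track)
        assert np.allclose(prof.profiles["up"], 0.0)

    def test_delta_spike_at_tss_centers_regardless_of_strand(self):
        for strand in "+-":
            genes = gene_df([self.g("a", "chr1", 5000, strand)])
            track = SignalTrack([("chr1", 0, 4990, 0.0), ("chr1", 4990, 5010, 10.0),
                                 ("chr1", 5010, 20_000, 0.0)])
            prof = meta_profile(genes, track, smooth_bins=1)
            peak_positions = prof.positions[prof.matrix[0] == prof.matrix[0].max()]
            assert np.all(np.abs(peak_positions) <= 10)

    def test_per_chromosome_standardization_removes_baselines(self):
        # identical shapes on two chromosomes with different baselines
        genes = gene_df([self.g("a", "chr1", 5000, "+"),
                         self.g("b", "chr2", 5000, "+")])
        segs = []
        for chrom, base in (("chr1", 0.0), ("chr2", 100.0)):
            segs += [(chrom, 0, 4990, base), (chrom, 4990, 5010, base + 5.0),
                     (chrom, 5010, 20_000, base)]
        prof = meta_profile(genes, SignalTrack(segs), smooth_bins=1)
        assert np.allclose(prof.matrix[0], prof.matrix[1], atol=1e-12)

    def test_invariant_to_adding_per_chromosome_constant(self):
        rng = np.random.default_rng(6)
        genes = gene_df([self.g(f"g{i}", "chr1", int(t), "+")
                         for i, t in enumerate(rng.integers(3000, 50_000, 5))])
        segs = [("chr1", i * 100, (i + 1) * 100, float(v))
                for i, v in enumerate(rng.random(600))]
        track = SignalTrack(segs)
        p1 = meta_profile(genes, track)
        p2 = meta_profile(genes, track.shifted({"chr1": 42.0}))
        assert np.allclose(p1.profiles["up"], p2.profiles["up"], atol=1e-9)

    def test_vector_length_and_positions(self):
        genes = gene_df([self.g("a", "chr1", 5000, "+")])
        prof = meta_profile(genes, SignalTrack([("chr1", 0, 10_000, 1.0)]),
                            half_width=2000, bin_width=10)
        assert prof.matrix.shape == (1, 400)
        assert prof.positions[0] == -1995.0 and prof.positions[-1] == 1995.0
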