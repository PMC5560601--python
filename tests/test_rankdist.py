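import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pcsig.diffexpr import Contrast, DEResult
from pcsig.rankdist import (BinProfile, average_bin_profiles, bin_counts,
                            chi2_uniform, expression_rank_profile,
                            percentile_fraction, rank_by_expression,
                            rank_by_statistic)
from tests.conftest import make_design


def _de_from_t(t_values: dict[str, float]) -> DEResult:
    genes = list(t_values)
    table = pd.DataFrame({
        "log2FC": list(t_values.values()), "s2": 0.1,
        "t": list(t_values.values()), "p": 0.5, "adj_p": 0.5,
        "direction": "up", "significant": False,
    }, index=pd.Index(genes, name="gene_symbol"))
    return DEResult(Contrast.of("A", "B"), table, 4.0, 0.1, 8.0)


class TestRanking:
    def test_descending_for_up(self):
        ranked = rank_by_statistic(_de_from_t({"a": 3.0, "b": -1.0}), "t", "up")
        assert ranked.genes == ("a", "b")

    def test_direction_reverses_order(self):
        de = _de_from_t({"a": 3.0, "b": -1.0, "c": 0.5})
        up = rank_by_statistic(de, "t", "up")
        down = rank_by_statistic(de, "t", "down")
        assert up.genes == tuple(reversed(down.genes))

    def test_matches_independent_sort(self, rng):
        t = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=100))}
        ranked = rank_by_statistic(_de_from_t(t), "t", "up")
        oracle = tuple(sorted(t, key=lambda g: (-t[g], g)))
        assert ranked.genes == oracle

    def test_ties_break_lexicographically(self):
        ranked = rank_by_statistic(_de_from_t({"b": 1.0, "a": 1.0}), "t", "up")
        assert ranked.genes == ("a", "b")

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            rank_by_statistic(_de_from_t({"a": 1.0}), "nonsense", "up")


class TestBinCounts:
    def test_empty_geneset_zero_counts(self):
        ranked = rank_by_statistic(
            _de_from_t({f"g{i}": float(i) for i in range(20)}), "t", "up")
        profile = bin_counts(ranked, set(), bin_size=5)
        assert profile.counts == (0.0,) * 4

    def test_first_bin_captures_top_genes(self):
        t = {f"g{i:03d}": float(100 - i) for i in range(100)}
        ranked = rank_by_statistic(_de_from_t(t), "t", "up")
        top = set(ranked.genes[:10])
        profile = bin_counts(ranked, top, bin_size=10)
        assert profile.counts[0] == 10 and sum(profile.counts) == 10

    def test_truncate_drops_remainder(self):
        t = {f"g{i:02d}": float(i) for i in range(23)}
        ranked = rank_by_statistic(_de_from_t(t), "t", "up")
        profile = bin_counts(ranked, set(t), bin_size=5, remainder="truncate")
        assert profile.n_bins == 4 and profile.universe_size == 20

    def test_last_bin_keeps_remainder(self):
        t = {f"g{i:02d}": float(i) for i in range(23)}
        ranked = rank_by_statistic(_de_from_t(t), "t", "up")
        profile = bin_counts(ranked, set(t), bin_size=5, remainder="last-bin")
        assert profile.bin_lengths == (5, 5, 5, 5, 3)
        assert sum(profile.counts) == 23

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 10), st.integers(10, 80))
    def test_counts_conserve_intersection(self, seed, bin_size, n_genes):
        rng = np.random.default_rng(seed)
        t = {f"g{i:03d}": float(v)
             for i, v in enumerate(rng.normal(size=n_genes))}
        ranked = rank_by_statistic(_de_from_t(t), "t", "up")
        members = set(rng.choice(sorted(t), size=n_genes // 2, replace=False))
        profile = bin_counts(ranked, members, bin_size=bin_size)
        in_universe = set(ranked.genes[: profile.universe_size]) & members
        assert sum(profile.counts) == len(in_universe)


class TestAverageProfiles:
    def _profile(self, counts):
        return BinProfile(tuple(float(c) for c in counts), 5,
                          5 * len(counts), int(sum(counts)),
                          tuple([5] * len(counts)))

    def test_identical_profiles_sem_zero(self):
        p = self._profile([1, 3, 2])
        mean, sem = average_bin_profiles([p, p, p])
        assert mean.counts == p.counts
        assert np.allclose(sem, 0.0)

    def test_mean_of_two(self):
        mean, _ = average_bin_profiles([self._profile([1, 3]),
                                        self._profile([3, 1])])
        assert mean.counts == (2.0, 2.0)

    def test_matches_arithmetic_oracle(self, rng):
        arrays = [rng.integers(0, 10, 6) for _ in range(3)]
        mean, sem = average_bin_profiles([self._profile(a) for a in arrays])
        stacked = np.array(arrays, dtype=float)
        assert np.allclose(mean.counts, stacked.mean(axis=0))
        assert np.allclose(sem, stacked.std(axis=0, ddof=1) / np.sqrt(3))

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            average_bin_profiles([self._profile([1, 2]),
                                  self._profile([1, 2, 3])])


class TestChi2Uniform:
    def test_uniform_counts_give_zero(self):
        res = chi2_uniform(BinProfile((4.0,) * 5, 10, 50, 20, (10,) * 5))
        assert res.chi2 == 0.0 and res.p == pytest.approx(1.0)

    def test_df_is_bins_minus_one(self):
        res = chi2_uniform(BinProfile((1.0,) * 42, 551, 42 * 551, 42,
                                      (551,) * 42))
        assert res.df == 41

    def test_hand_computed_statistic(self):
        # 10 members all in bin 1 of 5: expected 2 per bin,
        # chi2 = (10-2)^2/2 + 4*(0-2)^2/2 = 32 + 16 = 40
        res = chi2_uniform(BinProfile((10.0, 0, 0, 0, 0), 5, 25, 10, (5,) * 5))
        assert res.chi2 == pytest.approx(40.0)
        assert res.p == pytest.approx(stats.chi2.sf(40.0, 4))

    def test_unequal_last_bin_expected_proportional(self):
        # all 6 members in the short last bin (length 5 of 25 total)
        profile = BinProfile((0.0, 0.0, 6.0), 10, 25, 6, (10, 10, 5))
        res = chi2_uniform(profile)
        exp = np.array([2.4, 2.4, 1.2])
        assert res.chi2 == pytest.approx((((np.array([0, 0, 6]) - exp) ** 2)
                                          / exp).sum())

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            chi2_uniform(BinProfile((0.0, 0.0), 5, 10, 0, (5, 5)))

    def test_type_i_error_calibrated(self):
        """Uniform-null rejection rate at alpha=0.05 stays in [0.03, 0.07]
        (slightly conservative: without-replacement placement)."""
        rng = np.random.default_rng(42)
        n_univ, n_set, bs = 23142, 260, 551  # 42 bins, set is ~1% of universe
        n_bins = n_univ // bs
        rejected = 0
        n_sim = 2000
        for _ in range(n_sim):
            pos = rng.choice(n_univ, n_set, replace=False)
            counts = np.bincount(pos // bs, minlength=n_bins + 1)[:n_bins]
            in_bins = counts.sum()
            profile = BinProfile(tuple(counts.astype(float)), bs,
                                 n_bins * bs, int(in_bins),
                                 tuple([bs] * n_bins))
            rejected += chi2_uniform(profile).p < 0.05
        assert 0.03 <= rejected / n_sim <= 0.07


class TestExpressionProfiles:
    def test_top_expressed_set_lands_in_first_bin(self, rng):
        genes = [f"g{i:03d}" for i in range(100)]
        m = pd.DataFrame({"s1": np.arange(100, 0, -1, dtype=float),
                          "s2": np.arange(100, 0, -1, dtype=float)},
                         index=genes)
        design = make_design({"grp": 2})
        design.index = design["sample_id"] = ["s1", "s2"]
        profiles = expression_rank_profile(m, design, set(genes[:10]),
                                           n_bins=10)
        assert profiles["grp"].counts[0] == 10

    def test_identical_studies_sd_zero(self, rng):
        from pcsig.rankdist import merge_profiles_across_studies
        genes = [f"g{i:03d}" for i in range(60)]
        m = pd.DataFrame(rng.normal(8, 1, (60, 3)), index=genes,
                         columns=["s1", "s2", "s3"])
        design = make_design({"grp": 3})
        design.index = design["sample_id"] = ["s1", "s2", "s3"]
        p = expression_rank_profile(m, design, set(genes[:20]), n_bins=6)
        merged = merge_profiles_across_studies([p, p])
        assert np.allclose(merged["grp"][1], 0.0)

    def test_uniform_geneset_rarely_rejected(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i:04d}" for i in range(1000)]
        design = make_design({"grp": 2})
        rejections = 0
        for _ in range(50):
            m = pd.DataFrame(rng.normal(8, 1, (1000, 2)), index=genes,
                             columns=design.index)
            members = set(rng.choice(genes, 200, replace=False))
            profiles = expression_rank_profile(m, design, members, n_bins=20)
            rejections += chi2_uniform(profiles["grp"]).p < 0.05
        assert rejections / 50 <= 0.10


class TestPercentileFraction:
    def test_whole_universe_fraction(self, rng):
        genes = [f"g{i}" for i in range(1000)]
        m = pd.DataFrame({"s": rng.normal(size=1000)}, index=genes)
        frac = percentile_fraction(m, set(genes), q=0.90)
        assert frac == pytest.approx(0.10, abs=0.005)

    def test_low_expression_set_is_zero(self):
        m = pd.DataFrame({"s": np.arange(100, dtype=float)},
                         index=[f"g{i}" for i in range(100)])
        assert percentile_fraction(m, {"g0", "g1", "g2"}, q=0.5) == 0.0

    def test_planted_high_expression_fraction(self, rng):
        """Planting 70% of a set above the 90th percentile reproduces a
        ~70% highly-expressed fraction."""
        n = 1000
        base = rng.normal(8, 1, n)
        genes = [f"g{i:04d}" for i in range(n)]
        m = pd.DataFrame({"s": base}, index=genes)
        cutoff = np.quantile(base, 0.90)
        high = [g for g, v in zip(genes, base) if v > cutoff]
        low = [g for g, v in zip(genes, base) if v <= cutoff]
        members = set(high[:70]) | set(low[:30])
        assert percentile_fraction(m, members, q=0.90) == pytest.approx(0.70)
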