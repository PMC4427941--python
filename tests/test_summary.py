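"""Methylation summaries: context levels, histograms, classes, profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cfmethylome.errors import ValidationError
from cfmethylome.io import RegionSet
from cfmethylome.summary import (classify_sites, context_methylation,
                                 group_correlation, group_mean_levels,
                                 histogram_1pct, region_profile)

from conftest import build_methylome


def levels_series(pairs):
    """pairs: ((chrom, pos), level) items -> indexed Series."""
    idx = pd.MultiIndex.from_tuples([k for k, _ in pairs],
                                    names=["chrom", "pos"])
    return pd.Series([v for _, v in pairs], index=idx, name="level")


class TestContextMethylation:
    def test_single_cpg_call(self):
        m = build_methylome([("chr1", 10, "+", "CpG", 8, 2)])
        out = context_methylation(m)
        assert out["CpG"] == pytest.approx(0.8)
        assert math.isnan(out["CHG"]) and math.isnan(out["CHH"])

    def test_pooled_counts_not_mean_of_fractions(self):
        # one deep, one shallow site: pooled 10+0 meth of 20 reads = 0.5
        m = build_methylome([("chr1", 10, "+", "CpG", 10, 0),
                             ("chr1", 20, "+", "CpG", 0, 10)])
        assert context_methylation(m)["CpG"] == pytest.approx(0.5)

    def test_simulated_global_levels_recovered(self):
        rng = np.random.default_rng(0)
        n = 5000
        cov = rng.poisson(15, 2 * n) + 1
        meth_cpg = rng.binomial(cov[:n], 0.75)
        meth_chh = rng.binomial(cov[n:], 0.002)
        rows = [("chr1", 2 * i, "+", "CpG", m, c - m)
                for i, (m, c) in enumerate(zip(meth_cpg, cov[:n]))]
        rows += [("chr2", 2 * i, "+", "CHH", m, c - m)
                 for i, (m, c) in enumerate(zip(meth_chh, cov[n:]))]
        out = context_methylation(build_methylome(rows))
        assert out["CpG"] == pytest.approx(0.75, abs=0.01)
        assert out["CHH"] == pytest.approx(0.002, abs=0.002)


class TestGroupMeanLevels:
    def test_unweighted_mean_of_fractions(self):
        a = build_methylome([("chr1", 10, "+", "CpG", 2, 8)])    # 0.2
        b = build_methylome([("chr1", 10, "+", "CpG", 40, 60)])  # 0.4
        out = group_mean_levels([a, b])
        assert out.loc[("chr1", 10)] == pytest.approx(0.3)

    def test_min_samples_threshold_excludes_sites(self):
        a = build_methylome([("chr1", 10, "+", "CpG", 2, 8),
                             ("chr1", 20, "+", "CpG", 1, 1)])
        b = build_methylome([("chr1", 10, "+", "CpG", 4, 6)])
        out = group_mean_levels([a, b], min_samples=2)
        assert ("chr1", 20) not in out.index and ("chr1", 10) in out.index

    def test_matches_bruteforce_mean(self):
        rng = np.random.default_rng(1)
        samples = []
        for s in range(4):
            cov = rng.poisson(10, 1000) + 1
            meth = rng.binomial(cov, 0.5)
            samples.append(build_methylome(
                [("chr1", i * 2, "+", "CpG", m, c - m)
                 for i, (m, c) in enumerate(zip(meth, cov))]))
        out = group_mean_levels(samples)
        brute = {}
        for i in range(1000):
            vals = [s.levels().loc[("chr1", i * 2)] for s in samples]
            brute[("chr1", i * 2)] = np.mean(vals)
        for key, v in brute.items():
            assert abs(out.loc[key] - v) < 1e-12

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            group_mean_levels([])


class TestClassify:
    def test_equal_thirds(self):
        out = classify_sites([0.1, 0.5, 0.9])
        assert out == pytest.approx(
            {"low": 1 / 3, "intermediate": 1 / 3, "high": 1 / 3})

    @pytest.mark.parametrize("level,cls", [
        (0.20, "intermediate"), (0.75, "intermediate"),
        (0.199, "low"), (0.751, "high")])
    def test_boundaries_closed_intermediate(self, level, cls):
        out = classify_sites([level])
        assert out[cls] == 1.0

    def test_bad_cuts_rejected(self):
        with pytest.raises(ValidationError):
            classify_sites([0.5], low_cut=0.8, high_cut=0.2)

    def test_bimodal_mixture_weights_recovered(self):
        rng = np.random.default_rng(2)
        comp = rng.choice(3, size=20_000, p=[0.1, 0.2, 0.7])
        levels = np.choose(comp, [rng.beta(1, 19, 20_000),
                                  rng.beta(8, 8, 20_000),
                                  rng.beta(18, 2, 20_000)])
        out = classify_sites(levels)
        # component tails straddle the cuts, so tolerances are loose
        assert out["low"] == pytest.approx(0.1, abs=0.04)
        assert out["high"] == pytest.approx(0.7, abs=0.06)


class TestHistogram:
    def test_all_mass_in_one_bin(self):
        h = histogram_1pct([0.505])
        assert h.proportions[50] == 1.0 and h.n_sites == 1

    def test_level_one_goes_to_last_bin(self):
        h = histogram_1pct([0.0, 1.0])
        assert h.proportions[0] == 0.5 and h.proportions[99] == 0.5

    def test_uniform_levels_fill_bins_evenly(self):
        rng = np.random.default_rng(3)
        h = histogram_1pct(rng.random(10_000))
        sigma = math.sqrt(0.01 * 0.99 / 10_000)
        assert np.abs(h.proportions - 0.01).max() < 4 * sigma
        assert h.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            histogram_1pct([])


class TestRegionProfile:
    def _levels(self, n=100, inside_level=0.1, outside_level=0.8):
        pairs = []
        for i in range(n):
            pos = i * 10
            base = inside_level if pos < 200 else outside_level
            pairs.append((("chr1", pos), base + 0.0001 * i))
        return levels_series(pairs)

    def test_matched_sample_sizes_and_disjoint(self):
        lv = self._levels()
        regions = RegionSet.from_intervals("r", [("chr1", 0, 200)])
        out = region_profile(lv, regions, seed=0)
        assert len(out["unenriched"]) == len(out["enriched"]) == 20
        assert out["enriched"].mean() < out["unenriched"].mean()

    def test_seed_reproducible(self):
        lv = self._levels()
        regions = RegionSet.from_intervals("r", [("chr1", 0, 200)])
        a = region_profile(lv, regions, seed=5)
        b = region_profile(lv, regions, seed=5)
        assert np.array_equal(a["unenriched"], b["unenriched"])
        c = region_profile(lv, regions, seed=6)
        assert not np.array_equal(a["unenriched"], c["unenriched"])

    def test_whole_genome_region_rejected(self):
        lv = self._levels()
        regions = RegionSet.from_intervals("r", [("chr1", 0, 10_000)])
        with pytest.raises(ValidationError):
            region_profile(lv, regions, seed=0)

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValidationError):
            region_profile(self._levels(), RegionSet("empty"), seed=0)


class TestCorrelation:
    def test_identity_and_antisymmetry(self):
        a = levels_series([(("chr1", i), v) for i, v in
                           enumerate([0.1, 0.4, 0.9, 0.3])])
        assert group_correlation(a, a) == pytest.approx(1.0)
        assert group_correlation(a, 1 - a) == pytest.approx(-1.0)

    def test_matches_scipy_on_shared_sites(self):
        rng = np.random.default_rng(4)
        x, y = rng.random(1000), rng.random(1000)
        a = levels_series([(("chr1", i), v) for i, v in enumerate(x)])
        # offset positions so only 500 sites are shared
        b = levels_series([(("chr1", i + 500), v) for i, v in enumerate(y)])
        expected = stats.pearsonr(x[500:], y[:500]).statistic
        assert group_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_undefined(self):
        a = levels_series([(("chr1", 0), 0.5), (("chr1", 1), 0.5)])
        b = levels_series([(("chr1", 0), 0.1), (("chr1", 1), 0.9)])
        assert math.isnan(group_correlation(a, b))
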