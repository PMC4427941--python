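"""DMR calling: site statistics, Welch t, filtering, grouping, annotation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cfmethylome.dmr import (DMR, annotate_dmrs, call_dmrs, dmr_overlap,
                             filter_sites, group_site_stats, partition_genic,
                             site_t)
from cfmethylome.errors import ValidationError
from cfmethylome.io import RegionSet

from conftest import build_methylome


def stats_frame(rows):
    """rows: (chrom, pos, n, mean, sd)."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "n", "mean", "sd"])


def tstat_frame(rows):
    """rows: (chrom, pos, t, diff)."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "t", "diff"])


def brute_force_dmrs(tstats, t_min=5.0, max_gap=300, min_cpg=9, same_sign=True):
    """Literal sequential application of the calling rules."""
    surviving = [r for r in tstats.itertuples(index=False) if abs(r.t) >= t_min]
    groups, current = [], []
    for row in surviving:
        if current:
            prev = current[-1]
            ok = (row.chrom == prev.chrom and (row.pos - prev.pos) < max_gap
                  and (not same_sign or np.sign(row.diff) == np.sign(prev.diff)))
            if not ok:
                groups.append(current)
                current = []
        current.append(row)
    if current:
        groups.append(current)
    return [g for g in groups if len(g) >= min_cpg]


class TestGroupSiteStats:
    def test_constant_levels(self):
        samples = [build_methylome([("chr1", 10, "+", "CpG", 5, 5)])
                   for _ in range(3)]
        out = group_site_stats(samples)
        assert out.iloc[0]["mean"] == 0.5 and out.iloc[0]["sd"] == 0.0

    def test_closed_form_sd(self):
        samples = [build_methylome([("chr1", 10, "+", "CpG", 0, 10)]),
                   build_methylome([("chr1", 10, "+", "CpG", 10, 0)])]
        out = group_site_stats(samples)
        assert out.iloc[0]["sd"] == pytest.approx(math.sqrt(0.5), abs=1e-12)

    def test_min_samples_and_coverage_thresholds(self):
        samples = [build_methylome([("chr1", 10, "+", "CpG", 5, 5),
                                    ("chr1", 20, "+", "CpG", 1, 0)]),
                   build_methylome([("chr1", 10, "+", "CpG", 5, 5)])]
        out = group_site_stats(samples, min_coverage=2, min_samples=2)
        assert list(out["pos"]) == [10]

    def test_group_of_one_rejected(self):
        with pytest.raises(ValidationError):
            group_site_stats([build_methylome([("chr1", 10, "+", "CpG", 1, 1)])])


class TestSiteT:
    def test_hand_evaluated_welch_value(self):
        a = stats_frame([("chr1", 10, 5, 0.9, 0.05)])
        b = stats_frame([("chr1", 10, 5, 0.1, 0.05)])
        out = site_t(a, b)
        expected = 0.8 / math.sqrt(2 * 0.05 ** 2 / 5)
        assert out.iloc[0]["t"] == pytest.approx(expected, abs=1e-9)
        assert out.iloc[0]["t"] == pytest.approx(25.298, abs=1e-3)

    def test_identical_groups_give_zero(self):
        a = stats_frame([("chr1", 10, 4, 0.5, 0.1)])
        assert site_t(a, a).iloc[0]["t"] == 0.0

    def test_degenerate_variance_sentinel(self):
        a = stats_frame([("chr1", 10, 4, 0.8, 0.0)])
        b = stats_frame([("chr1", 10, 4, 0.5, 0.0)])
        out = site_t(a, b)
        assert out.iloc[0]["t"] == math.inf
        assert len(filter_sites(out, t_min=5.0)) == 1

    def test_missing_site_skipped(self):
        a = stats_frame([("chr1", 10, 4, 0.5, 0.1), ("chr1", 20, 4, 0.5, 0.1)])
        b = stats_frame([("chr1", 10, 4, 0.4, 0.1)])
        assert list(site_t(a, b)["pos"]) == [10]

    def test_swap_flips_every_sign(self):
        rng = np.random.default_rng(0)
        n = 200
        a = stats_frame([("chr1", i, 5, m, s) for i, (m, s) in
                         enumerate(zip(rng.random(n), rng.random(n) * 0.2))])
        b = stats_frame([("chr1", i, 7, m, s) for i, (m, s) in
                         enumerate(zip(rng.random(n), rng.random(n) * 0.2))])
        ab, ba = site_t(a, b), site_t(b, a)
        np.testing.assert_allclose(ab["t"], -ba["t"], atol=1e-14)


class TestFilter:
    @pytest.mark.parametrize("t,kept", [(4.999, False), (5.0, True),
                                        (-5.0, True), (-4.999, False)])
    def test_strict_boundary(self, t, kept):
        out = filter_sites(tstat_frame([("chr1", 10, t, 0.1 * np.sign(t))]))
        assert (len(out) == 1) is kept


class TestCallDmrs:
    def test_nine_close_sites_one_dmr(self):
        rows = [("chr1", 100 + 50 * i, 6.0, 0.3) for i in range(9)]
        dmrs = call_dmrs(tstat_frame(rows))
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.n_cpg == 9 and d.direction == "hyper_in_A"
        assert d.start == 100 and d.end == 502

    def test_eight_sites_no_dmr(self):
        rows = [("chr1", 100 + 50 * i, 6.0, 0.3) for i in range(8)]
        assert call_dmrs(tstat_frame(rows)) == []

    def test_gap_of_exactly_max_gap_splits(self):
        rows = ([("chr1", 100 + 30 * i, 6.0, 0.3) for i in range(9)]
                + [("chr1", 100 + 30 * 8 + 300 + 30 * i, 6.0, 0.3)
                   for i in range(9)])
        dmrs = call_dmrs(tstat_frame(rows))
        assert len(dmrs) == 2

    def test_sign_change_closes_group(self):
        rows = ([("chr1", 100 + 30 * i, 6.0, 0.3) for i in range(9)]
                + [("chr1", 400 + 30 * i, -6.0, -0.3) for i in range(9)])
        dmrs = call_dmrs(tstat_frame(rows))
        assert [d.direction for d in dmrs] == ["hyper_in_A", "hyper_in_B"]

    def test_unsorted_input_rejected(self):
        rows = [("chr1", 200, 6.0, 0.3), ("chr1", 100, 6.0, 0.3)]
        with pytest.raises(ValidationError):
            call_dmrs(tstat_frame(rows))

    def test_invariants_hold_on_random_instance(self):
        tstats = random_instance(np.random.default_rng(3), n=200)
        for d in call_dmrs(filter_sites(tstats)):
            gaps = np.diff(d.member_positions)
            assert d.n_cpg >= 9 and (gaps < 300).all()
            members = tstats.set_index("pos").loc[list(d.member_positions)]
            assert (np.abs(members["t"]) >= 5).all()
            assert len(set(np.sign(members["diff"]))) == 1


def random_instance(rng, n=200):
    """A random single-chromosome site pattern with clustered positions."""
    gaps = rng.choice([10, 40, 100, 290, 300, 400, 2000], size=n,
                      p=[0.3, 0.25, 0.2, 0.05, 0.05, 0.05, 0.1])
    pos = 100 + np.cumsum(gaps)
    t = rng.normal(0, 6, size=n)
    big = rng.random(n) < 0.03
    t[big] = np.sign(rng.random(n) - 0.5)[big] * np.inf
    diff = np.sign(t) * rng.uniform(0.05, 0.6, size=n)
    return tstat_frame(list(zip(["chr1"] * n, pos, t, diff)))


class TestBruteForceEquivalence:
    def test_small_instances_match_enumerator(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            tstats = random_instance(rng, n=int(rng.integers(10, 200)))
            called = call_dmrs(filter_sites(tstats))
            expected = brute_force_dmrs(tstats)
            assert len(called) == len(expected)
            for d, grp in zip(called, expected):
                assert d.member_positions == tuple(r.pos for r in grp)
                assert d.direction == ("hyper_in_A" if grp[0].diff > 0
                                       else "hyper_in_B")


class TestAnnotation:
    def _dmrs(self, coords):
        return [DMR(c, s, e, 9, "hyper_in_A", 0.3, 6.0,
                    tuple(range(s, s + 9))) for c, s, e in coords]

    def test_overlap_and_half_open_touch(self):
        islands = RegionSet.from_intervals("cgi", [("chr1", 100, 200)])
        inside = self._dmrs([("chr1", 120, 150)])
        touching = self._dmrs([("chr1", 200, 250)])  # starts at island.end
        assert annotate_dmrs(inside, [islands])["cgi"] == 1.0
        assert annotate_dmrs(touching, [islands])["cgi"] == 0.0

    def test_fraction_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 100_000, size=100)
        dmrs = self._dmrs([("chr1", int(s), int(s) + 50) for s in starts])
        feats = RegionSet.from_intervals(
            "f", [("chr1", int(s), int(s + w)) for s, w in
                  zip(rng.integers(0, 100_000, 30), rng.integers(10, 5000, 30))])
        brute = np.mean([
            any(min(d.end, e) > max(d.start, s) for _, s, e in feats.intervals)
            for d in dmrs])
        assert annotate_dmrs(dmrs, [feats])["f"] == pytest.approx(brute)

    def test_genic_partition_sums_to_one(self):
        genes = RegionSet.from_intervals("genes", [("chr1", 0, 1000)])
        dmrs = self._dmrs([("chr1", 100, 200), ("chr1", 5000, 5100)])
        out = partition_genic(dmrs, genes)
        assert out["intragenic"] + out["intergenic"] == pytest.approx(1.0)
        assert out["intragenic"] == 0.5

    def test_dmr_overlap_identity_disjoint_and_bruteforce(self):
        a = self._dmrs([("chr1", 0, 100), ("chr1", 500, 600)])
        b = self._dmrs([("chr1", 90, 110)])
        assert dmr_overlap(a, a) == 1.0
        assert dmr_overlap(a, b) == 0.5
        assert dmr_overlap(b, a) == 1.0
        assert math.isnan(dmr_overlap([], a))
        assert dmr_overlap(a, []) == 0.0
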