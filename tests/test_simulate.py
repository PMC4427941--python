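"""Generator contracts: determinism, mixture identities, planted truths."""

import numpy as np
import pandas as pd
import pytest

from cfmethylome.errors import ValidationError
from cfmethylome.io import read_cytosine_report, write_cytosine_report
from cfmethylome.fragments import methylation_by_length
from cfmethylome.simulate import (FragmentModel, MCIpModel, PlantedDMR,
                                  PlantedPHD, SimulationConfig,
                                  simulate_fragments, simulate_mcip,
                                  simulate_methylomes)

SMALL = dict(genome=(("chr1", 1_500_000),), mean_spacing=800, n_samples=3,
             non_cpg_spacing=None)


class TestConfigValidation:
    def test_out_of_range_dmr_levels_rejected(self):
        with pytest.raises(ValidationError, match="0,1"):
            SimulationConfig(planted_dmrs=(
                PlantedDMR("chr1", 1000, effect=0.9, anchor_high=0.8),))

    def test_domain_deeper_than_mixture_mean_rejected(self):
        with pytest.raises(ValidationError, match="depth"):
            SimulationConfig(planted_phds=(
                PlantedPHD("chr1", 0, 2_000_000, depth=0.9),))

    def test_planted_feature_outside_genome_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            SimulationConfig(genome=(("chr1", 10_000),),
                             planted_dmrs=(PlantedDMR("chr1", 9_990),))

    def test_error_lists_all_violations(self):
        with pytest.raises(ValidationError) as err:
            SimulationConfig(genome=(("chr1", 10_000),),
                             fetal_fraction=1.5,
                             planted_dmrs=(PlantedDMR("chr2", 100),))
        assert "fetal_fraction" in str(err.value) and "outside" in str(err.value)


class TestDeterminism:
    def test_identical_config_identical_output(self, tmp_path):
        cfg = SimulationConfig(seed=9, **SMALL)
        out1, _ = simulate_methylomes(cfg, groups=("placenta",))
        out2, _ = simulate_methylomes(cfg, groups=("placenta",))
        for a, b in zip(out1["placenta"], out2["placenta"]):
            pd.testing.assert_frame_equal(a.calls, b.calls)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_cytosine_report(out1["placenta"][0], p1)
        write_cytosine_report(out2["placenta"][0], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        a, _ = simulate_methylomes(SimulationConfig(seed=1, **SMALL),
                                   groups=("placenta",))
        b, _ = simulate_methylomes(SimulationConfig(seed=2, **SMALL),
                                   groups=("placenta",))
        assert not a["placenta"][0].calls.equals(b["placenta"][0].calls)

    def test_emitted_files_parse_cleanly(self, tmp_path):
        cfg = SimulationConfig(seed=3, strand_split=True, **SMALL)
        out, _ = simulate_methylomes(cfg, groups=("buffy_coat",))
        p = tmp_path / "r.tsv"
        write_cytosine_report(out["buffy_coat"][0], p)
        back = read_cytosine_report(p)
        assert len(back) == len(out["buffy_coat"][0])
        assert set(back.calls["strand"]) == {"+", "-"}


class TestMixtureIdentities:
    def _global_mean(self, methylomes):
        levels = pd.concat([m.levels() for m in methylomes])
        return float(levels.mean())

    def test_zero_fetal_fraction_matches_blood(self):
        cfg = SimulationConfig(seed=4, fetal_fraction=0.0, **SMALL)
        out, _ = simulate_methylomes(
            cfg, groups=("non_pregnant_ccf", "pregnant_ccf"))
        delta = abs(self._global_mean(out["pregnant_ccf"])
                    - self._global_mean(out["non_pregnant_ccf"]))
        assert delta < 0.01

    def test_unit_fetal_fraction_matches_placenta(self):
        phds = (PlantedPHD("chr1", 0, 1_500_000, depth=0.25),)
        cfg = SimulationConfig(seed=4, fetal_fraction=1.0, planted_phds=phds,
                               **SMALL)
        out, _ = simulate_methylomes(cfg, groups=("placenta", "pregnant_ccf"))
        delta = abs(self._global_mean(out["pregnant_ccf"])
                    - self._global_mean(out["placenta"]))
        assert delta < 0.01

    def test_placental_hypomethylation_emerges_in_domains(self):
        phds = (PlantedPHD("chr1", 0, 1_500_000, depth=0.25),)
        cfg = SimulationConfig(seed=5, planted_phds=phds, **SMALL)
        out, truth = simulate_methylomes(
            cfg, groups=("non_pregnant_ccf", "placenta"))
        blood = self._global_mean(out["non_pregnant_ccf"])
        plac = self._global_mean(out["placenta"])
        assert blood - plac == pytest.approx(0.25, abs=0.03)
        expected = truth.site_levels["level_blood"].mean() - \
            truth.site_levels["level_placenta"].mean()
        assert blood - plac == pytest.approx(expected, abs=0.02)


class TestFragmentSimulation:
    def test_zero_coefficient_true_ratio_one(self):
        fm = FragmentModel(beta=0.0, n_fragments=5000)
        cfg = SimulationConfig(seed=6, fragment_model=fm)
        frags, truth = simulate_fragments(cfg)
        assert truth.fragment_ratios["CpG"] == pytest.approx(1.0)
        est = methylation_by_length(frags)["CpG"]
        assert est == pytest.approx(1.0, abs=0.25)

    def test_sheared_mode_ignores_coefficient(self):
        fm = FragmentModel(beta=5.0, n_fragments=5000)
        cfg = SimulationConfig(seed=7, fragment_model=fm)
        frags, truth = simulate_fragments(cfg, mode="sheared_genomic")
        assert truth.fragment_ratios["CpG"] == pytest.approx(1.0)
        est = methylation_by_length(frags)["CpG"]
        assert est == pytest.approx(1.0, abs=0.25)

    def test_modal_length_near_nucleosome_peak(self):
        from cfmethylome.fragments import length_histogram
        frags, _ = simulate_fragments(SimulationConfig(
            seed=12, fragment_model=FragmentModel(n_fragments=50_000)))
        _, modal = length_histogram(frags)
        # smooth mono-nucleosome peak: argmax of the 1-bp histogram carries
        # a few bp of multinomial jitter around 168
        assert abs(modal - 168) <= 3

    def test_calibration_hits_target_ratio(self):
        fm = FragmentModel().calibrated(5.0)
        assert fm.analytic_fold_ratio("CpG") == pytest.approx(5.0, abs=1e-6)

    def test_non_finite_coefficient_rejected(self):
        with pytest.raises(ValidationError, match="finite"):
            FragmentModel(beta=float("inf")).validate()

    def test_short_boost_regions_receive_short_fragments(self):
        from cfmethylome.io import RegionSet
        from cfmethylome.fragments import short_fragment_region_enrichment
        regions = RegionSet.from_intervals(
            "promoters", [("chr1", i * 1_000_000, i * 1_000_000 + 100_000)
                          for i in range(10)])
        cfg = SimulationConfig(
            seed=8, fragment_model=FragmentModel(n_fragments=20_000))
        frags, _ = simulate_fragments(
            cfg, region_short_boost=(regions, 0.5, 60, 15))
        out = short_fragment_region_enrichment(frags, {"promoters": regions})
        assert out["promoters"] > out["genome"]


class TestMcipSimulation:
    def _frags(self, seed, beta=None):
        fm = FragmentModel(n_fragments=8000)
        if beta is not None:
            fm = FragmentModel(n_fragments=8000, beta=beta)
        return simulate_fragments(SimulationConfig(seed=seed, fragment_model=fm))[0]

    def test_zero_slope_splits_at_random(self):
        frags = self._frags(9)
        unmeth, meth = simulate_mcip(frags, MCIpModel(intercept=0.0, slope=0.0),
                                     seed=1)
        frac = len(meth) / len(frags)
        assert frac == pytest.approx(0.5, abs=0.03)
        long_u = np.mean([f.length > 300 for f in unmeth])
        long_m = np.mean([f.length > 300 for f in meth])
        assert abs(long_u - long_m) < 0.02

    def test_partition_exhaustive_exclusive(self):
        frags = self._frags(10)
        unmeth, meth = simulate_mcip(frags, MCIpModel(), seed=2)
        assert len(unmeth) + len(meth) == len(frags)

    def test_all_unmethylated_low_intercept_empty_capture(self):
        frags, _ = simulate_fragments(SimulationConfig(
            seed=11, fragment_model=FragmentModel(
                n_fragments=2000, alpha={"CpG": -30.0, "CHG": -30.0,
                                         "CHH": -30.0})))
        unmeth, meth = simulate_mcip(frags, MCIpModel(intercept=-30.0, slope=1.0),
                                     seed=3)
        assert meth == []
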