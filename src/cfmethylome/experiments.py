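"""Self-contained validation experiments on synthetic data.

Each function simulates a study-like dataset with planted ground truth, runs
the corresponding analysis end to end, and returns the measured quantities.
The experiment definitions double as the package's reference study
conditions; problem sizes are chosen to finish in minutes on one CPU (the
methods note documents each design).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dmr as dmr_mod, fragments as frag_mod, phd as phd_mod
from . import summary as summary_mod, trisomy as trisomy_mod
from .simulate import (FragmentModel, MCIpModel, PlantedDMR, PlantedPHD,
                       SimulationConfig, TrisomyModel, simulate_fragments,
                       simulate_mcip, simulate_methylomes,
                       simulate_trisomy_cohort)

#: euploid reference-panel size for z-score calibration/power experiments;
#: large enough for a stable unscaled MAD (see methods note)
CALIBRATION_PANEL = 192


def _reciprocal_matches(a: pd.DataFrame, b: pd.DataFrame,
                        min_fraction: float = 0.5) -> np.ndarray:
    """For each interval of ``a``, does any interval of ``b`` overlap it by
    >= ``min_fraction`` of both lengths?"""
    out = np.zeros(len(a), dtype=bool)
    for i, (chrom, start, end) in enumerate(
            a[["chrom", "start", "end"]].itertuples(index=False)):
        sub = b[b["chrom"] == chrom]
        if not len(sub):
            continue
        ov = (np.minimum(end, sub["end"].to_numpy())
              - np.maximum(start, sub["start"].to_numpy())).clip(min=0)
        ok = ((ov >= min_fraction * (end - start))
              & (ov >= min_fraction * (sub["end"] - sub["start"]).to_numpy()))
        out[i] = bool(ok.any())
    return out


def _call_dmrs_between(methylomes, group_a, group_b, **params):
    stats_a = dmr_mod.group_site_stats(methylomes[group_a])
    stats_b = dmr_mod.group_site_stats(methylomes[group_b])
    tstats = dmr_mod.site_t(stats_a, stats_b)
    return dmr_mod.call_dmrs(dmr_mod.filter_sites(tstats), **params)


def dmr_recovery(seed: int, n_dmrs: int = 50, genome_bp: int = 20_000_000,
                 n_null_seeds: int = 20) -> dict:
    """Planted-DMR recovery: 6 v 6 cohort, 12-CpG DMRs with |effect| 0.4 at
    ~15x coverage, plus a matched null (no planted DMRs)."""
    rng = np.random.default_rng(seed)
    margin = 50_000
    starts = np.sort(rng.choice(
        np.arange(margin, genome_bp - margin, 1000), size=n_dmrs,
        replace=False))
    # mostly hypomethylated in placenta, mirroring the observed direction skew
    planted = tuple(
        PlantedDMR("chr1", int(s),
                   direction="hypo_in_target" if i % 10 else "hyper_in_target")
        for i, s in enumerate(starts))
    config = SimulationConfig(seed=seed, genome=(("chr1", genome_bp),),
                              planted_dmrs=planted, non_cpg_spacing=None)
    methylomes, truth = simulate_methylomes(
        config, groups=("non_pregnant_ccf", "placenta"))
    calls = _call_dmrs_between(methylomes, "non_pregnant_ccf", "placenta")
    called = dmr_mod.dmrs_to_frame(calls)
    sensitivity = float(_reciprocal_matches(truth.dmrs, called).mean())
    precision = float(_reciprocal_matches(called, truth.dmrs).mean()) \
        if len(called) else float("nan")
    hyper_in_ccf = float(np.mean([d.direction == "hyper_in_A" for d in calls]))

    null_zero = 0
    for k in range(n_null_seeds):
        null_cfg = SimulationConfig(seed=seed + 1000 + k,
                                    genome=(("chr1", genome_bp),),
                                    non_cpg_spacing=None)
        null_meth, _ = simulate_methylomes(
            null_cfg, groups=("non_pregnant_ccf", "placenta"))
        null_calls = _call_dmrs_between(null_meth, "non_pregnant_ccf",
                                        "placenta")
        null_zero += len(null_calls) == 0
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "n_called": len(called),
        "fraction_hyper_in_ccf": hyper_in_ccf,
        "null_zero_call_fraction": null_zero / n_null_seeds,
    }


def phd_recovery(seed: int, n_domains: int = 10, n_null_seeds: int = 20) -> dict:
    """Ten planted 2-Mbp hypomethylated domains (depth 0.25) in CpG-sparse
    regions of a two-chromosome genome, plus a matched null."""
    domains = tuple(
        PlantedPHD(f"chr{i % 2 + 1}", 3_000_000 * (i // 2) + 500_000,
                   3_000_000 * (i // 2) + 2_500_000, depth=0.25,
                   cpg_spacing=1250)
        for i in range(n_domains))
    genome = (("chr1", 16_000_000), ("chr2", 16_000_000))
    config = SimulationConfig(seed=seed, genome=genome, planted_phds=domains,
                              non_cpg_spacing=None)
    methylomes, truth = simulate_methylomes(
        config, groups=("non_pregnant_ccf", "placenta"))
    levels = {g: summary_mod.group_mean_levels(methylomes[g], min_samples=2)
              for g in methylomes}
    bins = phd_mod.bin_genome(levels, config.chrom_sizes())
    calls = phd_mod.call_phds(bins, "placenta", "non_pregnant_ccf")

    bin_size = 50_000
    boundary_errors = []
    for _, t in truth.phds.iterrows():
        matches = [c for c in calls if c.chrom == t["chrom"]
                   and min(c.end, t["end"]) - max(c.start, t["start"]) > 0]
        if len(matches) == 1:
            c = matches[0]
            boundary_errors.append(
                max(abs(c.start - t["start"]), abs(c.end - t["end"])) // bin_size)
        else:
            boundary_errors.append(np.inf)
    recovered = int(np.sum(np.array(boundary_errors) <= 2))

    null_calls = 0
    for k in range(n_null_seeds):
        null_cfg = SimulationConfig(seed=seed + 2000 + k,
                                    genome=(("chr1", 16_000_000),),
                                    non_cpg_spacing=None)
        null_meth, _ = simulate_methylomes(
            null_cfg, groups=("non_pregnant_ccf", "placenta"))
        null_levels = {g: summary_mod.group_mean_levels(null_meth[g],
                                                        min_samples=2)
                       for g in null_meth}
        null_bins = phd_mod.bin_genome(null_levels, null_cfg.chrom_sizes())
        null_calls += len(phd_mod.call_phds(null_bins, "placenta",
                                            "non_pregnant_ccf"))
    domain_target = float(np.mean([c.mean_meth_target for c in calls])) \
        if calls else float("nan")
    domain_reference = float(np.mean([c.mean_meth_reference for c in calls])) \
        if calls else float("nan")
    return {
        "n_planted": n_domains,
        "n_recovered": recovered,
        "max_boundary_error_bins": float(np.max(boundary_errors)),
        "null_calls_total": null_calls,
        "domain_target_mean": domain_target,
        "domain_reference_mean": domain_reference,
    }


def fragment_ratio(seed: int, target_ratio: float = 5.0,
                   n_fragments: int = 60_000) -> dict:
    """Recovery of a planted long/short methylation fold ratio (~1e5 CpG
    calls), plus the zero-coefficient and sheared-mode negative controls."""
    model = FragmentModel(n_fragments=n_fragments).calibrated(target_ratio)
    config = SimulationConfig(seed=seed, fragment_model=model)
    frags, truth = simulate_fragments(config, mode="wgbs_ccf")
    est = frag_mod.methylation_by_length(frags)
    n_calls = sum(1 for f in frags for c in f.calls if c.context == "CpG")
    _, modal = frag_mod.length_histogram(frags)

    null_model = FragmentModel(n_fragments=20_000, beta=0.0)
    null_frags, _ = simulate_fragments(
        SimulationConfig(seed=seed + 1, fragment_model=null_model))
    sheared_frags, _ = simulate_fragments(
        SimulationConfig(seed=seed + 2, fragment_model=FragmentModel(
            n_fragments=20_000)), mode="sheared_genomic")
    return {
        "true_ratio": truth.fragment_ratios["CpG"],
        "estimated_ratio": est["CpG"],
        "n_cpg_calls": n_calls,
        "modal_length": modal,
        "zero_coefficient_ratio": frag_mod.methylation_by_length(null_frags)["CpG"],
        "sheared_mode_ratio": frag_mod.methylation_by_length(sheared_frags)["CpG"],
    }


def mcip_fractionation(seed: int, n_seeds: int = 20,
                       n_fragments: int = 8000) -> dict:
    """Does the methylated MBD-capture fraction carry more >300 bp fragments
    whenever capture and length-methylation coefficients are positive?"""
    monotone = 0
    folds = []
    for k in range(n_seeds):
        config = SimulationConfig(
            seed=seed + k,
            fragment_model=FragmentModel(n_fragments=n_fragments))
        frags, _ = simulate_fragments(config)
        unmeth, meth = simulate_mcip(frags, MCIpModel(), seed=seed + 500 + k)
        summaries, fold = frag_mod.fraction_size_comparison(unmeth, meth)
        folds.append(fold)
        monotone += (summaries["methylated"].proportion_gt[300]
                     > summaries["unmethylated"].proportion_gt[300])
    return {
        "monotone_fraction": monotone / n_seeds,
        "mean_gt300_fold": float(np.nanmean(folds)),
    }


def trisomy_calibration_and_power(seed: int, n_cohorts: int = 100) -> dict:
    """Euploid-only false-positive calibration and trisomy power/fold.

    Uses a large euploid reference panel so the unscaled MAD is stable; the
    power arm plants 3 trisomies at fetal fraction 0.10, 1e6 region reads,
    4x enrichment.
    """
    fp = total = 0
    median_z_max = 0.0
    cal_model = TrisomyModel(n_euploid=CALIBRATION_PANEL, n_trisomy=0)
    for k in range(n_cohorts):
        cohort, _ = simulate_trisomy_cohort(cal_model, seed=seed + k)
        results = trisomy_mod.robust_z(cohort)
        z = np.array([r.z for r in results])
        fp += int((np.abs(z) > 3).sum())
        total += z.size
        for treatment in ("unenriched", "enriched"):
            zt = [r.z for r in results if r.treatment == treatment]
            median_z_max = max(median_z_max, abs(float(np.median(zt))))

    power_model = TrisomyModel(n_euploid=CALIBRATION_PANEL, n_trisomy=3,
                               fetal_fraction=0.10, enrichment_factor=4.0,
                               depth=1_000_000)
    detected = n_trisomy = 0
    folds = []
    for k in range(n_cohorts):
        cohort, _ = simulate_trisomy_cohort(power_model,
                                            seed=seed + 10_000 + k)
        results = trisomy_mod.robust_z(cohort)
        tri_ids = {r.sample_id for r in results if not r.euploid_known}
        for r in results:
            if r.sample_id in tri_ids and r.treatment == "enriched":
                n_trisomy += 1
                detected += r.z > 3
        _, summary = trisomy_mod.enrichment_fold(results, samples=sorted(tri_ids))
        folds.append(summary["mean_fold"])
    return {
        "euploid_fp_rate": fp / total,
        "euploid_median_z_max_abs": median_z_max,
        "power_z_gt3": detected / n_trisomy,
        "mean_z_fold": float(np.mean(folds)),
        "enrichment_implied_fold": 4.0,
    }


def mixture_recapitulation(seed: int,
                           fetal_fractions=(0.05, 0.10, 0.20)) -> dict:
    """Within planted placenta-hypomethylated DMRs, pregnant ccf methylation
    must sit strictly between the placenta and non-pregnant means and fall
    as the fetal fraction grows."""
    genome = (("chr1", 8_000_000),)
    planted = tuple(PlantedDMR("chr1", 100_000 + i * 190_000)
                    for i in range(40))

    def dmr_mean(methylomes, group, truth):
        levels = summary_mod.group_mean_levels(methylomes[group], min_samples=2)
        pos = levels.index.get_level_values("pos").to_numpy()
        member = np.zeros(pos.size, dtype=bool)
        for _, t in truth.dmrs.iterrows():
            member |= (pos >= t["start"]) & (pos < t["end"])
        return float(levels.to_numpy()[member].mean())

    base_cfg = SimulationConfig(seed=seed, genome=genome, planted_dmrs=planted,
                                non_cpg_spacing=None)
    ref_meth, truth = simulate_methylomes(
        base_cfg, groups=("non_pregnant_ccf", "placenta"))
    blood_mean = dmr_mean(ref_meth, "non_pregnant_ccf", truth)
    placenta_mean = dmr_mean(ref_meth, "placenta", truth)

    pregnant_means = {}
    for f in fetal_fractions:
        cfg = SimulationConfig(seed=seed, genome=genome, planted_dmrs=planted,
                               fetal_fraction=f, non_cpg_spacing=None)
        meth, _ = simulate_methylomes(cfg, groups=("pregnant_ccf",))
        pregnant_means[f] = dmr_mean(meth, "pregnant_ccf", truth)

    ordered = [pregnant_means[f] for f in sorted(pregnant_means)]
    return {
        "blood_mean": blood_mean,
        "placenta_mean": placenta_mean,
        "pregnant_means": pregnant_means,
        "strictly_between": all(placenta_mean < m < blood_mean
                                for m in ordered),
        "monotone_decreasing": all(a > b for a, b in zip(ordered, ordered[1:])),
    }


def summary_normalization(seed: int) -> dict:
    """Histogram/class normalization and seeded background reproducibility
    on a small simulated cohort."""
    from .io import RegionSet

    config = SimulationConfig(seed=seed, genome=(("chr1", 2_000_000),),
                              n_samples=4)
    methylomes, _ = simulate_methylomes(config, groups=("non_pregnant_ccf",))
    samples = methylomes["non_pregnant_ccf"]
    levels = summary_mod.group_mean_levels(samples, min_samples=2)
    hist = summary_mod.histogram_1pct(levels)
    classes = summary_mod.classify_sites(levels)
    regions = RegionSet.from_intervals("r", [("chr1", 0, 300_000)])
    prof_a = summary_mod.region_profile(levels, regions, seed=seed)
    prof_b = summary_mod.region_profile(levels, regions, seed=seed)
    return {
        "n_sites": hist.n_sites,
        "histogram_sum": float(hist.proportions.sum()),
        "class_sum": float(sum(classes.values())),
        "classes": classes,
        "global_cpg_methylation": float(
            summary_mod.context_methylation(samples[0])["CpG"]),
        "profile_sizes_match": len(prof_a["enriched"]) == len(prof_a["unenriched"]),
        "profile_reproducible": bool(
            np.array_equal(prof_a["unenriched"], prof_b["unenriched"])),
    }
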