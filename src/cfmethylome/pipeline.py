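"""End-to-end pipeline orchestration with a reproducible run manifest.

A run is driven by one YAML config (see ``demo_config()`` for the schema in
code form) and executes stages in dependency order::

    simulate -> summary -> dmr -> phd -> fragments -> zscore

Every stage writes plain-text outputs under the output directory and records
them (with SHA-256 checksums) in ``manifest.json``. Re-running with an
unchanged config skips stages whose outputs already exist, so two full runs
from the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, dmr as dmr_mod, fragments as frag_mod, phd as phd_mod
from . import summary as summary_mod, trisomy as trisomy_mod
from .errors import PipelineError, ValidationError
from .io import (RegionSet, read_cytosine_report, write_bed, write_bedgraph,
                 write_cytosine_report, write_fragments, read_fragments)
from .simulate import (MixtureModel, PlantedDMR, PlantedPHD, SimulationConfig,
                       simulate_fragments, simulate_mcip, simulate_methylomes,
                       simulate_trisomy_cohort)
from .trisomy import read_count_table, write_count_table

STAGES = ("simulate", "summary", "dmr", "phd", "fragments", "zscore")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], skipped: bool = False):
        self.stages[stage] = {
            "skipped": skipped,
            "outputs": {str(p): _sha256(p) for p in outputs},
        }

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash, "seed": self.seed,
            "version": self.version, "stages": self.stages,
        }, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    """Stable hash of the config mapping (key order irrelevant)."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def demo_config(seed: int = 0) -> dict:
    """A small self-contained demo configuration."""
    return {
        "seed": seed,
        "genome": {"chr1": 6_000_000, "chr2": 6_000_000},
        "mean_spacing": 600,
        "n_samples": 6,
        "coverage_mean": 15,
        "overdispersion": 200,
        "fetal_fraction": 0.10,
        "planted_dmrs": [
            {"chrom": "chr1", "start": 200_000 + i * 250_000,
             "direction": "hypo_in_target" if i % 5 else "hyper_in_target"}
            for i in range(12)
        ],
        "planted_phds": [
            {"chrom": "chr2", "start": 500_000, "end": 2_500_000,
             "depth": 0.25, "cpg_spacing": 1200},
        ],
        "dmr": {"group_a": "non_pregnant_ccf", "group_b": "placenta",
                "t_min": 5.0, "max_gap": 300, "min_cpg": 9,
                "min_coverage": 1, "min_samples": 2},
        "phd": {"target_group": "placenta", "reference_group": "non_pregnant_ccf",
                "bin_size": 50_000, "delta": 0.15, "min_run": 10,
                "min_cpg_per_bin": 10},
        "fragments": {"n_fragments": 20_000, "target_ratio": 5.0,
                      "cutoff": 200, "threshold": 300},
        "zscore": {"n_euploid": 9, "n_trisomy": 3, "fetal_fraction": 0.10,
                   "enrichment_factor": 4.0, "depth": 1_000_000},
    }


def _sim_config(config: dict) -> SimulationConfig:
    frag_opts = config.get("fragments", {})
    sim = SimulationConfig(
        seed=int(config.get("seed", 0)),
        genome=tuple(config.get("genome", {"chr1": 10_000_000}).items()),
        mean_spacing=float(config.get("mean_spacing", 500)),
        n_samples=int(config.get("n_samples", 6)),
        coverage_mean=float(config.get("coverage_mean", 15)),
        overdispersion=float(config.get("overdispersion", 200)),
        mixture=MixtureModel(**config.get("mixture", {})),
        planted_dmrs=tuple(PlantedDMR(**d) for d in config.get("planted_dmrs", [])),
        planted_phds=tuple(PlantedPHD(**p) for p in config.get("planted_phds", [])),
        fetal_fraction=float(config.get("fetal_fraction", 0.10)),
    )
    fm = sim.fragment_model
    if "n_fragments" in frag_opts:
        from dataclasses import replace
        fm = replace(fm, n_fragments=int(frag_opts["n_fragments"]))
    if "target_ratio" in frag_opts:
        fm = fm.calibrated(float(frag_opts["target_ratio"]),
                           cutoff=int(frag_opts.get("cutoff", 200)))
    from dataclasses import replace
    return replace(sim, fragment_model=fm)


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError("pipeline config must be a mapping")
    return config


def run_pipeline(config: dict | str | Path, out_dir, stages=None) -> RunManifest:
    """Run the requested stages in dependency order.

    ``config`` is a mapping or a path to a YAML file. Stage outputs are
    cached: when a manifest from the same config exists and a stage's outputs
    are all present, the stage is skipped.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seed = int(config.get("seed", 0))
    requested = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = (set(stages) - set(STAGES)) if stages is not None else set()
    if unknown:
        raise ValidationError(f"unknown stages {sorted(unknown)}")

    previous = {}
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") == chash:
                previous = old.get("stages", {})
        except (json.JSONDecodeError, OSError):
            previous = {}

    manifest = RunManifest(config_hash=chash, seed=seed)
    runners = {
        "simulate": _stage_simulate, "summary": _stage_summary,
        "dmr": _stage_dmr, "phd": _stage_phd,
        "fragments": _stage_fragments, "zscore": _stage_zscore,
    }
    for stage in requested:
        cached = previous.get(stage)
        if cached and not cached.get("skipped") and all(
                Path(p).exists() for p in cached["outputs"]):
            manifest.stages[stage] = {"skipped": True,
                                      "outputs": cached["outputs"]}
            continue
        outputs = runners[stage](config, out)
        manifest.record(stage, outputs)
    manifest_path.write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _report_dir(out: Path) -> Path:
    return out / "reports"


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage {needed_by!r} needs {path}; run stage {stage!r} first")
    return path


def _stage_simulate(config: dict, out: Path) -> list[Path]:
    sim = _sim_config(config)
    methylomes, truth = simulate_methylomes(sim)
    outputs = []
    rdir = _report_dir(out)
    rdir.mkdir(exist_ok=True)
    for group, samples in methylomes.items():
        for m in samples:
            path = rdir / f"{m.sample_id}.cx.tsv"
            write_cytosine_report(m, path)
            outputs.append(path)
    for name, frame in (("truth_dmrs", truth.dmrs), ("truth_phds", truth.phds)):
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        outputs.append(path)

    frags, frag_truth = simulate_fragments(sim)
    frag_path = out / "fragments.tsv"
    write_fragments(frags, frag_path)
    outputs.append(frag_path)
    ratios_path = out / "truth_fragment_ratios.json"
    ratios_path.write_text(json.dumps(frag_truth.fragment_ratios, indent=2))
    outputs.append(ratios_path)

    zopts = config.get("zscore", {})
    from .simulate import TrisomyModel
    tm = TrisomyModel(**{k: v for k, v in zopts.items()
                         if k in TrisomyModel.__dataclass_fields__})
    cohort, cohort_truth = simulate_trisomy_cohort(tm, seed=sim.seed + 77)
    counts_path = out / "counts.tsv"
    write_count_table(cohort, counts_path)
    outputs.append(counts_path)
    truth_path = out / "truth_cohort.tsv"
    cohort_truth.samples.to_csv(truth_path, sep="\t", index=False)
    outputs.append(truth_path)

    sizes_path = out / "chrom_sizes.tsv"
    pd.DataFrame(sorted(sim.chrom_sizes().items()),
                 columns=["chrom", "size"]).to_csv(
        sizes_path, sep="\t", header=False, index=False)
    outputs.append(sizes_path)
    return outputs


def _load_groups(config: dict, out: Path, stage: str):
    rdir = _require(_report_dir(out), "simulate", stage)
    groups: dict[str, list] = {}
    for path in sorted(rdir.glob("*.cx.tsv")):
        group = path.name.rsplit("_", 1)[0]
        m = read_cytosine_report(path, sample_id=path.name.split(".")[0], group=group)
        groups.setdefault(group, []).append(m)
    if not groups:
        raise PipelineError(f"stage {stage!r}: no cytosine reports under {rdir}; "
                            "run stage 'simulate' first")
    return groups


def _stage_summary(config: dict, out: Path) -> list[Path]:
    groups = _load_groups(config, out, "summary")
    outputs = []
    summary_json = {}
    for group, samples in sorted(groups.items()):
        levels = summary_mod.group_mean_levels(samples, min_samples=2)
        hist = summary_mod.histogram_1pct(levels)
        hist_path = out / f"histogram_{group}.tsv"
        pd.DataFrame({"bin_pct": range(100),
                      "proportion": hist.proportions}).to_csv(
            hist_path, sep="\t", index=False)
        outputs.append(hist_path)
        summary_json[group] = {
            "n_sites": hist.n_sites,
            "classes": summary_mod.classify_sites(levels),
            "context_methylation": summary_mod.context_methylation(samples[0]),
        }
    path = out / "summary.json"
    path.write_text(json.dumps(summary_json, indent=2, sort_keys=True))
    outputs.append(path)
    return outputs


def _stage_dmr(config: dict, out: Path) -> list[Path]:
    opts = config.get("dmr", {})
    groups = _load_groups(config, out, "dmr")
    ga, gb = opts.get("group_a", "non_pregnant_ccf"), opts.get("group_b", "placenta")
    for g in (ga, gb):
        if g not in groups:
            raise PipelineError(f"stage 'dmr': group {g!r} has no reports")
    stats_a = dmr_mod.group_site_stats(groups[ga],
                                       min_coverage=opts.get("min_coverage", 1),
                                       min_samples=opts.get("min_samples", 2))
    stats_b = dmr_mod.group_site_stats(groups[gb],
                                       min_coverage=opts.get("min_coverage", 1),
                                       min_samples=opts.get("min_samples", 2))
    tstats = dmr_mod.site_t(stats_a, stats_b)
    filtered = dmr_mod.filter_sites(tstats, t_min=opts.get("t_min", 5.0))
    calls = dmr_mod.call_dmrs(filtered, max_gap=opts.get("max_gap", 300),
                              min_cpg=opts.get("min_cpg", 9))
    frame = dmr_mod.dmrs_to_frame(calls)
    tsv = out / "dmrs.tsv"
    frame.to_csv(tsv, sep="\t", index=False)
    bed = out / "dmrs.bed"
    rs = RegionSet("dmrs", frame[["chrom", "start", "end"]]
                   if len(frame) else pd.DataFrame(columns=["chrom", "start", "end"]))
    write_bed(rs, bed, names=frame["direction"] if len(frame) else None,
              scores=frame["mean_abs_t"].replace([float("inf")], 999.0)
              if len(frame) else None)
    return [tsv, bed]


def _stage_phd(config: dict, out: Path) -> list[Path]:
    opts = config.get("phd", {})
    groups = _load_groups(config, out, "phd")
    target = opts.get("target_group", "placenta")
    reference = opts.get("reference_group", "non_pregnant_ccf")
    sizes_path = _require(out / "chrom_sizes.tsv", "simulate", "phd")
    chrom_sizes = dict(pd.read_csv(sizes_path, sep="\t", header=None).values)
    levels = {g: summary_mod.group_mean_levels(groups[g], min_samples=2)
              for g in (target, reference) if g in groups}
    bins = phd_mod.bin_genome(levels, chrom_sizes,
                              bin_size=opts.get("bin_size", 50_000))
    calls = phd_mod.call_phds(bins, target, reference,
                              delta=opts.get("delta", 0.15),
                              min_run=opts.get("min_run", 10),
                              min_cpg_per_bin=opts.get("min_cpg_per_bin", 10))
    outputs = []
    bins_path = out / "bins.tsv"
    bins.to_csv(bins_path, sep="\t", index=False)
    outputs.append(bins_path)
    for g in levels:
        track = out / f"bins_{g}.bedgraph"
        write_bedgraph(bins, f"mean_{g}", track)
        outputs.append(track)
    phds_path = out / "phds.tsv"
    phd_mod.phds_to_frame(calls).to_csv(phds_path, sep="\t", index=False)
    outputs.append(phds_path)
    table, _curve = phd_mod.density_stratified_diff(bins, target, reference)
    strata_path = out / "density_strata.tsv"
    table.to_csv(strata_path, sep="\t", index=False)
    outputs.append(strata_path)
    return outputs


def _stage_fragments(config: dict, out: Path) -> list[Path]:
    opts = config.get("fragments", {})
    frag_path = _require(out / "fragments.tsv", "simulate", "fragments")
    frags = read_fragments(frag_path)
    hist, modal = frag_mod.length_histogram(frags)
    hist_path = out / "fragment_lengths.tsv"
    hist.to_csv(hist_path, sep="\t")
    ratios = frag_mod.methylation_by_length(frags, cutoff=opts.get("cutoff", 200))
    sim = _sim_config(config)
    unmeth, meth = simulate_mcip(frags, sim.mcip_model, seed=sim.seed + 13)
    _, fold = frag_mod.fraction_size_comparison(
        unmeth, meth, threshold=opts.get("threshold", 300))
    stats_path = out / "fragment_stats.json"
    stats_path.write_text(json.dumps({
        "modal_length": modal,
        "fold_ratio_by_context": ratios,
        "mcip_gt_threshold_fold": fold,
    }, indent=2, sort_keys=True))
    return [hist_path, stats_path]


def _stage_zscore(config: dict, out: Path) -> list[Path]:
    counts_path = _require(out / "counts.tsv", "simulate", "zscore")
    cohort = read_count_table(counts_path)
    results = trisomy_mod.robust_z(cohort)
    table, summary = trisomy_mod.enrichment_fold(
        results, samples=[r.sample_id for r in results
                          if not r.euploid_known])
    z_path = out / "zscores.tsv"
    pd.DataFrame([{"sample_id": r.sample_id, "treatment": r.treatment,
                   "chr21_fraction": r.chr21_fraction, "z": r.z,
                   "euploid_known": r.euploid_known} for r in results]).to_csv(
        z_path, sep="\t", index=False)
    folds_path = out / "zscore_folds.json"
    folds_path.write_text(json.dumps({
        "per_sample": table.to_dict(orient="records"),
        "summary": summary,
    }, indent=2, sort_keys=True))
    return [z_path, folds_path]
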