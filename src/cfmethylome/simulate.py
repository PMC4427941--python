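"""Synthetic-data generation with known ground truth.

The generator emulates the statistical structure of a cfDNA WGBS study of
pregnancy:

* CpG sites placed by a spacing model (exponential inter-site gaps, denser
  inside planted DMR loci, optionally sparser inside planted domains).
* Bimodal per-CpG methylation: a low mode near 5%, a high mode near 90%,
  and a small intermediate class, shared as a common "blood" baseline by the
  hematopoietic groups (non-pregnant ccf DNA, buffy coat).
* Planted DMRs override both groups' levels at dense CpG clusters
  (default: near-complete methylation 0.97 in the hypermethylated group
  against 0.57 in the other, i.e. an absolute effect of 0.4).
* Planted multi-megabase hypomethylated domains multiplicatively scale the
  placenta level so the expected bin-mean drop equals the configured depth;
  high-mode sites land in the intermediate band, which is what produces the
  placental intermediate-methylation excess.
* Pregnant ccf DNA is a per-read mixture: each read is placental with
  probability equal to the fetal fraction.
* Read counts: coverage ~ Poisson, methylated reads ~ beta-binomial
  (Beta-distributed per-sample level around the site truth).
* cfDNA fragment lengths from a nucleosome-peaked mixture (mode 168 bp) with
  a di-nucleosome shoulder, and per-cytosine methylation probability
  logistic in fragment length; a sheared-genomic mode severs that link.
* MBD-capture (MCIp) partitioning with capture probability logistic in the
  fragment's methylated-CpG count.
* Euploid/trisomy-21 per-chromosome count tables: the expected chr21 share
  is scaled by (1 + f_eff/2), with f_eff = fetal fraction (times the
  enrichment factor for the enriched treatment, capped so shares stay valid).

A fixed ``SimulationConfig`` (including its seed) yields byte-identical
output; one global seed feeds a per-purpose seed tree so each simulation
product can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import gamma as gamma_dist

from . import intervals
from .errors import ValidationError
from .io import FragmentCall, FragmentRecord, RegionSet, SampleMethylome, split_strands
from .trisomy import RegionCountTable

BLOOD_GROUPS = ("non_pregnant_ccf", "buffy_coat")
ALL_GROUPS = ("non_pregnant_ccf", "buffy_coat", "placenta", "pregnant_ccf")

#: hg19 autosome lengths (bp), used for count-table baseline shares
HG19_AUTOSOMES = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566,
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureModel:
    """Beta mixture for per-site base methylation levels.

    Weights order is (low, intermediate, high). Low/high components are Beta
    distributions with the given means and common concentration; the
    intermediate component is Beta(mid_alpha, mid_beta).
    """

    weights: tuple = (0.10, 0.10, 0.80)
    low_mean: float = 0.05
    high_mean: float = 0.90
    concentration: float = 20.0
    mid_alpha: float = 3.0
    mid_beta: float = 3.0

    def validate(self):
        if abs(sum(self.weights) - 1.0) > 1e-9 or any(w < 0 for w in self.weights):
            raise ValidationError("mixture weights must be non-negative and sum to 1")
        for m in (self.low_mean, self.high_mean):
            if not 0 < m < 1:
                raise ValidationError("mixture component means must be in (0,1)")

    def mean(self) -> float:
        w_low, w_mid, w_high = self.weights
        mid_mean = self.mid_alpha / (self.mid_alpha + self.mid_beta)
        return w_low * self.low_mean + w_mid * mid_mean + w_high * self.high_mean

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(3, size=n, p=list(self.weights))
        out = np.empty(n)
        c = self.concentration
        for k, (a, b) in enumerate([
                (self.low_mean * c, (1 - self.low_mean) * c),
                (self.mid_alpha, self.mid_beta),
                (self.high_mean * c, (1 - self.high_mean) * c)]):
            sel = comp == k
            out[sel] = rng.beta(a, b, size=int(sel.sum()))
        return out


@dataclass(frozen=True)
class PlantedDMR:
    """A dense CpG cluster with a fixed between-group level difference.

    ``direction="hypo_in_target"`` places the target (placenta) group at
    ``anchor_high - effect`` and the reference (blood) group at
    ``anchor_high``; ``"hyper_in_target"`` swaps them.
    """

    chrom: str
    start: int
    n_cpg: int = 12
    spacing: int = 25
    effect: float = 0.4
    direction: str = "hypo_in_target"
    anchor_high: float = 0.97

    @property
    def positions(self) -> np.ndarray:
        return self.start + np.arange(self.n_cpg, dtype=np.int64) * self.spacing

    @property
    def end(self) -> int:
        return int(self.positions[-1]) + 2

    @property
    def reference_level(self) -> float:
        return self.anchor_high if self.direction == "hypo_in_target" \
            else self.anchor_high - self.effect

    @property
    def target_level(self) -> float:
        return self.anchor_high - self.effect if self.direction == "hypo_in_target" \
            else self.anchor_high

    def validate(self):
        if self.direction not in ("hypo_in_target", "hyper_in_target"):
            raise ValidationError(f"bad DMR direction {self.direction!r}")
        if not (0 <= self.anchor_high - self.effect and self.anchor_high <= 1):
            raise ValidationError(
                "planted DMR levels leave [0,1]; out-of-range means are rejected")
        if self.n_cpg < 1 or self.spacing < 2:
            raise ValidationError("planted DMR needs n_cpg >= 1 and spacing >= 2")


@dataclass(frozen=True)
class PlantedPHD:
    """A contiguous hypomethylated domain for the target (placenta) group.

    ``depth`` is the expected drop of the domain's mean methylation relative
    to the baseline mixture mean; it is applied multiplicatively per site so
    no site leaves [0,1]. ``cpg_spacing`` optionally thins CpG density inside
    the domain (domains live in CpG-poor regions).
    """

    chrom: str
    start: int
    end: int
    depth: float = 0.25
    cpg_spacing: float | None = None

    def validate(self, mixture_mean: float):
        if self.end <= self.start:
            raise ValidationError("planted domain must have end > start")
        if not 0 < self.depth < mixture_mean:
            raise ValidationError(
                f"domain depth {self.depth} must be in (0, mixture mean "
                f"{mixture_mean:.3f}) so scaled levels stay in [0,1]")


@dataclass(frozen=True)
class FragmentModel:
    """cfDNA fragment-length mixture and length-methylation coupling.

    ``components`` are (weight, modal length, sd) of discretized gamma
    components: a sub-nucleosomal shoulder, the mono-nucleosome peak at
    168 bp, and a di-nucleosome shoulder near 320 bp. The per-cytosine
    methylation probability is logistic in length:
    ``p(len) = expit(alpha[context] + beta * (len - 200) / 100)``.
    """

    components: tuple = ((0.05, 80.0, 20.0), (0.83, 168.0, 25.0),
                         (0.12, 320.0, 60.0))
    cpg_rate: float = 0.010
    chg_rate: float = 0.002
    chh_rate: float = 0.004
    alpha: Mapping[str, float] = field(default_factory=lambda: {
        "CpG": -2.0, "CHG": -5.0, "CHH": -5.5})
    beta: float = 1.2
    n_fragments: int = 50_000
    min_length: int = 30
    max_length: int = 700

    def validate(self):
        w = [c[0] for c in self.components]
        if abs(sum(w) - 1.0) > 1e-9 or any(x < 0 for x in w):
            raise ValidationError("fragment component weights must sum to 1")
        if not np.isfinite(self.beta) or any(
                not np.isfinite(a) for a in self.alpha.values()):
            raise ValidationError(
                "fragment model coefficients must be finite (probabilities "
                "must stay inside (0,1))")

    def length_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Discretized length distribution on [min_length, max_length]."""
        lengths = np.arange(self.min_length, self.max_length + 1)
        pmf = np.zeros(lengths.size)
        for weight, mode, sd in self.components:
            shape, scale = _gamma_params(mode, sd)
            pmf += weight * gamma_dist.pdf(lengths, a=shape, scale=scale)
        return lengths, pmf / pmf.sum()

    def methylation_probability(self, lengths, context: str,
                                length_dependent: bool = True) -> np.ndarray:
        lengths = np.asarray(lengths, dtype=float)
        x = np.full_like(lengths, self.alpha[context])
        if length_dependent:
            x += self.beta * (lengths - 200.0) / 100.0
        return expit(x)

    def analytic_fold_ratio(self, context: str = "CpG", cutoff: int = 200,
                            length_dependent: bool = True) -> float:
        """Expected long/short methylation-rate ratio under this model.

        Cytosine counts scale with fragment length, so each length's weight
        in a size class is pmf(len) * len.
        """
        lengths, pmf = self.length_pmf()
        p = self.methylation_probability(lengths, context, length_dependent)
        w = pmf * lengths
        long = lengths > cutoff
        rate_long = (w[long] * p[long]).sum() / w[long].sum()
        rate_short = (w[~long] * p[~long]).sum() / w[~long].sum()
        return float(rate_long / rate_short)

    def calibrated(self, target_ratio: float, context: str = "CpG",
                   cutoff: int = 200) -> "FragmentModel":
        """Return a copy with ``beta`` solved so the analytic ratio matches."""
        def objective(beta):
            return replace(self, beta=beta).analytic_fold_ratio(
                context, cutoff) - target_ratio
        beta = brentq(objective, 0.0, 25.0, xtol=1e-10)
        return replace(self, beta=float(beta))


@dataclass(frozen=True)
class MCIpModel:
    """Capture probability into the methylated fraction: expit(a + b*m)."""

    intercept: float = -2.0
    slope: float = 1.0


@dataclass(frozen=True)
class TrisomyModel:
    """Cohort design for the chromosome-21 count simulation.

    Defaults model the proof-of-concept cohort: 12 pregnant donors, 3
    carrying a trisomy-21 fetus, counted at ~1e6 region reads per sample and
    treatment, with unmethylated-DNA enrichment multiplying the effective
    fetal fraction 4-fold.
    """

    n_euploid: int = 9
    n_trisomy: int = 3
    fetal_fraction: float = 0.10
    enrichment_factor: float = 4.0
    depth: int = 1_000_000
    chrom_weights: Mapping[str, float] | None = None  # default: hg19 lengths

    def validate(self):
        if self.n_euploid < 3:
            raise ValidationError("need >= 3 euploid samples per treatment")
        if not 0 <= self.fetal_fraction <= 1:
            raise ValidationError("fetal fraction must be in [0,1]")

    def baseline(self) -> tuple[list[str], np.ndarray]:
        weights = self.chrom_weights or HG19_AUTOSOMES
        chroms = sorted(weights, key=lambda c: int(c.replace("chr", "")))
        w = np.array([weights[c] for c in chroms], dtype=float)
        return chroms, w / w.sum()


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; every fraction validated into [0,1]."""

    seed: int = 0
    genome: tuple = (("chr1", 10_000_000), ("chr2", 10_000_000))
    mean_spacing: float = 500.0
    n_samples: int = 6
    coverage_mean: float = 15.0
    overdispersion: float = 200.0
    mixture: MixtureModel = field(default_factory=MixtureModel)
    planted_dmrs: tuple = ()
    planted_phds: tuple = ()
    fetal_fraction: float = 0.10
    fragment_model: FragmentModel = field(default_factory=FragmentModel)
    mcip_model: MCIpModel = field(default_factory=MCIpModel)
    trisomy_model: TrisomyModel = field(default_factory=TrisomyModel)
    non_cpg_spacing: float | None = 2000.0
    non_cpg_level: float = 0.002
    strand_split: bool = False

    def __post_init__(self):
        problems = []
        try:
            self.mixture.validate()
        except ValidationError as exc:
            problems.append(str(exc))
        sizes = dict(self.genome)
        for dmr in self.planted_dmrs:
            try:
                dmr.validate()
            except ValidationError as exc:
                problems.append(str(exc))
            if dmr.chrom not in sizes or dmr.end > sizes[dmr.chrom]:
                problems.append(f"planted DMR at {dmr.chrom}:{dmr.start} "
                                "outside the simulated genome")
        for phd in self.planted_phds:
            try:
                phd.validate(self.mixture.mean())
            except ValidationError as exc:
                problems.append(str(exc))
            if phd.chrom not in sizes or phd.end > sizes.get(phd.chrom, 0):
                problems.append(f"planted domain at {phd.chrom}:{phd.start} "
                                "outside the simulated genome")
        if not 0 <= self.fetal_fraction <= 1:
            problems.append("fetal_fraction must be in [0,1]")
        if self.coverage_mean <= 0 or self.mean_spacing <= 1:
            problems.append("coverage_mean must be > 0 and mean_spacing > 1")
        if not 0 <= self.non_cpg_level <= 1:
            problems.append("non_cpg_level must be in [0,1]")
        try:
            self.fragment_model.validate()
            self.trisomy_model.validate()
        except ValidationError as exc:
            problems.append(str(exc))
        if problems:
            raise ValidationError("invalid config: " + "; ".join(problems))

    def chrom_sizes(self) -> dict[str, int]:
        return {c: int(s) for c, s in self.genome}

    def rng(self, *key: str) -> np.random.Generator:
        """Deterministic per-purpose generator derived from the global seed."""
        material = [self.seed] + [_stable_hash(k) for k in key]
        return np.random.default_rng(np.random.SeedSequence(material))


def _stable_hash(key: str) -> int:
    # process-independent (unlike builtin hash) so seeding is reproducible
    import hashlib

    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "little")


def _gamma_params(mode: float, sd: float) -> tuple[float, float]:
    # mode = (shape-1)*scale, var = shape*scale^2
    var = sd * sd
    scale = (-mode + math.sqrt(mode * mode + 4 * var)) / 2.0
    shape = mode / scale + 1.0
    return shape, scale


@dataclass
class TruthTable:
    """Planted ground truth accompanying each simulated product."""

    dmrs: pd.DataFrame | None = None
    phds: pd.DataFrame | None = None
    site_levels: pd.DataFrame | None = None
    fragment_ratios: dict | None = None
    samples: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def _place_cpg_sites(config: SimulationConfig, rng: np.random.Generator):
    """Background CpG positions per chromosome with piecewise spacing."""
    positions = {}
    sparse = [p for p in config.planted_phds if p.cpg_spacing is not None]
    for chrom, size in config.genome:
        segments = [(0, size, config.mean_spacing)]
        for phd in sorted((p for p in sparse if p.chrom == chrom),
                          key=lambda p: p.start):
            new = []
            for s, e, sp in segments:
                if phd.end <= s or phd.start >= e:
                    new.append((s, e, sp))
                    continue
                if s < phd.start:
                    new.append((s, phd.start, sp))
                new.append((max(s, phd.start), min(e, phd.end), phd.cpg_spacing))
                if e > phd.end:
                    new.append((phd.end, e, sp))
            segments = new
        chrom_pos = []
        for s, e, sp in segments:
            n_guess = int((e - s) / sp * 1.4) + 16
            gaps = np.maximum(rng.exponential(sp, size=n_guess), 2.0)
            pts = s + np.cumsum(gaps)
            while pts.size and pts[-1] < e:
                extra = np.maximum(rng.exponential(sp, size=16), 2.0)
                pts = np.concatenate([pts, pts[-1] + np.cumsum(extra)])
            chrom_pos.append(pts[pts < e - 1].astype(np.int64))
        pos = np.unique(np.concatenate(chrom_pos)) if chrom_pos else np.array([], np.int64)
        positions[chrom] = pos
    return positions


def _beta_around(base: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Per-sample level ~ Beta(base*kappa, (1-base)*kappa); 0/1 stay exact."""
    p = np.asarray(base, dtype=float)
    out = p.copy()
    interior = (p > 0) & (p < 1)
    if interior.any():
        out[interior] = rng.beta(p[interior] * kappa, (1 - p[interior]) * kappa)
    return out


def simulate_methylomes(config: SimulationConfig,
                        groups: Sequence[str] = ALL_GROUPS):
    """Simulate per-group sample methylomes plus the planted truth.

    Returns ``(methylomes, truth)`` where ``methylomes`` maps group label to
    a list of :class:`SampleMethylome`. The hematopoietic groups share one
    base level per site; placenta deviates only inside planted DMRs/domains;
    pregnant ccf DNA is a per-read (1-f) blood + f placenta mixture.
    """
    unknown = set(groups) - set(ALL_GROUPS)
    if unknown:
        raise ValidationError(f"unknown groups {sorted(unknown)}")
    pos_by_chrom = _place_cpg_sites(config, config.rng("cpg-positions"))

    # merge planted DMR clusters into the site grid (background sites inside
    # a cluster footprint are removed so the cluster stays clean)
    cluster_truth = []
    for chrom in pos_by_chrom:
        clusters = [d for d in config.planted_dmrs if d.chrom == chrom]
        if not clusters:
            continue
        footprint = intervals.as_frame(
            [(chrom, d.start - 2, d.end + 2) for d in clusters])
        bg = pos_by_chrom[chrom]
        keep = ~intervals.points_in(np.full(bg.size, chrom), bg, footprint)
        merged = np.unique(np.concatenate(
            [bg[keep]] + [d.positions for d in clusters]))
        pos_by_chrom[chrom] = merged

    chroms = np.concatenate([
        np.full(pos_by_chrom[c].size, c, dtype=object) for c, _ in config.genome])
    positions = np.concatenate([pos_by_chrom[c] for c, _ in config.genome])

    blood = config.mixture.draw(positions.size, config.rng("base-levels"))
    placenta = blood.copy()
    scale_mean = config.mixture.mean()
    for phd in config.planted_phds:
        mask = (chroms == phd.chrom) & (positions >= phd.start) & (positions < phd.end)
        placenta[mask] = placenta[mask] * (1.0 - phd.depth / scale_mean)
    for dmr in config.planted_dmrs:
        mask = (chroms == dmr.chrom) & np.isin(positions, dmr.positions)
        blood[mask] = dmr.reference_level
        placenta[mask] = dmr.target_level
    if ((blood < 0) | (blood > 1) | (placenta < 0) | (placenta > 1)).any():
        raise ValidationError("planted effects push site levels outside [0,1]")

    f = config.fetal_fraction
    kappa = config.overdispersion
    methylomes: dict[str, list[SampleMethylome]] = {}
    for group in groups:
        samples = []
        for i in range(config.n_samples):
            rng = config.rng("sample", group, str(i))
            cov = rng.poisson(config.coverage_mean, size=positions.size)
            if group == "pregnant_ccf":
                p_blood = _beta_around(blood, kappa, rng)
                p_plac = _beta_around(placenta, kappa, rng)
                n_fetal = rng.binomial(cov, f)
                meth = rng.binomial(n_fetal, p_plac) + rng.binomial(cov - n_fetal, p_blood)
            else:
                base = placenta if group == "placenta" else blood
                meth = rng.binomial(cov, _beta_around(base, kappa, rng))
            covered = cov > 0
            df = pd.DataFrame({
                "chrom": chroms[covered],
                "pos": positions[covered],
                "strand": "+",
                "context": "CpG",
                "meth": meth[covered],
                "unmeth": cov[covered] - meth[covered],
            })
            if config.non_cpg_spacing:
                df = pd.concat(
                    [df, _non_cpg_calls(config, rng)], ignore_index=True)
            m = SampleMethylome(df, sample_id=f"{group}_{i + 1:02d}", group=group)
            if config.strand_split:
                m = split_strands(m, seed=int(rng.integers(2 ** 31)))
            samples.append(m)
        methylomes[group] = samples

    truth = TruthTable(
        dmrs=pd.DataFrame({
            "chrom": [d.chrom for d in config.planted_dmrs],
            "start": [int(d.positions[0]) for d in config.planted_dmrs],
            "end": [d.end for d in config.planted_dmrs],
            "direction": [d.direction for d in config.planted_dmrs],
            "effect": [d.effect for d in config.planted_dmrs],
            "reference_level": [d.reference_level for d in config.planted_dmrs],
            "target_level": [d.target_level for d in config.planted_dmrs],
        }),
        phds=pd.DataFrame({
            "chrom": [p.chrom for p in config.planted_phds],
            "start": [p.start for p in config.planted_phds],
            "end": [p.end for p in config.planted_phds],
            "depth": [p.depth for p in config.planted_phds],
        }),
        site_levels=pd.DataFrame({
            "chrom": chroms, "pos": positions,
            "level_blood": blood, "level_placenta": placenta,
        }),
    )
    return methylomes, truth


def _non_cpg_calls(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for chrom, size in config.genome:
        step = int(config.non_cpg_spacing)
        pos = np.arange(step, size - 1, step, dtype=np.int64)
        ctx = np.where(np.arange(pos.size) % 2 == 0, "CHH", "CHG")
        cov = rng.poisson(config.coverage_mean, size=pos.size)
        meth = rng.binomial(cov, config.non_cpg_level)
        keep = cov > 0
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos[keep], "strand": "+",
            "context": ctx[keep], "meth": meth[keep],
            "unmeth": cov[keep] - meth[keep],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# fragments / MCIp
# ---------------------------------------------------------------------------

def simulate_fragments(config: SimulationConfig, mode: str = "wgbs_ccf",
                       region_short_boost: tuple | None = None):
    """Simulate cfDNA fragments with per-cytosine methylation calls.

    ``mode="wgbs_ccf"`` couples per-cytosine methylation probability to
    fragment length through the model's logistic term;
    ``mode="sheared_genomic"`` emulates mechanically sheared tissue DNA:
    lengths are drawn the same way but methylation is length-independent, so
    the true long/short fold ratio is exactly 1.

    ``region_short_boost=(region_set, prob, mode_bp, sd_bp)`` redraws the
    length of fragments whose midpoint falls inside the region set with the
    given probability from a shorter distribution (regulatory-region
    fragmentation).

    Returns ``(fragments, truth)`` with analytic per-context fold ratios in
    ``truth.fragment_ratios``.
    """
    if mode not in ("wgbs_ccf", "sheared_genomic"):
        raise ValidationError(f"unknown fragment mode {mode!r}")
    model = config.fragment_model
    rng = config.rng("fragments", mode)
    n = model.n_fragments

    weights = np.array([c[0] for c in model.components])
    comp = rng.choice(len(model.components), size=n, p=weights)
    lengths = np.empty(n)
    for k, (_, mode_bp, sd) in enumerate(model.components):
        shape, scale = _gamma_params(mode_bp, sd)
        sel = comp == k
        lengths[sel] = rng.gamma(shape, scale, size=int(sel.sum()))
    lengths = np.clip(np.rint(lengths), model.min_length, model.max_length
                      ).astype(np.int64)

    chrom_names = [c for c, _ in config.genome]
    sizes = np.array([s for _, s in config.genome], dtype=float)
    chrom_idx = rng.choice(len(chrom_names), size=n, p=sizes / sizes.sum())
    mids = (rng.random(n) * sizes[chrom_idx]).astype(np.int64)

    if region_short_boost is not None:
        regions, prob, mode_bp, sd = region_short_boost
        chrom_arr = np.array(chrom_names, dtype=object)[chrom_idx]
        member = intervals.points_in(chrom_arr, mids, regions.df)
        redraw = member & (rng.random(n) < prob)
        shape, scale = _gamma_params(mode_bp, sd)
        lengths[redraw] = np.clip(
            np.rint(rng.gamma(shape, scale, size=int(redraw.sum()))),
            model.min_length, model.max_length).astype(np.int64)

    starts = np.maximum(mids - lengths // 2, 0)
    ends = starts + lengths

    length_dependent = mode == "wgbs_ccf"
    rates = {"CpG": model.cpg_rate, "CHG": model.chg_rate, "CHH": model.chh_rate}
    n_calls = {ctx: rng.poisson(rate * lengths) for ctx, rate in rates.items()}
    p_meth = {ctx: model.methylation_probability(lengths, ctx, length_dependent)
              for ctx in rates}

    fragments = []
    for i in range(n):
        calls = []
        for ctx in ("CpG", "CHG", "CHH"):
            k = int(n_calls[ctx][i])
            if k == 0:
                continue
            offsets = rng.integers(0, lengths[i], size=k)
            states = rng.random(k) < p_meth[ctx][i]
            calls.extend(FragmentCall(int(o), ctx, bool(s))
                         for o, s in zip(offsets, states))
        calls.sort(key=lambda c: c.offset)
        fragments.append(FragmentRecord(chrom_names[chrom_idx[i]],
                                        int(starts[i]), int(ends[i]),
                                        tuple(calls)))
    truth = TruthTable(fragment_ratios={
        ctx: model.analytic_fold_ratio(ctx, length_dependent=length_dependent)
        for ctx in rates})
    return fragments, truth


def simulate_mcip(fragments: Sequence[FragmentRecord], mcip_model: MCIpModel,
                  seed: int):
    """Partition fragments into unmethylated/methylated MBD-capture fractions.

    Each fragment goes to the methylated fraction with probability
    ``expit(a + b*m)`` where ``m`` is its methylated-CpG count; the partition
    is exhaustive and exclusive.
    """
    rng = np.random.default_rng(seed)
    m = np.array([sum(1 for c in f.calls if c.context == "CpG" and c.methylated)
                  for f in fragments])
    p = expit(mcip_model.intercept + mcip_model.slope * m)
    captured = rng.random(len(fragments)) < p
    meth = [f for f, c in zip(fragments, captured) if c]
    unmeth = [f for f, c in zip(fragments, captured) if not c]
    return unmeth, meth


# ---------------------------------------------------------------------------
# trisomy cohort
# ---------------------------------------------------------------------------

def simulate_trisomy_cohort(model: TrisomyModel, seed: int):
    """Simulate per-chromosome count tables for a euploid/trisomy-21 cohort.

    Per sample and treatment, counts are multinomial over autosomes with the
    chr21 share scaled by (1 + f_eff/2); f_eff is 0 for euploid samples, the
    fetal fraction for unenriched trisomy samples and fetal fraction x
    enrichment factor (capped at 1) for enriched trisomy samples.
    """
    model.validate()
    if model.enrichment_factor < 1:
        import warnings

        warnings.warn("enrichment factor < 1 depletes the fetal signal",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    chroms, base = model.baseline()
    i21 = chroms.index("chr21")
    cohort = []
    truth_rows = []
    sample_specs = (
        [(f"euploid_{i + 1:02d}", False) for i in range(model.n_euploid)]
        + [(f"trisomy_{i + 1:02d}", True) for i in range(model.n_trisomy)])
    for sample_id, is_trisomy in sample_specs:
        for treatment in ("unenriched", "enriched"):
            f_eff = 0.0
            if is_trisomy:
                f_eff = model.fetal_fraction
                if treatment == "enriched":
                    f_eff = min(f_eff * model.enrichment_factor, 1.0)
            shares = base.copy()
            shares[i21] *= 1.0 + f_eff / 2.0
            shares /= shares.sum()
            counts = rng.multinomial(model.depth, shares)
            cohort.append(RegionCountTable(
                sample_id, treatment, euploid_known=not is_trisomy,
                counts=dict(zip(chroms, (int(c) for c in counts)))))
            truth_rows.append({"sample_id": sample_id, "treatment": treatment,
                               "trisomy": is_trisomy, "f_eff": f_eff,
                               "expected_chr21_fraction": float(shares[i21])})
    return cohort, TruthTable(samples=pd.DataFrame(truth_rows))
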