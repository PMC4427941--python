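"""Global and regional methylation summaries.

Summaries mirror the descriptive layer of a cfDNA WGBS study: per-context
global methylation, the distribution of per-site mean methylation in 1%-wide
bins, classification of sites into low (<20%), intermediate and high (>75%)
methylation classes, methylation profiles inside annotated regions against a
matched random background, and between-group correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals
from .errors import ValidationError
from .io import CONTEXTS, RegionSet, SampleMethylome


@dataclass
class MethylationHistogram:
    """Relative proportions of sites in 100 half-open 1%-wide level bins."""

    proportions: np.ndarray
    n_sites: int
    bin_width: float = 1.0


def context_methylation(methylome: SampleMethylome) -> dict[str, float]:
    """Pooled-read methylation fraction per cytosine context.

    For each context, sum(meth) / sum(meth + unmeth) over included sites.
    Contexts with zero covered sites are reported as NaN (undefined), never 0.
    """
    df = methylome.calls
    df = df[df["included"]]
    out = {}
    for ctx in CONTEXTS:
        sub = df[df["context"] == ctx]
        total = int(sub["meth"].sum() + sub["unmeth"].sum())
        out[ctx] = float(sub["meth"].sum()) / total if total > 0 else math.nan
    return out


def group_mean_levels(methylomes: list[SampleMethylome], min_samples: int = 1,
                      context: str = "CpG") -> pd.Series:
    """Unweighted mean of per-sample methylation fractions at each site.

    A site enters only if covered (per each sample's inclusion flag) in at
    least ``min_samples`` samples. The mean weights every sample equally
    regardless of its read depth; pooled-count averaging would overweight
    deeply covered samples.
    """
    if not methylomes:
        raise ValidationError("empty sample group")
    per_sample = [m.levels(context=context) for m in methylomes]
    stacked = pd.concat(per_sample)
    grouped = stacked.groupby(level=["chrom", "pos"])
    n = grouped.size()
    mean = grouped.mean()
    return mean[n >= min_samples].rename("level")


def classify_sites(mean_levels, low_cut: float = 0.20,
                   high_cut: float = 0.75) -> dict[str, float]:
    """Fractions of sites in low / intermediate / high methylation classes.

    Low and high are strict (``level < low_cut``, ``level > high_cut``);
    the intermediate class is the closed interval in between, so a site at
    exactly the cut belongs to the intermediate class.
    """
    if low_cut >= high_cut:
        raise ValidationError(f"low_cut {low_cut} must be < high_cut {high_cut}")
    levels = np.asarray(mean_levels, dtype=float)
    if levels.size == 0:
        raise ValidationError("no sites to classify")
    low = float(np.mean(levels < low_cut))
    high = float(np.mean(levels > high_cut))
    return {"low": low, "intermediate": 1.0 - low - high, "high": high}


def histogram_1pct(mean_levels) -> MethylationHistogram:
    """1%-bin histogram of site methylation; bin k holds [k%, k+1%), 100% in bin 99."""
    levels = np.asarray(mean_levels, dtype=float)
    if levels.size == 0:
        raise ValidationError("cannot histogram an empty level set")
    idx = np.minimum(np.floor(levels * 100).astype(int), 99)
    counts = np.bincount(idx, minlength=100)
    return MethylationHistogram(proportions=counts / levels.size,
                                n_sites=int(levels.size))


def region_profile(mean_levels: pd.Series, regions: RegionSet,
                   seed: int) -> dict[str, np.ndarray]:
    """Levels of CpGs inside ``regions`` vs an equally sized random background.

    The background ("unenriched") is a seeded uniform sample, without
    replacement, of the same number of CpG sites drawn strictly outside the
    regions, mirroring a matched random-sampling control.
    """
    if len(regions) == 0:
        raise ValidationError("empty region set: no enriched/unenriched contrast")
    chroms = mean_levels.index.get_level_values("chrom").to_numpy()
    positions = mean_levels.index.get_level_values("pos").to_numpy()
    inside = intervals.points_in(chroms, positions, regions.df)
    enriched = mean_levels.to_numpy()[inside]
    outside_levels = mean_levels.to_numpy()[~inside]
    if enriched.size == 0:
        raise ValidationError("no CpG sites inside the region set")
    if outside_levels.size < enriched.size:
        raise ValidationError(
            f"only {outside_levels.size} CpG sites outside regions; "
            f"need {enriched.size} for a matched background")
    rng = np.random.default_rng(seed)
    pick = rng.choice(outside_levels.size, size=enriched.size, replace=False)
    return {"enriched": enriched, "unenriched": outside_levels[np.sort(pick)]}


def group_correlation(mean_levels_a: pd.Series, mean_levels_b: pd.Series) -> float:
    """Pearson correlation of two groups' mean levels over shared sites.

    Returns NaN (undefined) when either vector has zero variance on the
    intersection or fewer than 2 sites are shared.
    """
    joined = pd.concat([mean_levels_a.rename("a"), mean_levels_b.rename("b")],
                       axis=1, join="inner")
    if len(joined) < 2:
        return math.nan
    a = joined["a"].to_numpy()
    b = joined["b"].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])
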