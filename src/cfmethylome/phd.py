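"""Megabase-scale hypomethylated domain detection on 50 kbp genomic bins.

The genome is tiled with fixed-width bins (default 50 kbp). Each bin carries
the unweighted mean of per-site group methylation for every sample group,
plus CpG and gene density. A placenta hypomethylated domain (PHD) is a
maximal run of consecutive qualifying bins in which the reference group's
mean exceeds the target (placenta) group's mean by at least ``delta``.
Domains characteristically occupy regions of low CpG and gene density, so a
density-stratified differential methylation table with a local-regression
(LOWESS) smooth is provided as descriptive output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ValidationError
from .io import RegionSet

DEFAULT_BIN_SIZE = 50_000


def bin_genome(group_mean_levels: Mapping[str, pd.Series],
               chrom_sizes: Mapping[str, int],
               genes: RegionSet | None = None,
               cpg_positions: pd.Series | None = None,
               bin_size: int = DEFAULT_BIN_SIZE,
               min_sites_per_bin: int = 1) -> pd.DataFrame:
    """Tile chromosomes into half-open bins and summarize methylation/density.

    Returns a frame with one row per bin: ``chrom, start, end, cpg_count,
    gene_count`` and, per group, ``mean_<group>`` (NaN when fewer than
    ``min_sites_per_bin`` sites are available) and ``n_<group>``.

    ``cpg_positions`` (a Series/frame indexed or keyed by (chrom, pos))
    defaults to the union of sites over all groups. ``gene_count`` counts
    gene intervals overlapping each bin, so one gene may count in several
    bins. A site on a chromosome absent from ``chrom_sizes`` is an error.
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    rows = []
    offsets = {}
    for chrom in sorted(chrom_sizes):
        size = int(chrom_sizes[chrom])
        n_bins = max(1, -(-size // bin_size))
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, size)
        offsets[chrom] = len(rows)
        rows.extend(zip([chrom] * n_bins, starts, ends))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def bin_index(chroms, positions):
        idx = np.empty(len(positions), dtype=np.int64)
        for chrom in np.unique(chroms):
            if chrom not in offsets:
                raise ValidationError(f"unknown chromosome {chrom!r} in input")
            sel = chroms == chrom
            local = positions[sel] // bin_size
            if (positions[sel] >= chrom_sizes[chrom]).any():
                raise ValidationError(
                    f"position beyond length of chromosome {chrom!r}")
            idx[sel] = offsets[chrom] + local
        return idx

    if cpg_positions is None:
        keys = set()
        for levels in group_mean_levels.values():
            keys.update(zip(levels.index.get_level_values("chrom"),
                            levels.index.get_level_values("pos")))
        cpg = pd.DataFrame(sorted(keys), columns=["chrom", "pos"])
    else:
        idx = cpg_positions.index if isinstance(cpg_positions, pd.Series) else cpg_positions
        cpg = pd.DataFrame({"chrom": idx.get_level_values("chrom"),
                            "pos": idx.get_level_values("pos")})
    cpg_idx = bin_index(cpg["chrom"].to_numpy(), cpg["pos"].to_numpy(np.int64))
    bins["cpg_count"] = np.bincount(cpg_idx, minlength=len(bins)).astype(np.int64)

    gene_counts = np.zeros(len(bins), dtype=np.int64)
    if genes is not None and len(genes):
        for chrom, start, end in genes.df.itertuples(index=False):
            if chrom not in offsets:
                raise ValidationError(f"unknown chromosome {chrom!r} in gene set")
            first = offsets[chrom] + start // bin_size
            last = offsets[chrom] + (min(end, chrom_sizes[chrom]) - 1) // bin_size
            gene_counts[first:last + 1] += 1
    bins["gene_count"] = gene_counts

    for group, levels in group_mean_levels.items():
        chroms = levels.index.get_level_values("chrom").to_numpy()
        positions = levels.index.get_level_values("pos").to_numpy(np.int64)
        idx = bin_index(chroms, positions)
        n = np.bincount(idx, minlength=len(bins))
        total = np.bincount(idx, weights=levels.to_numpy(), minlength=len(bins))
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = total / n
        mean[n < min_sites_per_bin] = np.nan
        bins[f"mean_{group}"] = mean
        bins[f"n_{group}"] = n.astype(np.int64)
    return bins


@dataclass(frozen=True)
class PHD:
    """A contiguous hypomethylated domain of consecutive qualifying bins.

    Per-domain means weight member bins by their CpG count, so the domain
    summary reflects site mass rather than bin count.
    """

    chrom: str
    start: int
    end: int
    n_bins: int
    mean_meth_target: float
    mean_meth_reference: float


def call_phds(bins: pd.DataFrame, target_group: str, reference_group: str,
              delta: float = 0.15, min_run: int = 10,
              min_cpg_per_bin: int = 10) -> list[PHD]:
    """Maximal runs of consecutive bins with reference - target >= delta.

    A bin qualifies when both group means are defined, its CpG count is at
    least ``min_cpg_per_bin`` and the hypomethylation depth reaches ``delta``.
    Runs are broken by any non-qualifying bin (no gap tolerance) and by
    chromosome boundaries; runs shorter than ``min_run`` bins are dropped.
    """
    if delta <= 0:
        raise ValidationError("delta must be > 0")
    tcol, rcol = f"mean_{target_group}", f"mean_{reference_group}"
    for col in (tcol, rcol):
        if col not in bins.columns:
            raise ValidationError(f"bins are missing column {col!r}")
    target = bins[tcol].to_numpy(dtype=float)
    reference = bins[rcol].to_numpy(dtype=float)
    cpg = bins["cpg_count"].to_numpy()
    qualifies = (~np.isnan(target) & ~np.isnan(reference)
                 & (cpg >= min_cpg_per_bin)
                 & (reference - target >= delta))
    chroms = bins["chrom"].to_numpy()

    phds = []
    i = 0
    n = len(bins)
    while i < n:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and qualifies[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        run = slice(i, j + 1)
        if (j - i + 1) >= min_run:
            weights = cpg[run].astype(float)
            wsum = weights.sum()
            phds.append(PHD(
                chrom=str(chroms[i]),
                start=int(bins["start"].iloc[i]),
                end=int(bins["end"].iloc[j]),
                n_bins=j - i + 1,
                mean_meth_target=float((target[run] * weights).sum() / wsum),
                mean_meth_reference=float((reference[run] * weights).sum() / wsum),
            ))
        i = j + 1
    return phds


def phds_to_frame(phds: list[PHD]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [p.chrom for p in phds],
        "start": [p.start for p in phds],
        "end": [p.end for p in phds],
        "n_bins": [p.n_bins for p in phds],
        "mean_meth_target": [p.mean_meth_target for p in phds],
        "mean_meth_reference": [p.mean_meth_reference for p in phds],
    })


def density_stratified_diff(bins: pd.DataFrame, target_group: str,
                            reference_group: str,
                            strata: Sequence[int] = (10, 50, 100, 200, 400),
                            lowess_frac: float = 0.3):
    """Differential methylation (target - reference) stratified by CpG density.

    ``strata`` are CpG-count breakpoints; stratum k holds bins with
    ``strata[k-1] <= cpg_count < strata[k]``. Negative mean differences
    indicate hypomethylation of the target group. Returns ``(table, curve)``
    where ``curve`` is a LOWESS fit of the per-bin difference against CpG
    count (descriptive only; never used for domain calling).
    """
    tcol, rcol = f"mean_{target_group}", f"mean_{reference_group}"
    usable = bins.dropna(subset=[tcol, rcol]).copy()
    usable["diff"] = usable[tcol] - usable[rcol]
    edges = [0, *sorted(strata), np.inf]
    records = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = usable[(usable["cpg_count"] >= lo) & (usable["cpg_count"] < hi)]
        records.append({
            "cpg_min": lo, "cpg_max": hi, "n_bins": len(sub),
            "mean_diff": float(sub["diff"].mean()) if len(sub) else np.nan,
            f"mean_{target_group}": float(sub[tcol].mean()) if len(sub) else np.nan,
            f"mean_{reference_group}": float(sub[rcol].mean()) if len(sub) else np.nan,
        })
    table = pd.DataFrame.from_records(records)
    if len(usable) >= 3:
        with np.errstate(invalid="ignore", divide="ignore"):  # ties in x
            fit = lowess(usable["diff"].to_numpy(),
                         usable["cpg_count"].to_numpy(float),
                         frac=lowess_frac, return_sorted=True)
        curve = pd.DataFrame(fit, columns=["cpg_count", "smoothed_diff"])
    else:
        curve = pd.DataFrame(columns=["cpg_count", "smoothed_diff"])
    return table, curve


def dmr_phd_overlap(hypomethylated_dmrs, phds: list[PHD]) -> float:
    """Fraction of DMRs with >=1 bp overlap to any PHD; NaN when no DMRs."""
    from . import intervals  # local to avoid cycle at import time

    if not hypomethylated_dmrs:
        return float("nan")
    q = intervals.as_frame(
        [(d.chrom, d.start, d.end) for d in hypomethylated_dmrs])
    if not phds:
        return 0.0
    t = intervals.as_frame([(p.chrom, p.start, p.end) for p in phds])
    return float(np.mean(intervals.overlaps_any(q, t)))
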