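"""Differentially methylated region (DMR) calling between two sample groups.

The procedure is deliberately simple and threshold-based:

1. For each CpG site, compute the mean and standard deviation of per-sample
   methylation fractions within each group.
2. Compute a two-sample t-statistic per site (Welch form, from the group
   summary statistics).
3. Remove all sites with ``|t| < 5``.
4. Group surviving sites when consecutive sites on the same chromosome are
   less than 300 bp apart (and, by default, share the sign of the group
   difference).
5. A group of nine or more CpG sites is a DMR.

No multiple-testing correction is applied; the ``|t| >= 5`` cut *is* the
procedure. Sites where both groups have zero variance but different means are
assigned a signed infinite sentinel so that maximally separated (fully
methylated vs fully unmethylated) sites are kept by any finite threshold
rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals
from .errors import ValidationError
from .io import RegionSet, SampleMethylome

#: half-open DMR end = last member CpG + 2, covering the final dinucleotide
CPG_DINUCLEOTIDE = 2


def group_site_stats(methylomes: list[SampleMethylome], min_coverage: int = 1,
                     min_samples: int = 2, context: str = "CpG") -> pd.DataFrame:
    """Per-site n / mean / sd of per-sample methylation fractions.

    ``sd`` is the sample standard deviation (n-1 denominator). A site is
    emitted only when covered with >= ``min_coverage`` reads in at least
    ``min_samples`` samples. Requires a group of >= 2 samples.
    """
    if len(methylomes) < 2:
        raise ValidationError("group_site_stats needs a group of >= 2 samples")
    frames = []
    for m in methylomes:
        df = m.calls
        df = df[(df["context"] == context)]
        cov = df["meth"] + df["unmeth"]
        df = df[cov >= max(min_coverage, 1)]
        frames.append(pd.DataFrame({
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "level": (df["meth"] / (df["meth"] + df["unmeth"])).to_numpy(),
        }))
    stacked = pd.concat(frames, ignore_index=True)
    g = stacked.groupby(["chrom", "pos"], sort=True)["level"]
    out = g.agg(n="size", mean="mean", sd="std").reset_index()
    out["sd"] = out["sd"].fillna(0.0)  # n == 1 sites are filtered next anyway
    return out[out["n"] >= min_samples].reset_index(drop=True)


def site_t(stats_a: pd.DataFrame, stats_b: pd.DataFrame) -> pd.DataFrame:
    """Welch t-statistic per shared site, oriented A minus B.

    t = (mean_A - mean_B) / sqrt(sd_A^2/n_A + sd_B^2/n_B).  Sites present in
    only one group are skipped. Degenerate sites (both sd = 0): t = 0 when the
    means agree, +/-inf sentinel when they differ.
    """
    merged = stats_a.merge(stats_b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    diff = merged["mean_a"].to_numpy() - merged["mean_b"].to_numpy()
    se = np.sqrt(merged["sd_a"].to_numpy() ** 2 / merged["n_a"].to_numpy()
                 + merged["sd_b"].to_numpy() ** 2 / merged["n_b"].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    degenerate = se == 0
    t[degenerate & (diff == 0)] = 0.0
    t[degenerate & (diff != 0)] = np.sign(diff[degenerate & (diff != 0)]) * np.inf
    out = merged[["chrom", "pos"]].copy()
    out["t"] = t
    out["diff"] = diff
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def filter_sites(tstats: pd.DataFrame, t_min: float = 5.0) -> pd.DataFrame:
    """Keep exactly the sites with ``|t| >= t_min`` (strict removal below)."""
    return tstats[np.abs(tstats["t"].to_numpy()) >= t_min].reset_index(drop=True)


@dataclass(frozen=True)
class DMR:
    """A called differentially methylated region.

    Coordinates are 0-based half-open: first member CpG through last member
    CpG + 2. ``direction`` is ``hyper_in_A`` when the A-group mean is higher.
    """

    chrom: str
    start: int
    end: int
    n_cpg: int
    direction: str
    mean_diff: float
    mean_abs_t: float
    member_positions: tuple

    def __post_init__(self):
        if self.n_cpg != len(self.member_positions):
            raise ValidationError("n_cpg inconsistent with member_positions")


def call_dmrs(filtered: pd.DataFrame, max_gap: int = 300, min_cpg: int = 9,
              same_sign: bool = True) -> list[DMR]:
    """Group filtered sites into DMRs.

    Consecutive surviving sites on the same chromosome with position
    difference strictly below ``max_gap`` stay in one group; with
    ``same_sign`` (default) a sign change of the group difference closes the
    current group. Groups of >= ``min_cpg`` sites are returned as DMRs.
    Input must be sorted by (chrom, pos).
    """
    if len(filtered) == 0:
        return []
    chroms = filtered["chrom"].to_numpy()
    pos = filtered["pos"].to_numpy()
    order_ok = all(
        (chroms[i] != chroms[i + 1]) or (pos[i] < pos[i + 1])
        for i in range(len(pos) - 1))
    if not order_ok:
        raise ValidationError("call_dmrs requires input sorted by (chrom, pos)")
    t = filtered["t"].to_numpy(dtype=float)
    diff = filtered["diff"].to_numpy(dtype=float)
    sign = np.sign(diff)

    new_group = np.ones(len(pos), dtype=bool)
    if len(pos) > 1:
        same_chrom = chroms[1:] == chroms[:-1]
        close = (pos[1:] - pos[:-1]) < max_gap
        cont = same_chrom & close
        if same_sign:
            cont &= sign[1:] == sign[:-1]
        new_group[1:] = ~cont
    group_id = np.cumsum(new_group)

    dmrs = []
    for gid in np.unique(group_id):
        sel = group_id == gid
        if int(sel.sum()) < min_cpg:
            continue
        p = pos[sel]
        d = diff[sel]
        dmrs.append(DMR(
            chrom=str(chroms[sel][0]),
            start=int(p[0]),
            end=int(p[-1]) + CPG_DINUCLEOTIDE,
            n_cpg=int(sel.sum()),
            direction="hyper_in_A" if d.mean() > 0 else "hyper_in_B",
            mean_diff=float(d.mean()),
            mean_abs_t=float(np.abs(t[sel]).mean()),
            member_positions=tuple(int(x) for x in p),
        ))
    return dmrs


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [d.chrom for d in dmrs],
        "start": [d.start for d in dmrs],
        "end": [d.end for d in dmrs],
        "n_cpg": [d.n_cpg for d in dmrs],
        "direction": [d.direction for d in dmrs],
        "mean_diff": [d.mean_diff for d in dmrs],
        "mean_abs_t": [d.mean_abs_t for d in dmrs],
    })


def annotate_dmrs(dmrs: list[DMR], feature_sets: list[RegionSet]) -> dict[str, float]:
    """Fraction of DMRs overlapping (>=1 bp, half-open) each feature set."""
    if not dmrs:
        return {fs.name: float("nan") for fs in feature_sets}
    q = intervals.as_frame([(d.chrom, d.start, d.end) for d in dmrs])
    return {
        fs.name: float(np.mean(intervals.overlaps_any(q, fs.df)))
        for fs in feature_sets
    }


def partition_genic(dmrs: list[DMR], genes: RegionSet) -> dict[str, float]:
    """Split DMRs into intragenic (overlapping a gene) vs intergenic fractions."""
    if not dmrs:
        return {"intragenic": float("nan"), "intergenic": float("nan")}
    q = intervals.as_frame([(d.chrom, d.start, d.end) for d in dmrs])
    intra = float(np.mean(intervals.overlaps_any(q, genes.df)))
    return {"intragenic": intra, "intergenic": 1.0 - intra}


def dmr_overlap(dmrs_a: list[DMR], dmrs_b: list[DMR]) -> float:
    """Fraction of A-DMRs overlapped (>=1 bp) by any B-DMR; NaN if A empty."""
    if not dmrs_a:
        return float("nan")
    if not dmrs_b:
        return 0.0
    qa = intervals.as_frame([(d.chrom, d.start, d.end) for d in dmrs_a])
    qb = intervals.as_frame([(d.chrom, d.start, d.end) for d in dmrs_b])
    return float(np.mean(intervals.overlaps_any(qa, qb)))
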