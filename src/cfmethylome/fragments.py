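"""Fragment-length and fragmentation/methylation statistics for cfDNA.

Circulating cfDNA is fragmented non-randomly: the dominant fragment length
is one nucleosome (~168 bp), and cytosines on long (>200 bp) fragments are
far more likely to be methylated than cytosines on short fragments. This
module computes length histograms, the long/short methylation fold ratio per
cytosine context, the pair-level filters and size comparison for MBD-capture
(MCIp) sequencing fractions, and short-fragment enrichment within annotated
regulatory regions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals
from .errors import ValidationError
from .io import CONTEXTS, FragmentRecord, RegionSet


def length_histogram(fragments: Sequence[FragmentRecord]):
    """Counts per fragment length plus the modal length (ties -> smallest)."""
    if not fragments:
        raise ValidationError("length_histogram needs at least one fragment")
    lengths = np.array([f.length for f in fragments])
    counts = pd.Series(Counter(lengths)).sort_index()
    counts.index.name = "length"
    modal = int(counts.index[np.argmax(counts.to_numpy())])
    return counts.rename("count"), modal


def methylation_by_length(fragments: Sequence[FragmentRecord],
                          cutoff: int = 200,
                          boundary: str = "short") -> dict[str, float]:
    """Long/short methylation-rate fold ratio per cytosine context.

    ratio = (methylated calls / total calls on fragments longer than
    ``cutoff``) / (same rate on fragments of length <= ``cutoff``), i.e. the
    per-cytosine methylation-rate ratio after scaling each size class by the
    number of cytosines measured in it. Fragments of exactly ``cutoff`` bp
    fall in the short class by default; ``boundary="drop"`` excludes them.
    Contexts with an empty size class or a zero short-class rate are NaN.
    """
    if boundary not in ("short", "drop"):
        raise ValidationError("boundary must be 'short' or 'drop'")
    meth = {ctx: [0, 0] for ctx in CONTEXTS}   # context -> [long, short] methylated
    total = {ctx: [0, 0] for ctx in CONTEXTS}  # context -> [long, short] measured
    for fr in fragments:
        if fr.length > cutoff:
            cls = 0
        elif fr.length == cutoff and boundary == "drop":
            continue
        else:
            cls = 1
        for call in fr.calls:
            total[call.context][cls] += 1
            if call.methylated:
                meth[call.context][cls] += 1
    out = {}
    for ctx in CONTEXTS:
        (m_long, m_short), (t_long, t_short) = meth[ctx], total[ctx]
        if t_long == 0 or t_short == 0 or m_short == 0:
            out[ctx] = math.nan
        else:
            out[ctx] = (m_long / t_long) / (m_short / t_short)
    return out


@dataclass(frozen=True)
class ReadPair:
    """Mate chromosomes and start positions of one sequenced pair."""

    chrom1: str
    start1: int
    chrom2: str
    start2: int


def mcip_pair_filter(pairs: Iterable[ReadPair], max_size: int = 500):
    """Apply MCIp pair-level filters and derive fragment sizes.

    Size is the distance between the start sites of the two paired reads.
    Pairs with size > ``max_size`` or with mates mapped to different
    chromosomes are discarded. A negative size (mis-ordered mates) is an
    error. Returns ``(fragments, tally)`` where tally counts
    kept/oversize/discordant pairs.
    """
    kept = []
    tally = {"kept": 0, "oversize": 0, "discordant": 0}
    for pair in pairs:
        if pair.chrom1 != pair.chrom2:
            tally["discordant"] += 1
            continue
        size = pair.start2 - pair.start1
        if size < 0:
            raise ValidationError(
                f"negative pair size at {pair.chrom1}:{pair.start1}-{pair.start2}"
                " (mates mis-ordered)")
        if size > max_size:
            tally["oversize"] += 1
            continue
        tally["kept"] += 1
        kept.append(FragmentRecord(pair.chrom1, pair.start1, pair.start1 + size))
    return kept, tally


@dataclass
class SizeFractionSummary:
    """Length histogram and long-fragment proportions of one MCIp fraction."""

    label: str
    histogram: pd.Series
    proportion_gt: dict[int, float]


def fraction_size_comparison(unmeth: Sequence[FragmentRecord],
                             meth: Sequence[FragmentRecord],
                             threshold: int = 300):
    """Compare long-fragment proportions of the two MCIp fractions.

    For each fraction, the proportion of fragments strictly longer than
    ``threshold``; fold = methylated proportion / unmethylated proportion
    (NaN when the unmethylated proportion is zero).
    """
    if not unmeth or not meth:
        raise ValidationError("both MCIp fractions must be non-empty")
    summaries = {}
    props = {}
    for label, frags in (("unmethylated", unmeth), ("methylated", meth)):
        hist, _ = length_histogram(frags)
        lengths = np.array([f.length for f in frags])
        prop = float(np.mean(lengths > threshold))
        summaries[label] = SizeFractionSummary(
            label, hist, proportion_gt={threshold: prop})
        props[label] = prop
    fold = (props["methylated"] / props["unmethylated"]
            if props["unmethylated"] > 0 else math.nan)
    return summaries, fold


def short_fragment_region_enrichment(fragments: Sequence[FragmentRecord],
                                     region_sets: Mapping[str, RegionSet] | Sequence[RegionSet],
                                     cutoff: int = 100) -> dict[str, float]:
    """Proportion of short (< ``cutoff`` bp) fragments per region set.

    A fragment belongs to a region when its midpoint falls inside it
    (half-open), so a fragment straddling a border is assigned
    unambiguously. The genome-wide proportion is reported under ``genome``;
    region sets containing no fragment midpoints report NaN.
    """
    if not fragments:
        raise ValidationError("no fragments supplied")
    if not isinstance(region_sets, Mapping):
        region_sets = {rs.name: rs for rs in region_sets}
    chroms = np.array([f.chrom for f in fragments])
    mids = np.array([f.midpoint for f in fragments])
    short = np.array([f.length < cutoff for f in fragments])
    out = {"genome": float(np.mean(short))}
    for name, rs in region_sets.items():
        member = intervals.points_in(chroms, mids, rs.df)
        out[name] = float(np.mean(short[member])) if member.any() else math.nan
    return out
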