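"""Robust z-score evaluation of chromosome-21 representation.

Counting is restricted to reads aligned within a subset of placenta
hypomethylated domains, where the effective fetal fraction is increased by
enriching for unmethylated DNA. Within each treatment (unenriched /
enriched) independently, the chromosome-21 fraction's median and MAD are
computed from known-euploid samples only, and every sample is scored as

    z = (fraction_sample - median_euploid) / MAD_euploid

with the MAD unscaled (the plain median of absolute deviations from the
median, no 1.4826 normal-consistency factor); ``scaled_mad=True`` enables
the consistency-scaled variant. A z above 3 suggests chromosome-21
overrepresentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateStatisticError, ValidationError

MAD_NORMAL_CONSISTENCY = 1.4826

TREATMENTS = ("unenriched", "enriched")


@dataclass
class RegionCountTable:
    """Per-chromosome read counts of one sample under one treatment."""

    sample_id: str
    treatment: str
    euploid_known: bool
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"treatment must be one of {TREATMENTS}")
        if any(v < 0 for v in self.counts.values()):
            raise ValidationError("negative read count")
        if not any(v > 0 for v in self.counts.values()):
            raise ValidationError(f"sample {self.sample_id}: all counts zero")

    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class ZScoreResult:
    sample_id: str
    treatment: str
    chr21_fraction: float
    z: float
    euploid_known: bool = False


def chr21_fraction(table: RegionCountTable, target: str = "chr21") -> float:
    """Reads on the target chromosome divided by total reads."""
    total = table.total()
    if total == 0:
        raise ValidationError("zero total count")
    return table.counts.get(target, 0) / total


def robust_z(cohort: Sequence[RegionCountTable], target: str = "chr21",
             scaled_mad: bool = False) -> list[ZScoreResult]:
    """Robust z-scores anchored on known-euploid samples, per treatment.

    Median and MAD are computed within each treatment stratum from samples
    flagged ``euploid_known`` only (>= 3 required); test samples never
    contribute to the anchor. Even-sized medians use the midpoint
    convention. A zero MAD is an error naming the stratum.
    """
    results = []
    for treatment in TREATMENTS:
        stratum = [t for t in cohort if t.treatment == treatment]
        if not stratum:
            continue
        fractions = {id(t): chr21_fraction(t, target) for t in stratum}
        anchor = np.array([fractions[id(t)] for t in stratum if t.euploid_known])
        if anchor.size < 3:
            raise ValidationError(
                f"treatment {treatment!r}: need >= 3 known-euploid samples, "
                f"got {anchor.size}")
        median = float(np.median(anchor))
        mad = float(np.median(np.abs(anchor - median)))
        if scaled_mad:
            mad *= MAD_NORMAL_CONSISTENCY
        if mad == 0:
            raise DegenerateStatisticError(
                f"treatment {treatment!r}: euploid MAD is zero")
        for t in stratum:
            frac = fractions[id(t)]
            results.append(ZScoreResult(t.sample_id, treatment, frac,
                                        (frac - median) / mad, t.euploid_known))
    return results


def enrichment_fold(results: Sequence[ZScoreResult],
                    samples: Sequence[str] | None = None):
    """Per-sample z-score fold change of enrichment, plus a summary.

    fold = z_enriched / z_unenriched for every sample present under both
    treatments (NaN when z_unenriched is 0). The summary reports the mean
    and range over ``samples`` (default: all samples with a finite fold).
    """
    by_sample: dict[str, dict[str, float]] = {}
    for r in results:
        by_sample.setdefault(r.sample_id, {})[r.treatment] = r.z
    rows = []
    for sid, zs in by_sample.items():
        if "unenriched" not in zs or "enriched" not in zs:
            continue
        zu, ze = zs["unenriched"], zs["enriched"]
        fold = ze / zu if zu != 0 else math.nan
        rows.append({"sample_id": sid, "z_unenriched": zu, "z_enriched": ze,
                     "fold": fold})
    table = pd.DataFrame(rows)
    subset = table if samples is None else table[table["sample_id"].isin(samples)]
    folds = subset["fold"].dropna() if len(subset) else pd.Series(dtype=float)
    summary = {
        "mean_fold": float(folds.mean()) if len(folds) else math.nan,
        "min_fold": float(folds.min()) if len(folds) else math.nan,
        "max_fold": float(folds.max()) if len(folds) else math.nan,
        "n": int(len(folds)),
    }
    return table, summary


# ---------------------------------------------------------------------------
# count table I/O (TSV: sample_id, treatment, euploid_known, chrom, count)
# ---------------------------------------------------------------------------

def read_count_table(path) -> list[RegionCountTable]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    required = {"sample_id", "treatment", "euploid_known", "chrom", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"count table missing columns {sorted(missing)}")
    out = []
    for (sid, treatment), sub in df.groupby(["sample_id", "treatment"], sort=True):
        euploid = bool(sub["euploid_known"].iloc[0])
        counts = dict(zip(sub["chrom"], sub["count"].astype(int)))
        out.append(RegionCountTable(sid, treatment, euploid, counts))
    return out


def write_count_table(cohort: Sequence[RegionCountTable], path) -> None:
    rows = []
    for t in cohort:
        for chrom in sorted(t.counts):
            rows.append((t.sample_id, t.treatment, int(t.euploid_known),
                         chrom, int(t.counts[chrom])))
    pd.DataFrame(rows, columns=["sample_id", "treatment", "euploid_known",
                                "chrom", "count"]).to_csv(
        Path(path), sep="\t", index=False)
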