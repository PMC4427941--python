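"""Readers, writers and core containers for methylome data.

Formats handled here:

* **Cytosine report** -- the per-cytosine TSV emitted by bisulfite methylation
  callers: ``chrom, 1-based position, strand (+/-), count methylated,
  count unmethylated, context (CpG/CHG/CHH), trinucleotide``. Positions are
  converted to 0-based on read; everything downstream of this module is
  0-based half-open.
* **BED3+** region files (CpG islands, genes, promoters, histone peaks).
* **Fragment TSV** -- one cfDNA fragment per line: ``chrom, start, end,
  calls`` where ``calls`` is a semicolon-joined list of
  ``offset:context:M|U`` triplets (``.`` when the fragment carries no
  measured cytosine).

The central strand operation is :func:`collapse_strands`: a CpG dinucleotide
yields a C call on the plus strand at position ``p`` and a G-paired C call on
the minus strand at ``p+1``; under the assumption that strand-specific CpG
methylation is rare, both are summed onto the plus-strand coordinate and the
methylation level is recalculated from the summed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import intervals
from .errors import DuplicateRecordError, ParseError, ValidationError

CONTEXTS = ("CpG", "CHG", "CHH")

#: columns of the internal call table
CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth", "included"]

_DEFAULT_TRI = {"CpG": "CGN", "CHG": "CAG", "CHH": "CAT"}


@dataclass(frozen=True)
class CytosineCall:
    """One cytosine's methylated/unmethylated read counts.

    ``pos`` is the 0-based forward-strand coordinate; for a strand-collapsed
    CpG it is the coordinate of the C on the plus strand.
    """

    chrom: str
    pos: int
    context: str
    meth_count: int
    unmeth_count: int
    strand: str = "+"

    def __post_init__(self):
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValidationError("negative methylation counts")

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count


class SampleMethylome:
    """All cytosine calls of one sample, as a sorted table.

    Parameters
    ----------
    calls
        DataFrame with columns ``chrom, pos, strand, context, meth, unmeth``
        and optionally ``included`` (coverage >= ``min_coverage``) and ``tri``.
    sample_id, group
        Identity of the sample; ``group`` is a free label, conventionally one
        of ``non_pregnant_ccf, pregnant_ccf, buffy_coat, placenta, custom``.
    """

    def __init__(self, calls: pd.DataFrame, sample_id: str = "sample",
                 group: str = "custom", min_coverage: int = 1):
        df = calls.copy()
        for col in ("chrom", "pos", "strand", "context", "meth", "unmeth"):
            if col not in df.columns:
                raise ValidationError(f"call table missing column {col!r}")
        df["pos"] = df["pos"].astype(np.int64)
        df["meth"] = df["meth"].astype(np.int64)
        df["unmeth"] = df["unmeth"].astype(np.int64)
        if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
            raise ValidationError("negative methylation counts")
        bad = ~df["context"].isin(CONTEXTS)
        if bad.any():
            raise ValidationError(
                f"unknown context {df.loc[bad, 'context'].iloc[0]!r}")
        if "included" not in df.columns:
            df["included"] = (df["meth"] + df["unmeth"]) >= min_coverage
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        self.calls = df.reset_index(drop=True)
        self.sample_id = sample_id
        self.group = group
        self.min_coverage = int(min_coverage)

    def __len__(self) -> int:
        return len(self.calls)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"SampleMethylome({self.sample_id!r}, group={self.group!r}, "
                f"n_calls={len(self)})")

    def levels(self, context: str = "CpG", included_only: bool = True) -> pd.Series:
        """Per-site methylation fraction meth/(meth+unmeth).

        Returns a Series indexed by (chrom, pos); zero-coverage sites are
        dropped (a level is undefined without reads).
        """
        df = self.calls
        mask = df["context"] == context if context is not None else slice(None)
        df = df[mask]
        if included_only:
            df = df[df["included"]]
        cov = df["meth"] + df["unmeth"]
        df = df[cov > 0]
        lev = df["meth"] / (df["meth"] + df["unmeth"])
        lev.index = pd.MultiIndex.from_arrays(
            [df["chrom"], df["pos"]], names=["chrom", "pos"])
        return lev.rename("level")

    def iter_calls(self) -> Iterable[CytosineCall]:
        for row in self.calls.itertuples(index=False):
            yield CytosineCall(row.chrom, int(row.pos), row.context,
                               int(row.meth), int(row.unmeth), row.strand)


@dataclass
class RegionSet:
    """A named set of 0-based half-open genomic intervals."""

    name: str
    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=intervals.COLS))

    @classmethod
    def from_intervals(cls, name: str, ivs: Iterable[tuple]) -> "RegionSet":
        df = intervals.as_frame(ivs)
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValidationError(f"region set {name!r} has empty/negative intervals")
        return cls(name, df)

    def merged(self) -> "RegionSet":
        return RegionSet(self.name, intervals.merge(self.df))

    @property
    def intervals(self) -> list[tuple]:
        return [tuple(r) for r in self.df.itertuples(index=False)]

    def total_bp(self) -> int:
        m = intervals.merge(self.df)
        return int((m["end"] - m["start"]).sum()) if len(m) else 0

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class FragmentCall:
    """One measured cytosine on a fragment: offset from fragment start."""

    offset: int
    context: str
    methylated: bool


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced cfDNA fragment with its per-cytosine calls."""

    chrom: str
    start: int
    end: int
    calls: tuple = ()

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"fragment {self.chrom}:{self.start}-{self.end} has length <= 0")
        for c in self.calls:
            if not (0 <= c.offset < self.length):
                raise ValidationError(
                    f"call offset {c.offset} outside fragment of length {self.length}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + self.length // 2


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path, min_coverage: int = 1, sample_id: str | None = None,
                         group: str = "custom") -> SampleMethylome:
    """Read a per-cytosine methylation report.

    Input positions are 1-based (caller dialect) and converted to 0-based.
    Lines with coverage below ``min_coverage`` are retained but flagged
    ``included=False`` so they are excluded from statistics. Both strands are
    retained; run :func:`collapse_strands` before CpG-level analyses.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ParseError(path, lineno,
                                 f"expected 7 tab-separated fields, got {len(parts)}")
            chrom, pos_s, strand, meth_s, unmeth_s, context, tri = parts
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            if context not in CONTEXTS:
                raise ParseError(path, lineno, f"unknown context {context!r}")
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer field: {exc}") from None
            if pos < 1:
                raise ParseError(path, lineno, f"1-based position must be >=1, got {pos}")
            if meth < 0 or unmeth < 0:
                raise ParseError(path, lineno, "negative count")
            rows.append((chrom, pos - 1, strand, context, meth, unmeth, tri))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                     "meth", "unmeth", "tri"])
    if sample_id is None:
        sample_id = path.stem
    return SampleMethylome(df, sample_id=sample_id, group=group,
                           min_coverage=min_coverage)


def write_cytosine_report(methylome: SampleMethylome, path) -> None:
    """Write the 7-column cytosine report (positions back to 1-based)."""
    df = methylome.calls
    if "tri" in df.columns:
        tri = df["tri"].fillna(df["context"].map(_DEFAULT_TRI))
    else:
        tri = df["context"].map(_DEFAULT_TRI)
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["pos"] + 1,
        "strand": df["strand"],
        "meth": df["meth"],
        "unmeth": df["unmeth"],
        "context": df["context"],
        "tri": tri,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def collapse_strands(methylome: SampleMethylome) -> SampleMethylome:
    """Sum CpG calls of both strands onto the plus-strand C coordinate.

    A minus-strand CpG call at position ``p`` belongs to the CpG whose
    plus-strand C sits at ``p - 1``. Counts (not levels) are summed, so total
    methylated and unmethylated read counts are conserved and the collapsed
    level is recalculated from pooled reads. Non-CpG contexts pass through
    unchanged. Idempotent: a collapsed methylome has no minus-strand CpG rows.
    """
    df = methylome.calls
    cpg = df[df["context"] == "CpG"]
    rest = df[df["context"] != "CpG"]

    plus = cpg[cpg["strand"] == "+"]
    if plus.duplicated(subset=["chrom", "pos"]).any():
        dup = plus[plus.duplicated(subset=["chrom", "pos"])].iloc[0]
        raise DuplicateRecordError(
            f"duplicate plus-strand CpG record at {dup['chrom']}:{dup['pos']}")
    minus = cpg[cpg["strand"] == "-"].copy()
    if minus.duplicated(subset=["chrom", "pos"]).any():
        dup = minus[minus.duplicated(subset=["chrom", "pos"])].iloc[0]
        raise DuplicateRecordError(
            f"duplicate minus-strand CpG record at {dup['chrom']}:{dup['pos']}")
    minus["pos"] = minus["pos"] - 1

    pooled = (
        pd.concat([plus, minus], ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "unmeth"]]
        .sum()
    )
    pooled["strand"] = "+"
    pooled["context"] = "CpG"
    pooled["included"] = (pooled["meth"] + pooled["unmeth"]) >= methylome.min_coverage
    keep_cols = [c for c in CALL_COLUMNS if c in rest.columns] + (
        ["tri"] if "tri" in rest.columns else [])
    merged = pd.concat([pooled, rest[keep_cols]], ignore_index=True)
    return SampleMethylome(merged, sample_id=methylome.sample_id,
                           group=methylome.group,
                           min_coverage=methylome.min_coverage)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, name: str | None = None, merge: bool = False) -> RegionSet:
    """Read BED3+ into a sorted RegionSet (0-based half-open, as in BED)."""
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "BED line has fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
            if start >= end:
                raise ParseError(path, lineno,
                                 f"start {start} >= end {end} (half-open, empty interval)")
            rows.append((parts[0], start, end))
    rs = RegionSet.from_intervals(name or path.stem, rows)
    return rs.merged() if merge else rs


def write_bed(region_set: RegionSet, path, names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None) -> None:
    """Write BED3 (or BED6 when names/scores are given; strand written '.')."""
    df = region_set.df.copy()
    if names is not None or scores is not None:
        df["name"] = list(names) if names is not None else region_set.name
        df["score"] = list(scores) if scores is not None else 0
        df["strand"] = "."
    df.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(bins: pd.DataFrame, value_column: str, path) -> None:
    """Write a per-bin track (chrom, start, end, value); NaN bins are skipped."""
    df = bins[["chrom", "start", "end", value_column]].dropna(subset=[value_column])
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# fragment TSV
# ---------------------------------------------------------------------------

def read_fragments(path) -> list[FragmentRecord]:
    """Read the fragment TSV: chrom, start, end, ``offset:context:M|U;...``."""
    path = Path(path)
    out = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(path, lineno, "expected 4 tab-separated fields")
            chrom, start_s, end_s, calls_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
            if end <= start:
                raise ParseError(path, lineno, f"end {end} <= start {start}")
            calls = []
            if calls_s != ".":
                for item in calls_s.split(";"):
                    fields = item.split(":")
                    if len(fields) != 3:
                        raise ParseError(path, lineno, f"bad call triplet {item!r}")
                    off_s, context, state = fields
                    if context not in CONTEXTS:
                        raise ParseError(path, lineno, f"unknown context {context!r}")
                    if state not in ("M", "U"):
                        raise ParseError(path, lineno, f"bad call state {state!r}")
                    off = int(off_s)
                    if not (0 <= off < end - start):
                        raise ParseError(
                            path, lineno,
                            f"call offset {off} outside fragment of length {end - start}")
                    calls.append(FragmentCall(off, context, state == "M"))
            out.append(FragmentRecord(chrom, start, end, tuple(calls)))
    return out


def write_fragments(fragments: Iterable[FragmentRecord], path) -> None:
    with Path(path).open("w") as fh:
        for fr in fragments:
            calls = ";".join(
                f"{c.offset}:{c.context}:{'M' if c.methylated else 'U'}"
                for c in fr.calls) or "."
            fh.write(f"{fr.chrom}\t{fr.start}\t{fr.end}\t{calls}\n")


def split_strands(methylome: SampleMethylome, seed: int) -> SampleMethylome:
    """Randomly split collapsed CpG counts back onto two strands.

    Inverse-direction helper for :func:`collapse_strands`: each collapsed
    CpG's reads are assigned to the plus-strand C (position ``p``) or the
    minus-strand C (position ``p+1``) with equal probability. Intended for
    emitting realistic strand-resolved reports from simulated methylomes.
    """
    rng = np.random.default_rng(seed)
    df = methylome.calls
    cpg = df[df["context"] == "CpG"]
    rest = df[df["context"] != "CpG"]
    meth = cpg["meth"].to_numpy()
    unmeth = cpg["unmeth"].to_numpy()
    meth_plus = rng.binomial(meth, 0.5)
    unmeth_plus = rng.binomial(unmeth, 0.5)
    plus = cpg.copy()
    plus["meth"], plus["unmeth"], plus["strand"] = meth_plus, unmeth_plus, "+"
    minus = cpg.copy()
    minus["pos"] = minus["pos"] + 1
    minus["meth"], minus["unmeth"] = meth - meth_plus, unmeth - unmeth_plus
    minus["strand"] = "-"
    both = pd.concat([plus, minus, rest], ignore_index=True)
    both = both[(both["meth"] + both["unmeth"]) > 0]
    return SampleMethylome(both.drop(columns=["included"]),
                           sample_id=methylome.sample_id, group=methylome.group,
                           min_coverage=methylome.min_coverage)
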