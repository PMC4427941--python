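"""Internal half-open interval arithmetic on (chrom, start, end) frames.

All frames use 0-based half-open coordinates, sorted by (chrom, start).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COLS = ["chrom", "start", "end"]


def as_frame(intervals) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        df = intervals[COLS].copy()
    else:
        df = pd.DataFrame(list(intervals), columns=COLS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df.sort_values(COLS, kind="mergesort").reset_index(drop=True)


def merge(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or bookended intervals per chromosome."""
    if len(df) == 0:
        return df.copy()
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # running maximum of ends; a new block starts where start > max(prev ends)
        keep_s, keep_e = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= keep_e[-1]:
                keep_e[-1] = max(keep_e[-1], e)
            else:
                keep_s.append(s)
                keep_e.append(e)
        out.append(pd.DataFrame({"chrom": chrom, "start": keep_s, "end": keep_e}))
    return pd.concat(out, ignore_index=True)


def _per_chrom_arrays(df: pd.DataFrame):
    merged = merge(df)
    return {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in merged.groupby("chrom", sort=False)
    }


def overlaps_any(queries: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each query interval overlap >=1 bp of any target?"""
    lookup = _per_chrom_arrays(targets)
    out = np.zeros(len(queries), dtype=bool)
    qc = queries["chrom"].to_numpy()
    qs = queries["start"].to_numpy()
    qe = queries["end"].to_numpy()
    for chrom, (ts, te) in lookup.items():
        sel = np.flatnonzero(qc == chrom)
        if sel.size == 0:
            continue
        # merged targets are disjoint & sorted: the only candidate is the last
        # target starting strictly before the query end
        idx = np.searchsorted(ts, qe[sel], side="left") - 1
        ok = idx >= 0
        hit = np.zeros(sel.size, dtype=bool)
        hit[ok] = te[idx[ok]] > qs[sel][ok]
        out[sel] = hit
    return out


def points_in(chroms: np.ndarray, positions: np.ndarray, targets: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each point fall inside any target interval (half-open)?"""
    lookup = _per_chrom_arrays(targets)
    out = np.zeros(len(positions), dtype=bool)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    for chrom, (ts, te) in lookup.items():
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        idx = np.searchsorted(ts, positions[sel], side="right") - 1
        ok = idx >= 0
        hit = np.zeros(sel.size, dtype=bool)
        hit[ok] = te[idx[ok]] > positions[sel][ok]
        out[sel] = hit
    return out
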