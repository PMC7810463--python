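"""Genomic interval arithmetic on BED-convention coordinates.

All intervals are 0-based, half-open ``[start, end)``. Interval sets are
plain pandas DataFrames with at least the columns ``chrom``, ``start``,
``end`` (and usually ``name``), which keeps every stage a file-roundtrip
away from plain BED text.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name"]


def validate_intervals(df: pd.DataFrame) -> None:
    """Raise ValueError on malformed intervals (start >= end or negative)."""
    if len(df) == 0:
        return
    if (df["start"] < 0).any():
        raise ValueError("negative interval start")
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(
            f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']} (start >= end)"
        )


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended intervals into a maximal disjoint union.

    Book-ended means gap 0: ``[10,20)`` and ``[20,30)`` fuse to ``[10,30)``
    (the bedtools ``merge`` default). Output is sorted by (chrom, start) and
    pairwise disjoint with positive gaps.
    """
    validate_intervals(df)
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_start, cur_end = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, e)
            else:
                out.append((chrom, cur_start, cur_end))
                cur_start, cur_end = s, e
        out.append((chrom, cur_start, cur_end))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def extend_to_min_length(
    start: int, end: int, min_length: int, chrom_size: int
) -> tuple[int, int]:
    """Extend a short interval symmetrically about its midpoint to ``min_length``.

    Intervals already >= ``min_length`` are returned unchanged. The extension
    is split evenly between the two sides, with an odd remainder going to the
    right; if a side hits a chromosome boundary the deficit is pushed to the
    other side, so the result has exactly ``min_length`` bases whenever the
    chromosome allows it.
    """
    if start < 0 or start >= end:
        raise ValueError(f"invalid interval [{start},{end})")
    if min_length > chrom_size:
        raise ValueError(f"min_length {min_length} exceeds chrom size {chrom_size}")
    length = end - start
    if length >= min_length:
        return start, end
    extra = min_length - length
    left = extra // 2
    right = extra - left
    new_start = start - left
    new_end = end + right
    if new_start < 0:
        new_end += -new_start
        new_start = 0
    if new_end > chrom_size:
        new_start -= new_end - chrom_size
        new_end = chrom_size
        new_start = max(new_start, 0)
    return new_start, new_end


def extend_intervals(
    df: pd.DataFrame, min_length: int, chrom_sizes: dict[str, int]
) -> pd.DataFrame:
    """Apply :func:`extend_to_min_length` row-wise."""
    out = df.copy()
    coords = [
        extend_to_min_length(s, e, min_length, chrom_sizes[c])
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
    out["start"] = [c[0] for c in coords]
    out["end"] = [c[1] for c in coords]
    return out


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it share >= 1 bp with any subject interval?

    Half-open semantics, so book-ended intervals do NOT overlap. Runs in
    O((n + m) log m) via a prefix-max sweep over subjects sorted by start.
    """
    validate_intervals(query)
    validate_intervals(subject)
    result = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return result
    subj_by_chrom = {
        chrom: grp.sort_values("start") for chrom, grp in subject.groupby("chrom")
    }
    q_chrom = query["chrom"].to_numpy()
    q_start = query["start"].to_numpy()
    q_end = query["end"].to_numpy()
    for chrom, sg in subj_by_chrom.items():
        pos = np.flatnonzero(q_chrom == chrom)
        if len(pos) == 0:
            continue
        s_starts = sg["start"].to_numpy()
        s_end_cummax = np.maximum.accumulate(sg["end"].to_numpy())
        # subject overlaps query iff subject.start < q.end and subject.end > q.start
        idx = np.searchsorted(s_starts, q_end[pos], side="left")
        hit = np.zeros(len(pos), dtype=bool)
        nz = idx > 0
        hit[nz] = s_end_cummax[idx[nz] - 1] > q_start[pos][nz]
        result[pos] = hit
    return result


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end[, name, ...]).

    An empty file yields an empty three-column frame.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    ncol = df.shape[1]
    names = ["chrom", "start", "end", "name", "score", "strand"][:ncol]
    df.columns = names + list(df.columns[len(names):])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    validate_intervals(df)
    return df


def write_bed(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    cols = columns or [c for c in BED_COLUMNS + ["score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
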