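"""Replication-origin interval analytics on BED / narrowPeak peak sets.

Origins mapped by short-nascent-strand sequencing arrive as peak intervals.
This module provides the downstream analytics: distance-window clustering
(bedtools-merge ``-d`` semantics: intervals on the same chromosome whose gap
is at most the window are merged into their span), inter-origin distances
(IOD, the distance between mid positions of consecutive peaks within a
chromosome), between-set overlap statistics, and cluster-count profiles over
windows (10/20/30 kb by default).

Intervals are 0-based half-open; ``mid = floor((start + end) / 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_WINDOWS = (10_000, 20_000, 30_000)


@dataclass
class OriginSet:
    """Sorted, duplicate-free genomic intervals (chrom, start, end)."""

    intervals: pd.DataFrame  # columns chrom, start, end (sorted)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OriginSet":
        df = df[["chrom", "start", "end"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df.index[(df["start"] >= df["end"])][0]
            raise ValueError(f"interval with start >= end at row {bad}")
        df = df.drop_duplicates().sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        return cls(df)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def mids(self) -> pd.DataFrame:
        df = self.intervals.copy()
        df["mid"] = (df["start"] + df["end"]) // 2
        return df

    def to_bed(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_peaks(path) -> OriginSet:
    """Read a BED or ENCODE narrowPeak file into an OriginSet.

    Only chrom/start/end are used; extra narrowPeak columns are tolerated.
    Malformed lines raise with their line number.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path.name}:{ln}: expected at least 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path.name}:{ln}: non-integer coordinates") from e
            if start >= end:
                raise ValueError(f"{path.name}:{ln}: start >= end ({start} >= {end})")
            rows.append((parts[0], start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if df.empty:
        return OriginSet(pd.DataFrame(columns=["chrom", "start", "end"]).astype({"start": np.int64, "end": np.int64}))
    return OriginSet.from_frame(df)


def merge_origins(origins: OriginSet, window: int) -> OriginSet:
    """Merge intervals whose same-chromosome gap is <= window into their span.

    Matches distance-``d`` interval merging: touching or closer-than-window
    intervals coalesce; output intervals are sorted, non-overlapping and have
    pairwise gaps > window.  The operation is idempotent.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if len(origins) == 0:
        return OriginSet(origins.intervals.copy())
    out = []
    for chrom, grp in origins.intervals.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= window:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return OriginSet(pd.DataFrame(out, columns=["chrom", "start", "end"]))


@dataclass
class IODStats:
    """Inter-origin distances: per-chromosome gap lists plus pooled summaries."""

    gaps: pd.DataFrame  # columns chrom, gap (bp)
    mean: float
    median: float
    n: int
    per_chromosome: pd.DataFrame = field(default_factory=pd.DataFrame)


def inter_origin_distances(origins: OriginSet) -> IODStats:
    """Distances between mid positions of consecutive peaks, per chromosome.

    Gaps never cross chromosome boundaries; the mean/median pool all
    chromosomes.  An empty or single-peak set yields n = 0.
    """
    rows = []
    mids = origins.mids
    for chrom, grp in mids.groupby("chrom", sort=True):
        m = np.sort(grp["mid"].to_numpy())
        for g in np.diff(m):
            rows.append((chrom, int(g)))
    gaps = pd.DataFrame(rows, columns=["chrom", "gap"])
    if gaps.empty:
        return IODStats(gaps, float("nan"), float("nan"), 0, pd.DataFrame(columns=["chrom", "mean", "median", "n"]))
    per_chrom = (
        gaps.groupby("chrom")["gap"].agg(["mean", "median", "count"]).rename(columns={"count": "n"}).reset_index()
    )
    return IODStats(
        gaps=gaps,
        mean=float(gaps["gap"].mean()),
        median=float(gaps["gap"].median()),
        n=len(gaps),
        per_chromosome=per_chrom,
    )


def origin_overlap(set_a: OriginSet, set_b: OriginSet) -> dict:
    """Between-set overlap: counts/percentages in both directions plus union stats.

    shared(a→b) counts a-intervals intersecting >= 1 b-interval by >= 1 bp
    (half-open semantics).  The union-based percentage supports Euler-style
    reporting when the reference set of a published percentage is ambiguous.
    """
    n_ab = _count_overlapping(set_a, set_b)
    n_ba = _count_overlapping(set_b, set_a)
    n_a, n_b = len(set_a), len(set_b)
    union = n_a + n_b - n_ab  # a-intervals hitting b collapse with their partners
    return {
        "n_a": n_a,
        "n_b": n_b,
        "shared_a_in_b": n_ab,
        "shared_b_in_a": n_ba,
        "pct_a_in_b": 100.0 * n_ab / n_a if n_a else 0.0,
        "pct_b_in_a": 100.0 * n_ba / n_b if n_b else 0.0,
        "pct_of_union": 100.0 * n_ab / union if union else 0.0,
    }


def _count_overlapping(set_a: OriginSet, set_b: OriginSet) -> int:
    """Count a-intervals with >= 1 bp intersection with some b-interval (sweep)."""
    count = 0
    b_by_chrom = dict(tuple(set_b.intervals.groupby("chrom", sort=False)))
    for chrom, grp in set_a.intervals.groupby("chrom", sort=False):
        if chrom not in b_by_chrom:
            continue
        b = b_by_chrom[chrom]
        b_starts = b["start"].to_numpy()
        b_ends = b["end"].to_numpy()
        # b is sorted by start; for each a-interval find candidate b-intervals
        max_end = np.maximum.accumulate(b_ends)
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            i = np.searchsorted(b_starts, e)  # b intervals starting before a ends
            if i == 0:
                continue
            if max_end[i - 1] > s:  # some earlier b interval reaches past a's start
                # confirm with a scan over the candidate block (rarely long)
                if np.any((b_starts[:i] < e) & (b_ends[:i] > s)):
                    count += 1
    return count


def cluster_count_profile(origins: OriginSet, windows: Sequence[int] = DEFAULT_WINDOWS) -> pd.DataFrame:
    """Merged-set sizes at each clustering window (counts non-increasing)."""
    if list(windows) != sorted(windows):
        raise ValueError("windows must be sorted ascending")
    rows = [{"window": 0, "n_origins": len(origins)}]
    for w in windows:
        rows.append({"window": int(w), "n_origins": len(merge_origins(origins, int(w)))})
    return pd.DataFrame(rows)
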