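"""Classified genomic intervals (DomainSet) and interval arithmetic.

Coordinates are 0-based half-open throughout, matching BED conventions.
Domains carry one of two classes: ``class1`` (intermediate H3K9me2 density)
and ``class2`` (high density). Background and blacklist regions are never
part of a DomainSet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASS1 = "class1"
CLASS2 = "class2"
DOMAIN_CLASSES = (CLASS1, CLASS2)

_COLUMNS = ["chrom", "start", "end", "domain_class"]


@dataclass(frozen=True)
class DomainSet:
    """Sorted, non-overlapping classified intervals.

    The backing frame has columns ``chrom``, ``start``, ``end``,
    ``domain_class`` and is sorted by (chrom, start). Intervals never
    overlap within the set (adjacent intervals of different class may touch).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if list(df.columns) != _COLUMNS:
            raise ValueError(f"DomainSet frame must have columns {_COLUMNS}")
        if len(df) == 0:
            return
        if not df["domain_class"].isin(DOMAIN_CLASSES).all():
            bad = sorted(set(df["domain_class"]) - set(DOMAIN_CLASSES))
            raise ValueError(f"unknown domain classes: {bad}")
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        # sorted and non-overlapping within each chromosome
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not (starts[1:] >= ends[:-1]).all():
                raise ValueError(f"overlapping or unsorted intervals on {chrom}")

    @classmethod
    def from_records(cls, records) -> "DomainSet":
        """Build from (chrom, start, end, domain_class) tuples; sorts them."""
        df = pd.DataFrame(list(records), columns=_COLUMNS)
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        return cls(df)

    @classmethod
    def empty(cls) -> "DomainSet":
        return cls(pd.DataFrame(columns=_COLUMNS).astype(
            {"start": np.int64, "end": np.int64}))

    @property
    def is_empty(self) -> bool:
        return len(self.df) == 0

    def __len__(self) -> int:
        return len(self.df)

    def class_bp(self) -> dict[str, int]:
        """Total bp per class."""
        out = {c: 0 for c in DOMAIN_CLASSES}
        if not self.is_empty:
            widths = self.df["end"] - self.df["start"]
            for c, bp in widths.groupby(self.df["domain_class"]).sum().items():
                out[str(c)] = int(bp)
        return out

    @property
    def total_bp(self) -> int:
        return int(sum(self.class_bp().values()))

    def chrom_intervals(self, chrom: str, merged: bool = False) -> np.ndarray:
        """(n, 2) start/end array for one chromosome, class-agnostic.

        With ``merged=True``, touching intervals are coalesced.
        """
        sub = self.df[self.df["chrom"] == chrom]
        iv = sub[["start", "end"]].to_numpy(dtype=np.int64).reshape(-1, 2)
        return merge_touching(iv) if merged else iv

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def contiguous_lengths(self) -> np.ndarray:
        """Lengths of contiguous domain tracts, class-agnostic.

        Adjacent class1/class2 intervals count as one tract, matching how
        the contiguous length of an H3K9me2 domain is measured.
        """
        lengths: list[int] = []
        for chrom in self.chroms():
            merged = self.chrom_intervals(chrom, merged=True)
            lengths.extend((merged[:, 1] - merged[:, 0]).tolist())
        return np.asarray(lengths, dtype=np.int64)

    def select_class(self, domain_class: str) -> "DomainSet":
        return DomainSet(self.df[self.df["domain_class"] == domain_class]
                         .reset_index(drop=True))

    def to_bed(self, path) -> None:
        """Write BED4 (name column = class)."""
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.domain_class}\n")

    @classmethod
    def from_bed(cls, path) -> "DomainSet":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED4 requires 4 columns")
                try:
                    records.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
        return cls.from_records(records)


def merge_touching(intervals: np.ndarray) -> np.ndarray:
    """Coalesce sorted intervals that touch or overlap. Input (n, 2)."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> int:
    """Total overlap bp between two sorted non-overlapping interval arrays."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += hi - lo
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return int(total)


def bp_jaccard(a: DomainSet, b: DomainSet) -> float:
    """Class-agnostic bp-level Jaccard index between two domain sets."""
    inter = 0
    a_bp = b_bp = 0
    for chrom in set(a.chroms()) | set(b.chroms()):
        ia = a.chrom_intervals(chrom, merged=True)
        ib = b.chrom_intervals(chrom, merged=True)
        a_bp += int((ia[:, 1] - ia[:, 0]).sum())
        b_bp += int((ib[:, 1] - ib[:, 0]).sum())
        inter += _intersect_arrays(ia, ib)
    union = a_bp + b_bp - inter
    return inter / union if union else float("nan")


def overlap_bp(intervals: np.ndarray, start: int, end: int) -> int:
    """Overlap of [start, end) with a sorted non-overlapping interval array."""
    if len(intervals) == 0 or end <= start:
        return 0
    lo = np.clip(intervals[:, 0], start, end)
    hi = np.clip(intervals[:, 1], start, end)
    return int(np.maximum(hi - lo, 0).sum())
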