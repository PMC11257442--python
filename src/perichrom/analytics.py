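"""Domain statistics, cross-condition sharing, meta-domain profiles, dispersion.

These are the descriptive layers over called domain sets: per-class counts
and bp coverage, the fraction of the genome inside domains, contiguous
domain tract lengths, UpSet-style sharing of domains between conditions,
scaled meta-domain signal profiles, and signal dispersion within regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import DOMAIN_CLASSES, DomainSet
from .layout import GenomeLayout
from .tracks import BinnedTrack


@dataclass(frozen=True)
class DomainStats:
    """Per-class and combined domain statistics."""

    per_class: pd.DataFrame  # index: class; columns: count, total_bp, min/median/max length
    coverage_fraction: float
    median_contiguous_bp: float  # NaN when there are no domains

    def to_tsv(self, path) -> None:
        self.per_class.to_csv(path, sep="\t")


@dataclass(frozen=True)
class SharingTable:
    """Membership-pattern partition of the union of condition domain sets."""

    df: pd.DataFrame  # one bool column per condition + bp (+ n_regions)
    conditions: tuple[str, ...]
    mode: str

    @property
    def union_bp(self) -> int:
        return int(self.df["bp"].sum()) if "bp" in self.df else 0

    @property
    def shared_all_fraction(self) -> float:
        """Fraction of the union present in every condition (bp mode)."""
        mask = np.ones(len(self.df), dtype=bool)
        for c in self.conditions:
            mask &= self.df[c].to_numpy()
        total = self.df["bp"].sum()
        return float(self.df.loc[mask, "bp"].sum() / total) if total else float("nan")

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def domain_stats(domains: DomainSet, layout: GenomeLayout) -> DomainStats:
    """Exact bp accounting per class plus genome coverage fraction.

    The median contiguous length is over class-agnostic tracts (touching
    class1/class2 intervals coalesced). An empty set reports coverage 0 and
    a missing (NaN) median.
    """
    for row in domains.df.itertuples(index=False):
        if row.chrom not in layout or row.end > layout.length(row.chrom):
            raise ValueError(f"interval {row.chrom}:{row.start}-{row.end} exceeds layout")
    rows = {}
    for klass in DOMAIN_CLASSES:
        sub = domains.select_class(klass)
        widths = (sub.df["end"] - sub.df["start"]).to_numpy()
        rows[klass] = {
            "count": len(widths),
            "total_bp": int(widths.sum()) if len(widths) else 0,
            "min_bp": int(widths.min()) if len(widths) else np.nan,
            "median_bp": float(np.median(widths)) if len(widths) else np.nan,
            "max_bp": int(widths.max()) if len(widths) else np.nan,
        }
    per_class = pd.DataFrame(rows).T
    coverage = domains.total_bp / layout.total_bp
    tracts = domains.contiguous_lengths()
    median_tract = float(np.median(tracts)) if len(tracts) else float("nan")
    return DomainStats(per_class, float(coverage), median_tract)


def condition_sharing(domain_sets: dict[str, DomainSet], mode: str = "bp",
                      reciprocal_threshold: float = 0.5) -> SharingTable:
    """UpSet-style sharing of domains across conditions.

    ``bp`` mode partitions the union of all (class-agnostic, coalesced)
    domains by membership pattern and reports bp per pattern. ``domain``
    mode counts whole domains per pattern, where a domain belongs to another
    condition's pattern when some domain there reciprocally overlaps it by
    at least ``reciprocal_threshold`` of both lengths.
    """
    if len(domain_sets) < 2:
        raise ValueError("need at least two conditions")
    conditions = tuple(domain_sets)
    if mode == "bp":
        return _sharing_bp(domain_sets, conditions)
    if mode == "domain":
        return _sharing_domains(domain_sets, conditions, reciprocal_threshold)
    raise ValueError(f"unknown sharing mode {mode!r}")


def _sharing_bp(domain_sets, conditions):
    chroms: list[str] = []
    for ds in domain_sets.values():
        chroms.extend(ds.chroms())
    chroms = list(dict.fromkeys(chroms))
    acc: dict[tuple[bool, ...], list[int]] = {}
    for chrom in chroms:
        per_cond = [domain_sets[c].chrom_intervals(chrom, merged=True)
                    for c in conditions]
        bounds = np.unique(np.concatenate([iv.ravel() for iv in per_cond] or
                                          [np.array([], dtype=np.int64)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            pattern = tuple(_covers(iv, lo) for iv in per_cond)
            if not any(pattern):
                continue
            ent = acc.setdefault(pattern, [0, 0])
            ent[0] += int(hi - lo)
            ent[1] += 1
    rows = [{**dict(zip(conditions, pat)), "bp": bp, "n_regions": n}
            for pat, (bp, n) in sorted(acc.items(), reverse=True)]
    df = pd.DataFrame(rows, columns=[*conditions, "bp", "n_regions"])
    return SharingTable(df, conditions, "bp")


def _covers(intervals: np.ndarray, pos: int) -> bool:
    idx = np.searchsorted(intervals[:, 0], pos, side="right") - 1
    return idx >= 0 and intervals[idx, 1] > pos


def _sharing_domains(domain_sets, conditions, threshold):
    rows = []
    for cond in conditions:
        ds = domain_sets[cond]
        counts: dict[tuple[bool, ...], int] = {}
        for chrom in ds.chroms():
            own = ds.chrom_intervals(chrom, merged=True)
            others = {c: domain_sets[c].chrom_intervals(chrom, merged=True)
                      for c in conditions}
            for s, e in own:
                pattern = tuple(
                    c == cond or _reciprocal_hit(others[c], s, e, threshold)
                    for c in conditions)
                counts[pattern] = counts.get(pattern, 0) + 1
        for pat, n in sorted(counts.items(), reverse=True):
            rows.append({"condition": cond, **dict(zip(conditions, pat)),
                         "n_domains": n})
    df = pd.DataFrame(rows, columns=["condition", *conditions, "n_domains"])
    return SharingTable(df, conditions, "domain")


def _reciprocal_hit(intervals: np.ndarray, start: int, end: int,
                    threshold: float) -> bool:
    length = end - start
    for s, e in intervals:
        if s >= end:
            break
        ov = min(e, end) - max(s, start)
        if ov > 0 and ov >= threshold * length and ov >= threshold * (e - s):
            return True
    return False


def meta_domain_profile(track: BinnedTrack, domains: DomainSet,
                        body_bins: int = 100, flank_bp: int = 50_000) -> np.ndarray:
    """Mean scaled signal profile across domains with fixed-width flanks.

    Each domain body is resampled to ``body_bins`` positions by linear
    interpolation of its bin values; ``flank_bp`` of native-resolution bins
    is appended on each side. Positions beyond chromosome ends are excluded
    from the mean. Returns a vector of length ``2*flank_bins + body_bins``.
    """
    if domains.is_empty:
        raise ValueError("meta profile of an empty DomainSet")
    bin_size = track.bin_size
    n_flank = flank_bp // bin_size
    profiles = []
    for row in domains.df.itertuples(index=False):
        v = track.values[row.chrom]
        first = row.start // bin_size
        last = max(first + 1, -(-row.end // bin_size))
        body = v[first:last]
        if len(body) == 1:
            resampled = np.full(body_bins, float(body[0]))
        else:
            resampled = np.interp(np.linspace(0, len(body) - 1, body_bins),
                                  np.arange(len(body)), body)
        left = np.full(n_flank, np.nan)
        right = np.full(n_flank, np.nan)
        lo = first - n_flank
        left_vals = v[max(lo, 0):first]
        if len(left_vals):
            left[n_flank - len(left_vals):] = left_vals
        right_vals = v[last:last + n_flank]
        if len(right_vals):
            right[:len(right_vals)] = right_vals
        profiles.append(np.concatenate([left, resampled, right]))
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.vstack(profiles), axis=0)


def signal_dispersion(track: BinnedTrack, regions: DomainSet | None = None,
                      whole_genome: bool = False) -> tuple[float, float]:
    """Mean and population sd of bin values whose midpoints fall in regions.

    With ``whole_genome=True`` all bins are used, which equals passing a
    DomainSet covering the full layout.
    """
    if whole_genome:
        values = track.concat()
    else:
        if regions is None or regions.is_empty:
            raise ValueError("regions required unless whole_genome=True")
        parts = []
        for chrom in track.layout.names:
            iv = regions.chrom_intervals(chrom, merged=True)
            if len(iv) == 0:
                continue
            v = track.values[chrom]
            starts = np.arange(len(v)) * track.bin_size
            ends = np.minimum(starts + track.bin_size, track.layout.length(chrom))
            mids = (starts + ends) / 2  # terminal partial bin uses its true midpoint
            idx = np.searchsorted(iv[:, 0], mids, side="right") - 1
            inside = (idx >= 0) & (mids < iv[np.clip(idx, 0, None), 1])
            parts.append(v[inside])
        values = np.concatenate(parts) if parts else np.array([])
    if len(values) == 0:
        return float("nan"), float("nan")
    return float(np.mean(values)), float(np.std(values))
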