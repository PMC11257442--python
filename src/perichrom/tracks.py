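"""Binned coverage tracks: spike-in scaling, rebinning, replicate averaging.

A :class:`BinnedTrack` holds one nonnegative value per fixed-size bin per
chromosome (the last bin of a chromosome may span fewer bp). Values arrive
on whatever per-bin unit the upstream coverage tool produced (typically
RPKM); spike-in scaling is a multiplicative factor applied on top, so the
order of the two normalizations is irrelevant.

Spike-in scale factors follow the CUT&RUN convention of dividing a fixed
constant (30,000) by the number of properly paired spike-in reads, so that
libraries with more spike-in signal are scaled down.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .layout import GenomeLayout

DEFAULT_SPIKE_CONSTANT = 30_000

#: normalization provenance values a track may carry
PROVENANCES = ("raw", "rpkm", "spikein_rpkm", "averaged")


@dataclass(frozen=True)
class SpikeInScale:
    """Spike-in scale factor: ``constant / spike_reads``."""

    spike_reads: int
    constant: int = DEFAULT_SPIKE_CONSTANT
    factor: float = field(init=False)

    def __post_init__(self) -> None:
        if self.spike_reads <= 0:
            raise ValueError("spike_reads must be a positive integer")
        if self.constant <= 0:
            raise ValueError("constant must be positive")
        object.__setattr__(self, "factor", self.constant / self.spike_reads)


def compute_scale_factor(spike_reads: int, constant: int = DEFAULT_SPIKE_CONSTANT) -> SpikeInScale:
    """Spike-in scale factor for one library.

    Parameters
    ----------
    spike_reads
        Properly paired reads aligned to the spike-in genome; must be > 0.
    constant
        Arbitrary fixed numerator shared by all libraries (default 30,000).
    """
    return SpikeInScale(spike_reads=spike_reads, constant=constant)


@dataclass(frozen=True)
class BinnedTrack:
    """Per-chromosome vectors of binned, nonnegative signal.

    ``values[chrom]`` has ``ceil(chrom_length / bin_size)`` entries.
    ``meta`` records condition, replicate and normalization provenance.
    """

    layout: GenomeLayout
    bin_size: int
    values: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if set(self.values) != set(self.layout.names):
            raise ValueError("track chromosomes do not match layout")
        for chrom in self.layout.names:
            v = self.values[chrom]
            expect = self.layout.n_bins(chrom, self.bin_size)
            if len(v) != expect:
                raise ValueError(
                    f"{chrom}: expected {expect} bins of {self.bin_size} bp, got {len(v)}")
            if not np.isfinite(v).all():
                raise ValueError(f"{chrom}: non-finite values")
            if (v < 0).any():
                raise ValueError(f"{chrom}: negative values")

    @property
    def provenance(self) -> str:
        return self.meta.get("normalization", "raw")

    def concat(self) -> np.ndarray:
        """All values in genome order as one vector."""
        return np.concatenate([self.values[c] for c in self.layout.names])

    @property
    def n_bins(self) -> int:
        return sum(len(self.values[c]) for c in self.layout.names)

    def bin_interval(self, chrom: str, i: int) -> tuple[int, int]:
        """bp interval [start, end) of bin ``i`` (end clipped at chrom length)."""
        start = i * self.bin_size
        return start, min(start + self.bin_size, self.layout.length(chrom))


def normalize_track(track: BinnedTrack, scale: SpikeInScale) -> BinnedTrack:
    """Apply a spike-in scale factor multiplicatively.

    Raises if the track is already spike-in normalized (double scaling).
    """
    if track.provenance not in ("raw", "rpkm"):
        raise ValueError(
            f"track is already {track.provenance!r}; refusing to scale twice")
    values = {c: v * scale.factor for c, v in track.values.items()}
    meta = dict(track.meta)
    meta["normalization"] = "spikein_rpkm"
    meta["spikein_factor"] = scale.factor
    return replace(track, values=values, meta=meta)


def rebin(track: BinnedTrack, target_bin: int) -> BinnedTrack:
    """Rebin to a coarser resolution; target must be a multiple of the source.

    Each target bin takes the mean of its constituent source bins; a partial
    trailing window averages only over the source bins that exist.
    """
    if target_bin <= 0 or target_bin % track.bin_size != 0:
        raise ValueError(
            f"target bin {target_bin} is not a positive multiple of {track.bin_size}")
    k = target_bin // track.bin_size
    if k == 1:
        return replace(track, meta=dict(track.meta))
    values = {}
    for chrom, v in track.values.items():
        n_out = -(-len(v) // k)
        sums = np.add.reduceat(v, np.arange(0, len(v), k))
        counts = np.full(n_out, k)
        if len(v) % k:
            counts[-1] = len(v) % k
        values[chrom] = sums / counts
    return BinnedTrack(track.layout, target_bin, values, dict(track.meta))


def average_replicates(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Per-bin arithmetic mean across replicate tracks."""
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.layout != first.layout or t.bin_size != first.bin_size:
            raise ValueError("replicate tracks must share layout and bin size")
    values = {
        c: np.mean([t.values[c] for t in tracks], axis=0)
        for c in first.layout.names
    }
    meta = {k: v for k, v in first.meta.items() if k != "replicate"}
    meta["normalization"] = "averaged"
    meta["n_replicates"] = len(tracks)
    return BinnedTrack(first.layout, first.bin_size, values, meta)


# ---------------------------------------------------------------------------
# I/O

def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a 4-column bedGraph (one row per bin, 0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in track.layout.names:
            v = track.values[chrom]
            for i, x in enumerate(v):
                start, end = track.bin_interval(chrom, i)
                fh.write(f"{chrom}\t{start}\t{end}\t{x:.6g}\n")


def read_bedgraph(path, layout: GenomeLayout, bin_size: int,
                  meta: dict | None = None) -> BinnedTrack:
    """Read a 4-column bedGraph into a binned track.

    Intervals must align to the bin grid (an interval may span several whole
    bins, which all receive its value); uncovered bins are 0, matching
    bedGraph gap semantics. Malformed lines raise with file and line number.
    """
    values = {c: np.zeros(layout.n_bins(c, bin_size)) for c in layout.names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = fields[0]
            if chrom not in layout:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph record") from exc
            if start % bin_size:
                raise ValueError(
                    f"{path}:{lineno}: interval start {start} not on the {bin_size}-bp grid")
            if end > layout.length(chrom):
                raise ValueError(f"{path}:{lineno}: interval exceeds chromosome length")
            first = start // bin_size
            last = -(-end // bin_size)
            values[chrom][first:last] = value
    return BinnedTrack(layout, bin_size, values, dict(meta or {}))


def write_bigwig(track: BinnedTrack, path) -> None:
    """Write the track as bigWig (requires pyBigWig)."""
    import pyBigWig  # optional dependency

    bw = pyBigWig.open(str(path), "w")
    bw.addHeader([(c, track.layout.length(c)) for c in track.layout.names])
    for chrom in track.layout.names:
        v = track.values[chrom]
        starts = np.arange(len(v)) * track.bin_size
        ends = np.minimum(starts + track.bin_size, track.layout.length(chrom))
        bw.addEntries([chrom] * len(v), starts.tolist(),
                      ends=ends.tolist(), values=v.astype(float).tolist())
    bw.close()


def read_bigwig(path, layout: GenomeLayout, bin_size: int,
                meta: dict | None = None) -> BinnedTrack:
    """Read a bigWig into a binned track (mean per bin; requires pyBigWig)."""
    import pyBigWig  # optional dependency

    bw = pyBigWig.open(str(path))
    values = {}
    for chrom in layout.names:
        n = layout.n_bins(chrom, bin_size)
        stats = bw.stats(chrom, 0, layout.length(chrom), nBins=n, type="mean")
        values[chrom] = np.array([0.0 if s is None else s for s in stats])
    bw.close()
    return BinnedTrack(layout, bin_size, values, dict(meta or {}))
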