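"""Genome layout: ordered chromosome names and lengths."""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths in bp.

    Parameters
    ----------
    names
        Chromosome names in genome order; must be unique.
    lengths
        Chromosome lengths in bp, parallel to ``names``; all > 0.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def length(self, chrom: str) -> int:
        return self.lengths[self._index[chrom]]

    @property
    def total_bp(self) -> int:
        return sum(self.lengths)

    def n_bins(self, chrom: str, bin_size: int) -> int:
        """Number of bins of ``bin_size`` covering ``chrom`` (last may be partial)."""
        return math.ceil(self.length(chrom) / bin_size)

    def total_bins(self, bin_size: int) -> int:
        return sum(self.n_bins(c, bin_size) for c in self.names)

    @classmethod
    def from_file(cls, path) -> "GenomeLayout":
        """Read a two-column chrom.sizes TSV (name, length)."""
        names: list[str] = []
        lengths: list[int] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
                try:
                    lengths.append(int(fields[1]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from exc
                names.append(fields[0])
        return cls(tuple(names), tuple(lengths))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.names, self.lengths):
                fh.write(f"{name}\t{length}\n")
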