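"""Per-copy transposable-element derepression calling.

Individual TE copies (e.g. of the young LINE-1 family L1MdA_I) are
quantified from uniquely-assignable read counts. A copy is called
derepressed between two conditions when its size-factor-normalized fold
change (with a pseudocount of one normalized count) reaches the fold
threshold (>= 10 by default, matching "upregulated at least 10-fold") AND
the expression difference is significant after Benjamini-Hochberg
adjustment. H3K9me2 enrichment on up-called versus unchanged copies is then
contrasted with a Kruskal-Wallis / Dunn comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .genes import CountsMatrix, GroupComparison, compare_groups, normalize_counts, welch_de_table


@dataclass(frozen=True)
class TECopy:
    """One genomic copy of a TE family."""

    copy_id: str
    family: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.copy_id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_te_bed(path) -> list[TECopy]:
    """Read TE copies from BED6 (name = ``copy_id:family`` or just copy id)."""
    copies = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns")
            name = f[3]
            copy_id, _, family = name.partition(":")
            strand = f[5] if len(f) > 5 else "+"
            copies.append(TECopy(copy_id, family or "unknown", f[0],
                                 int(f[1]), int(f[2]), strand))
    return copies


def call_derepressed(copies: list[TECopy], counts: CountsMatrix,
                     cond_a: str, cond_b: str, fold_threshold: float = 10.0,
                     alpha: float = 0.05, strict: bool = False,
                     de_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Call per-copy derepression of condition B relative to condition A.

    Returns one row per copy present in the counts: normalized means, fold
    change ((mean_b + 1) / (mean_a + 1)), pvalue/padj, and ``called`` which
    is "up" when fold >= fold_threshold (strictly > with ``strict=True``)
    and padj < alpha, else "unchanged". An externally computed DE table
    (columns fold/padj or log2FoldChange/padj) may be injected via
    ``de_table``; otherwise the built-in Welch stand-in is used. Copies
    absent from the counts are excluded with a warning.
    """
    ids = [c.copy_id for c in copies]
    present = [i for i in ids if i in counts.counts.index]
    missing = len(ids) - len(present)
    if missing:
        warnings.warn(f"{missing} TE copies absent from counts table; excluded",
                      RuntimeWarning)
    if de_table is None:
        de = welch_de_table(counts, cond_a, cond_b)
    else:
        de = de_table.copy()
        if "fold" not in de and "log2FoldChange" in de:
            de["fold"] = 2.0 ** de["log2FoldChange"]
    de = de.loc[present]
    passes = de["fold"] > fold_threshold if strict else de["fold"] >= fold_threshold
    significant = de["padj"] < alpha
    out = de.copy()
    out["called"] = (passes & significant).map({True: "up", False: "unchanged"})
    fam = {c.copy_id: c.family for c in copies}
    out.insert(0, "family", [fam[i] for i in out.index])
    out.index.name = "copy_id"
    return out


def k9_on_copy_sets(k9_counts: CountsMatrix, calls: pd.DataFrame,
                    condition: str) -> GroupComparison:
    """Compare normalized H3K9me2 levels on up-called vs unchanged copies.

    ``k9_counts`` is a per-copy H3K9me2 counts table (e.g. uniquely mapped
    CUT&RUN reads in copies); it is size-factor normalized here and the
    per-copy mean over the condition's replicates is the compared value.
    """
    norm = normalize_counts(k9_counts)
    cols = k9_counts.condition_samples(condition)
    per_copy = norm[cols].mean(axis=1)
    groups = {}
    for label in ("up", "unchanged"):
        ids = calls.index[calls["called"] == label]
        ids = ids.intersection(per_copy.index)
        if len(ids) == 0:
            raise ValueError(f"no copies in the {label!r} set")
        groups[label] = per_copy.loc[ids].to_numpy()
    return compare_groups(groups)
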