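"""Replicate consensus domains via multi-way interval intersection.

Replicate-level domain calls are combined by partitioning the genome at
every interval boundary (the same semantics as a multi-way ``multiinter``),
annotating each fragment with the replicates (and classes) that cover it,
and keeping fragments supported by at least ``min_support`` replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import CLASS1, CLASS2, DomainSet


@dataclass(frozen=True)
class SupportPartition:
    """Disjoint fragments covering the union of replicate domains.

    ``df`` columns: chrom, start, end, support, n_class1, n_class2 and one
    ``rep{i}`` column per replicate holding the covering class or ``.``.
    """

    df: pd.DataFrame
    n_replicates: int

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def multi_intersect(replicate_domains: list[DomainSet]) -> SupportPartition:
    """Partition the union of replicate domains at every boundary.

    Each output fragment records which replicates cover it and with which
    class. Fragments covered by no replicate are omitted, so the fragments
    exactly tile the union of the inputs.
    """
    if not replicate_domains:
        raise ValueError("need at least one replicate DomainSet")
    n_rep = len(replicate_domains)
    chroms: list[str] = []
    for ds in replicate_domains:
        chroms.extend(ds.chroms())
    chroms = list(dict.fromkeys(chroms))

    rows = []
    for chrom in chroms:
        per_rep = []
        for ds in replicate_domains:
            sub = ds.df[ds.df["chrom"] == chrom]
            per_rep.append((sub["start"].to_numpy(), sub["end"].to_numpy(),
                            sub["domain_class"].to_numpy()))
        bounds = np.unique(np.concatenate(
            [np.concatenate([s, e]) for s, e, _ in per_rep]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            classes = []
            for starts, ends, klasses in per_rep:
                idx = np.searchsorted(starts, lo, side="right") - 1
                if idx >= 0 and ends[idx] > lo:
                    classes.append(str(klasses[idx]))
                else:
                    classes.append(".")
            support = sum(c != "." for c in classes)
            if support == 0:
                continue
            rows.append((chrom, int(lo), int(hi), support,
                         classes.count(CLASS1), classes.count(CLASS2), *classes))
    cols = ["chrom", "start", "end", "support", "n_class1", "n_class2"]
    cols += [f"rep{i}" for i in range(n_rep)]
    df = pd.DataFrame(rows, columns=cols)
    return SupportPartition(df, n_rep)


def consensus_filter(partition: SupportPartition, min_support: int = 2) -> DomainSet:
    """Keep fragments with support >= ``min_support``; majority class.

    The class of a kept fragment is the majority class among supporting
    replicates, ties resolved toward the weaker call (class1). Adjacent
    same-class fragments are coalesced.
    """
    if not 1 <= min_support <= partition.n_replicates:
        raise ValueError(
            f"min_support must be in [1, {partition.n_replicates}]")
    kept = partition.df[partition.df["support"] >= min_support]
    records = []
    for row in kept.itertuples(index=False):
        klass = CLASS2 if row.n_class2 > row.n_class1 else CLASS1
        if records and records[-1][0] == row.chrom and records[-1][2] == row.start \
                and records[-1][3] == klass:
            records[-1][2] = row.end
        else:
            records.append([row.chrom, row.start, row.end, klass])
    if not records:
        return DomainSet.empty()
    return DomainSet.from_records([tuple(r) for r in records])
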