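"""Gene-level accounting: domain assignment, TPM, expressed fractions,
domain flow between cell states, library-size normalization, and rank-based
group comparisons of H3K9me2 levels.

The expression unit is TPM (transcripts per million); a gene counts as
"expressed" when its mean TPM across a condition's replicates reaches a
threshold (5 by default). Library-size normalization uses median-of-ratios
size factors. Group comparisons use the tie-corrected Kruskal-Wallis test
followed by Dunn's pairwise z tests with a multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import CLASS1, CLASS2, DomainSet, overlap_bp
from .layout import GenomeLayout

OUTSIDE = "outside"
CATEGORIES = (OUTSIDE, CLASS1, CLASS2)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with the effective length used for TPM."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    effective_length: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.effective_length is None:
            object.__setattr__(self, "effective_length", self.end - self.start)
        if self.effective_length <= 0:
            raise ValueError(f"{self.gene_id}: effective_length must be > 0")


@dataclass(frozen=True)
class CountsMatrix:
    """Nonnegative integer feature x sample counts with sample metadata.

    ``samples`` is indexed by sample id with columns ``condition`` and
    ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns must match samples index")

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples.index[self.samples["condition"] == condition]
        if len(sel) == 0:
            raise ValueError(f"no samples for condition {condition!r}")
        return list(sel)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature")


@dataclass(frozen=True)
class FlowTable:
    """Gene movement between domain categories in two cell states."""

    per_gene: pd.DataFrame  # gene_id, category_a, category_b, status
    aggregates: dict[str, int]  # constitutive / gained / lost / never


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis H with Dunn's pairwise post-hoc z tests."""

    group_stats: pd.DataFrame  # index: group; columns n, median
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj
    adjust_method: str


# ---------------------------------------------------------------------------
# annotation readers

def read_genes_bed(path) -> list[GeneModel]:
    """Read gene loci from BED4+ (name column = gene id)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns")
            strand = f[5] if len(f) > 5 else "+"
            genes.append(GeneModel(f[3], f[0], int(f[1]), int(f[2]), strand))
    return genes


def read_genes_gtf(path, feature: str = "gene") -> list[GeneModel]:
    """Read gene loci from GTF via gffutils (in-memory db).

    Effective length defaults to the locus span; pass exon-union lengths via
    ``GeneModel`` construction when exon structure matters.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="merge",
                            disable_infer_genes=True, disable_infer_transcripts=True)
    genes = []
    for g in db.features_of_type(feature):
        genes.append(GeneModel(g.id, g.seqid, g.start - 1, g.end, g.strand or "+"))
    return genes


# ---------------------------------------------------------------------------
# operations

def assign_genes(genes: list[GeneModel], domains: DomainSet,
                 layout: GenomeLayout | None = None,
                 rule: str = "majority") -> pd.Series:
    """Assign each gene to outside / class1 / class2.

    ``majority`` (default): the category with the most gene-body bp wins; a
    bp tie between class1 and class2 goes to class2, and a tie between the
    best domain class and outside goes to the domain class. ``any_overlap``:
    any domain overlap assigns the gene to its largest-bp domain class.
    Returns a Series indexed by gene id.
    """
    if rule not in ("majority", "any_overlap"):
        raise ValueError(f"unknown assignment rule {rule!r}")
    by_chrom_class = {}
    for klass in (CLASS1, CLASS2):
        sub = domains.select_class(klass)
        by_chrom_class[klass] = {c: sub.chrom_intervals(c) for c in sub.chroms()}
    out = {}
    for g in genes:
        if layout is not None and (g.chrom not in layout or g.end > layout.length(g.chrom)):
            raise ValueError(f"gene {g.gene_id} outside layout")
        bp1 = overlap_bp(by_chrom_class[CLASS1].get(g.chrom, np.empty((0, 2), int)),
                         g.start, g.end)
        bp2 = overlap_bp(by_chrom_class[CLASS2].get(g.chrom, np.empty((0, 2), int)),
                         g.start, g.end)
        bp_out = (g.end - g.start) - bp1 - bp2
        best_class = CLASS2 if bp2 >= bp1 else CLASS1
        best_bp = max(bp1, bp2)
        if rule == "any_overlap":
            out[g.gene_id] = best_class if best_bp > 0 else OUTSIDE
        else:
            out[g.gene_id] = best_class if (best_bp >= bp_out and best_bp > 0) else OUTSIDE
    return pd.Series(out, name="category")


def tpm(counts: CountsMatrix, genes: list[GeneModel]) -> pd.DataFrame:
    """Transcripts per million; columns sum to 1e6.

    rate_g = count_g / length_kb_g; TPM_g = rate_g / sum(rates) * 1e6.
    """
    lengths = pd.Series({g.gene_id: g.effective_length for g in genes})
    missing = counts.counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"genes without effective_length: {list(missing)[:5]}")
    kb = lengths.reindex(counts.counts.index) / 1000.0
    rates = counts.counts.div(kb, axis=0)
    totals = rates.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total rate in samples: {bad}")
    return rates.div(totals, axis=1) * 1e6


def expressed_fraction(assignment: pd.Series, tpm_matrix: pd.DataFrame,
                       samples: pd.DataFrame, condition: str,
                       threshold: float = 5.0) -> dict[str, float]:
    """Fraction of genes expressed (mean TPM >= threshold) per category.

    Empty categories are reported as NaN.
    """
    cols = samples.index[samples["condition"] == condition]
    if len(cols) == 0:
        raise ValueError(f"no samples for condition {condition!r}")
    mean_tpm = tpm_matrix[list(cols)].mean(axis=1)
    expressed = mean_tpm >= threshold
    out = {}
    for cat in CATEGORIES:
        ids = assignment.index[assignment == cat]
        out[cat] = float(expressed.reindex(ids).mean()) if len(ids) else float("nan")
    return out


def domain_flow(assign_a: pd.Series, assign_b: pd.Series) -> FlowTable:
    """Cross-tabulate gene domain residence between two cell states.

    class1/class2 collapse to "in-domain" before flow accounting:
    constitutive = in both, gained = outside->in, lost = in->outside,
    never = outside in both. Aggregates sum to the gene universe.
    """
    if set(assign_a.index) != set(assign_b.index):
        raise ValueError("gene universes differ between states")
    b = assign_b.reindex(assign_a.index)
    in_a = assign_a.isin([CLASS1, CLASS2])
    in_b = b.isin([CLASS1, CLASS2])
    status = np.select(
        [in_a & in_b, ~in_a & in_b, in_a & ~in_b],
        ["constitutive", "gained", "lost"], default="never")
    per_gene = pd.DataFrame({
        "gene_id": assign_a.index, "category_a": assign_a.to_numpy(),
        "category_b": b.to_numpy(), "status": status,
    })
    agg = {k: int((status == k).sum())
           for k in ("constitutive", "gained", "lost", "never")}
    return FlowTable(per_gene, agg)


def size_factors(counts: CountsMatrix) -> pd.Series:
    """Median-of-ratios library-size factors, rescaled to median 1.

    The reference is the per-feature geometric mean over features positive
    in every sample; each sample's factor is the median count/reference
    ratio. Factors are divided by their median so that unperturbed samples
    sit at 1. Dividing counts by the factors normalizes them.
    """
    mat = counts.counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature is positive in all samples")
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1, keepdims=True)
    raw = np.exp(np.median(logs - ref, axis=0))
    raw = raw / np.median(raw)
    return pd.Series(raw, index=counts.counts.columns, name="size_factor")


def normalize_counts(counts: CountsMatrix) -> pd.DataFrame:
    """Counts divided by their median-of-ratios size factors."""
    return counts.counts.div(size_factors(counts), axis=1)


def compare_groups(values_by_group: dict[str, np.ndarray],
                   adjust: str = "holm") -> GroupComparison:
    """Tie-corrected Kruskal-Wallis plus Dunn's pairwise post-hoc tests.

    ``adjust`` is one of holm (default), bonferroni, fdr_bh. All-identical
    values yield H = 0, p = 1.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(list(groups.values()))
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need at least three values in total")
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups.values())
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    pos = 0
    for k, v in groups.items():
        mean_ranks[k] = ranks[pos:pos + len(v)].mean()
        pos += len(v)
    # pooled rank variance with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (n_total - 1)))
    variance = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(groups, 2):
        se = np.sqrt(variance * (1 / len(groups[a]) + 1 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p_raw})
    pw = pd.DataFrame(rows)
    pw["p_adj"] = multipletests(pw["p_raw"], method=adjust)[1]
    gs = pd.DataFrame({
        "n": {k: len(v) for k, v in groups.items()},
        "median": {k: float(np.median(v)) for k, v in groups.items()},
    })
    return GroupComparison(gs, float(h), float(p), pw, adjust)


def welch_de_table(counts: CountsMatrix, cond_a: str, cond_b: str) -> pd.DataFrame:
    """Simple differential-expression stand-in between two conditions.

    Size-factor-normalized counts, Welch's t-test on log1p values per
    feature, Benjamini-Hochberg adjustment. Columns: mean_a, mean_b, fold
    ((mean_b+1)/(mean_a+1)), pvalue, padj. This is a deliberately plain
    screen, not a dispersion-shrinkage DE engine.
    """
    norm = normalize_counts(counts)
    a = norm[counts.condition_samples(cond_a)].to_numpy()
    b = norm[counts.condition_samples(cond_b)].to_numpy()
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(np.log1p(b), np.log1p(a), axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    # zero-variance features: identical means are null, different means extreme
    bad = ~np.isfinite(pvals)
    if bad.any():
        pvals[bad] = np.where(np.isclose(mean_a[bad], mean_b[bad]), 1.0, 0.0)
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b,
        "fold": (mean_b + 1.0) / (mean_a + 1.0),
        "pvalue": pvals, "padj": padj,
    }, index=counts.counts.index)
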