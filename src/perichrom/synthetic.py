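"""Synthetic genomes with planted H3K9me2 domain structure.

The generator emulates the statistical structure the analysis assumes:

* a per-bin hidden state per chromosome drawn from a sticky Markov chain
  over background / class1 / class2, adjusted to hit a target fraction of
  the genome inside domains, plus rare short blacklist runs of extreme
  signal planted inside background stretches;
* per-replicate coverage tracks whose bin values are the inverse-log1p
  transform of Gaussian emissions around the planted state means, divided
  by the library's spike-in scale factor (so that spike-in normalization
  recovers the planted signal), with additive replicate noise on the
  transformed scale;
* negative-binomial RNA count tables for genes and TE copies in which
  domain-resident features are repressed in both conditions and a marked
  subset of class2-resident L1MdA_I copies is additionally induced at least
  ``derepression_fold``-fold in the "mutant" condition;
* negative-binomial H3K9me2 count tables for TE copies proportional to the
  planted signal of the state they reside in.

Everything is deterministic given ``SynthConfig.seed``; the returned
:class:`SyntheticTruth` carries the planted state maps, feature placements
and effect sizes that downstream tests score against.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .intervals import CLASS1, CLASS2, DomainSet
from .layout import GenomeLayout
from .tracks import BinnedTrack, DEFAULT_SPIKE_CONSTANT
from .genes import CountsMatrix

# planted state codes
BG, C1, C2, BL = 0, 1, 2, 3
STATE_CLASS = {C1: CLASS1, C2: CLASS2}

CONDITIONS = ("wildtype", "mutant")

#: TE family names used for the synthetic annotation; the first is the
#: young LINE-1 family whose copies can be marked for derepression.
TE_FAMILIES = ("L1MdA_I", "L1MdF_II", "ERVB4_2-I", "RLTR45-int", "B2_Mm2")

# rng stream ids so each generator draws from an independent substream
_S_TRUTH, _S_TRACKS, _S_RNA, _S_K9 = 1, 2, 3, 4


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults describe the conditions the analysis is validated under: a
    500-Mb-equivalent genome of 50,000 10-kb bins, 60% of the genome in
    domains (40% of domain bp class2), sticky states (self-transition
    0.99), unit-separated log1p emission means with sd 0.5, three CUT&RUN
    replicates per condition, three RNA replicates, 10-fold minimum planted
    TE induction and strong (5x per class step) domain gene repression.
    """

    seed: int = 0
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    bin_size_bp: int = 10_000
    target_domain_fraction: float = 0.60
    class2_share: float = 0.40
    blacklist_fraction: float = 0.005
    emission_means: tuple[float, ...] = (0.0, 1.0, 3.0, 8.0)
    emission_sds: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5)
    stickiness: float = 0.99
    n_replicates: int = 3
    replicate_noise_sd: float = 0.05
    spike_read_counts: tuple[int, ...] = (30_000, 20_000, 40_000)
    spike_constant: int = DEFAULT_SPIKE_CONSTANT
    n_genes: int = 2_000
    n_te_copies: int = 500
    repression_effect: float = 0.1
    derepression_fold: float = 10.0
    derepressed_fraction: float = 0.2
    n_rna_replicates: int = 3
    nb_dispersion: float = 0.02
    depth_multipliers: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chrom_length_bp, self.bin_size_bp,
               self.n_replicates, self.n_rna_replicates) <= 0:
            raise ValueError("configuration error: counts and lengths must be positive")
        if self.n_genes < 0 or self.n_te_copies < 0:
            raise ValueError("configuration error: feature counts must be >= 0")
        for name in ("target_domain_fraction", "class2_share", "blacklist_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"configuration error: {name} must be in [0, 1]")
        if not 0 < self.stickiness < 1:
            raise ValueError("configuration error: stickiness must be in (0, 1)")
        means = np.asarray(self.emission_means, dtype=float)
        if len(means) != 4 or (np.diff(means) <= 0).any():
            raise ValueError("configuration error: emission_means must be a "
                             "strictly increasing 4-vector")
        if len(self.emission_sds) != 4 or any(s < 0 for s in self.emission_sds):
            raise ValueError("configuration error: emission_sds must be a "
                             "nonnegative 4-vector")
        if len(self.spike_read_counts) < self.n_replicates or \
                any(s <= 0 for s in self.spike_read_counts):
            raise ValueError("configuration error: need a positive spike read "
                             "count per replicate")
        if self.repression_effect <= 0 or self.derepression_fold <= 0:
            raise ValueError("configuration error: effects must be positive")

    @property
    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))
        return GenomeLayout(names, (self.chrom_length_bp,) * self.n_chromosomes)

    @property
    def total_bins(self) -> int:
        return self.layout.total_bins(self.bin_size_bp)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth the downstream stages are scored against."""

    config: SynthConfig
    states: dict[str, dict[str, np.ndarray]]  # condition -> chrom -> int8
    transition: np.ndarray  # 3-state chain used for bg/class1/class2
    genes: pd.DataFrame
    te: pd.DataFrame

    @property
    def layout(self) -> GenomeLayout:
        return self.config.layout

    def domain_fraction(self, condition: str = "wildtype") -> float:
        st = self.states[condition]
        total = sum(len(v) for v in st.values())
        dom = sum(int(np.isin(v, (C1, C2)).sum()) for v in st.values())
        return dom / total

    def planted_domains(self, condition: str = "wildtype") -> DomainSet:
        """Planted class1/class2 state runs as a DomainSet."""
        bin_size = self.config.bin_size_bp
        records = []
        for chrom, st in self.states[condition].items():
            boundaries = np.flatnonzero(np.diff(st)) + 1
            edges = np.concatenate([[0], boundaries, [len(st)]])
            for lo, hi in zip(edges[:-1], edges[1:]):
                code = int(st[lo])
                if code in STATE_CLASS:
                    start = int(lo) * bin_size
                    end = min(int(hi) * bin_size, self.layout.length(chrom))
                    records.append((chrom, start, end, STATE_CLASS[code]))
        return DomainSet.from_records(records) if records else DomainSet.empty()

    @property
    def derepressed_ids(self) -> list[str]:
        return list(self.te.index[self.te["derepressed"]])

    def genes_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.genes.itertuples():
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.Index}\t0\t{row.strand}\n")

    def te_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.te.itertuples():
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                         f"{row.Index}:{row.family}\t0\t{row.strand}\n")

    def manifest(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "domain_fraction": {c: self.domain_fraction(c) for c in self.states},
            "n_genes": int(len(self.genes)),
            "n_te_copies": int(len(self.te)),
            "n_derepressed": int(self.te["derepressed"].sum()),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


# ---------------------------------------------------------------------------
# state map

def _chain_params(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Stationary target and sticky transition matrix of the 3-state chain."""
    t = cfg.target_domain_fraction
    pi = np.array([1 - t, t * (1 - cfg.class2_share), t * cfg.class2_share])
    A = np.zeros((3, 3))
    for i in range(3):
        others = pi.copy()
        others[i] = 0.0
        if others.sum() > 0:
            A[i] = (1 - cfg.stickiness) * others / others.sum()
        A[i, i] = 1 - A[i].sum()
    return pi, A


def _sample_chain(n: int, pi: np.ndarray, A: np.ndarray, rng) -> np.ndarray:
    states = np.empty(n, dtype=np.int8)
    cum_pi = np.cumsum(pi)
    cum_A = np.cumsum(A, axis=1)
    u = rng.random(n)
    states[0] = np.searchsorted(cum_pi, u[0])
    for i in range(1, n):
        states[i] = np.searchsorted(cum_A[states[i - 1]], u[i])
    return states


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) runs where mask is True."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [len(mask)]
    return list(zip(starts, ends))


def _adjust_domain_bins(per_chrom: dict[str, np.ndarray], target_bins: int,
                        target_c2: int, rng) -> None:
    """Convert run edges between background and domain states to hit targets.

    Whole or partial runs are converted at their edges so planted states
    stay contiguous; the loop terminates when the exact bin targets are met.
    """
    def counts():
        dom = c2 = 0
        for st in per_chrom.values():
            dom += int(np.isin(st, (C1, C2)).sum())
            c2 += int((st == C2).sum())
        return dom, c2

    chroms = list(per_chrom)
    for _ in range(100_000):
        dom, c2 = counts()
        need = target_bins - dom
        if need == 0:
            break
        grow = need > 0
        # collect candidate runs across chromosomes
        candidates = []
        for chrom in chroms:
            st = per_chrom[chrom]
            mask = (st == BG) if grow else np.isin(st, (C1, C2))
            candidates.extend((chrom, lo, hi) for lo, hi in _runs_of(mask))
        if not candidates:
            break
        chrom, lo, hi = candidates[rng.integers(len(candidates))]
        take = min(hi - lo, abs(need))
        st = per_chrom[chrom]
        if grow:
            new_state = C2 if c2 < target_c2 else C1
            # extend from the edge touching an existing domain when possible
            if lo > 0 and st[lo - 1] in (C1, C2):
                st[lo:lo + take] = new_state
            else:
                st[hi - take:hi] = new_state
        else:
            # trim a domain run from its edge
            side = rng.integers(2)
            if side == 0:
                st[lo:lo + take] = BG
            else:
                st[hi - take:hi] = BG
    # balance class2 share by relabeling domain-run edges
    for _ in range(100_000):
        _, c2 = counts()
        need = target_c2 - c2
        if need == 0:
            break
        src, dst = (C1, C2) if need > 0 else (C2, C1)
        candidates = []
        for chrom in chroms:
            st = per_chrom[chrom]
            candidates.extend((chrom, lo, hi) for lo, hi in _runs_of(st == src))
        if not candidates:
            break
        chrom, lo, hi = candidates[rng.integers(len(candidates))]
        take = min(hi - lo, abs(need))
        per_chrom[chrom][lo:lo + take] = dst


def _plant_blacklist(per_chrom: dict[str, np.ndarray], n_bl: int, rng) -> None:
    """Plant short (1-2 bin) blacklist runs inside background stretches.

    Placing them in background keeps the planted domain fraction intact and
    mirrors isolated artifact regions of aberrant signal.
    """
    chroms = list(per_chrom)
    placed = 0
    for _ in range(n_bl * 50):
        if placed >= n_bl:
            break
        chrom = chroms[rng.integers(len(chroms))]
        st = per_chrom[chrom]
        runs = [(lo, hi) for lo, hi in _runs_of(st == BG) if hi - lo >= 4]
        if not runs:
            continue
        lo, hi = runs[rng.integers(len(runs))]
        width = int(min(rng.integers(1, 3), n_bl - placed))
        pos = int(rng.integers(lo + 1, hi - 1 - width + 1)) if hi - 1 - width >= lo + 1 else lo + 1
        st[pos:pos + width] = BL
        placed += width
    if placed < n_bl:
        warnings.warn("could not place all requested blacklist bins", RuntimeWarning)


def generate_truth(config: SynthConfig) -> SyntheticTruth:
    """Plant the state map, gene/TE placements and expression means.

    Deterministic given ``config.seed``. The planted domain fraction hits
    ``target_domain_fraction`` to the bin.
    """
    rng = np.random.default_rng([config.seed, _S_TRUTH])
    layout = config.layout
    bin_size = config.bin_size_bp
    per_chrom: dict[str, np.ndarray] = {}
    if config.target_domain_fraction == 0:
        for chrom in layout.names:
            per_chrom[chrom] = np.zeros(layout.n_bins(chrom, bin_size), dtype=np.int8)
        _, A = _chain_params(config)
    else:
        pi, A = _chain_params(config)
        for chrom in layout.names:
            per_chrom[chrom] = _sample_chain(layout.n_bins(chrom, bin_size), pi, A, rng)
        total = config.total_bins
        target_bins = round(config.target_domain_fraction * total)
        target_c2 = round(config.target_domain_fraction * config.class2_share * total)
        _adjust_domain_bins(per_chrom, target_bins, target_c2, rng)
    n_bl = round(config.blacklist_fraction * config.total_bins)
    if n_bl:
        _plant_blacklist(per_chrom, n_bl, rng)

    states = {cond: {c: per_chrom[c].copy() for c in layout.names}
              for cond in CONDITIONS}
    genes = _place_genes(config, per_chrom, rng)
    te = _place_te_copies(config, per_chrom, rng)
    return SyntheticTruth(config, states, A, genes, te)


def _feature_category(per_chrom, chrom, start, end, bin_size) -> str:
    """Majority-bp planted category of a feature."""
    st = per_chrom[chrom]
    first = start // bin_size
    last = -(-end // bin_size)
    bp = {BG: 0, C1: 0, C2: 0, BL: 0}
    for b in range(first, last):
        lo = max(start, b * bin_size)
        hi = min(end, (b + 1) * bin_size)
        bp[int(st[b])] += hi - lo
    dom_best = C2 if bp[C2] >= bp[C1] else C1
    if bp[dom_best] > 0 and bp[dom_best] >= bp[BG] + bp[BL]:
        return STATE_CLASS[dom_best]
    return "outside"


def _random_placement(layout, rng, length):
    idx = rng.integers(len(layout.names))
    chrom = layout.names[idx]
    length = min(length, layout.length(chrom))
    start = int(rng.integers(0, layout.length(chrom) - length + 1))
    return chrom, start, start + length


def _place_genes(config, per_chrom, rng) -> pd.DataFrame:
    layout = config.layout
    rows = []
    for i in range(config.n_genes):
        length = int(np.clip(rng.lognormal(np.log(30_000), 0.8), 2_000, 300_000))
        chrom, start, end = _random_placement(layout, rng, length)
        cat = _feature_category(per_chrom, chrom, start, end, config.bin_size_bp)
        base = float(rng.lognormal(4.5, 2.0))
        if cat == CLASS2:
            mult = config.repression_effect
        elif cat == CLASS1:
            mult = math.sqrt(config.repression_effect)
        else:
            mult = 1.0
        mean = base * mult
        rows.append({
            "gene_id": f"gene{i:05d}", "chrom": chrom, "start": start,
            "end": end, "strand": "+" if rng.random() < 0.5 else "-",
            "category": cat, "base_mean": base,
            "mean_wildtype": mean, "mean_mutant": mean,
        })
    cols = ["gene_id", "chrom", "start", "end", "strand", "category",
            "base_mean", "mean_wildtype", "mean_mutant"]
    return pd.DataFrame(rows, columns=cols).set_index("gene_id")


def _class2_runs(per_chrom, bin_size):
    runs = []
    for chrom, st in per_chrom.items():
        runs.extend((chrom, lo * bin_size, hi * bin_size)
                    for lo, hi in _runs_of(st == C2))
    return runs


def _place_te_copies(config, per_chrom, rng) -> pd.DataFrame:
    layout = config.layout
    n = config.n_te_copies
    families = [TE_FAMILIES[0] if rng.random() < 0.4
                else TE_FAMILIES[1 + rng.integers(len(TE_FAMILIES) - 1)]
                for _ in range(n)]
    is_l1mda = np.array([f == TE_FAMILIES[0] for f in families])
    n_derep = round(config.derepressed_fraction * int(is_l1mda.sum()))
    derep_idx = set(rng.choice(np.flatnonzero(is_l1mda), size=n_derep,
                               replace=False).tolist()) if n_derep else set()
    c2_runs = _class2_runs(per_chrom, config.bin_size_bp)
    if derep_idx and not c2_runs:
        raise ValueError("configuration error: derepressed copies require "
                         "planted class2 regions")
    rows = []
    for i in range(n):
        length = int(rng.integers(500, 7_000))
        if i in derep_idx:
            chrom, run_lo, run_hi = c2_runs[rng.integers(len(c2_runs))]
            run_hi = min(run_hi, layout.length(chrom))
            length = min(length, run_hi - run_lo)
            start = int(rng.integers(run_lo, run_hi - length + 1))
            end = start + length
        else:
            chrom, start, end = _random_placement(layout, rng, length)
        cat = _feature_category(per_chrom, chrom, start, end, config.bin_size_bp)
        # young-LINE copies are quantified at substantial depth: baseline
        # normalized counts log-uniform over [500, 5000] before repression
        base = float(10 ** rng.uniform(np.log10(500), np.log10(5_000)))
        mean_wt = base * (config.repression_effect if cat in (CLASS1, CLASS2) else 1.0)
        if i in derep_idx and config.derepression_fold != 1.0:
            # per-copy induction log-uniform on [fold, 10*fold]: the planted
            # derepression is AT LEAST derepression_fold, with the order-of-
            # magnitude spread real per-copy inductions show
            fold = float(10 ** rng.uniform(np.log10(config.derepression_fold),
                                           np.log10(10 * config.derepression_fold)))
        else:
            fold = 1.0
        mid_bin = ((start + end) // 2) // config.bin_size_bp
        state = int(per_chrom[chrom][mid_bin])
        k9_mean = (2.0 + 20.0 * np.expm1(config.emission_means[state])) \
            * (end - start) / 1000.0
        rows.append({
            "copy_id": f"te{i:05d}", "family": families[i], "chrom": chrom,
            "start": start, "end": end,
            "strand": "+" if rng.random() < 0.5 else "-", "category": cat,
            "derepressed": i in derep_idx, "planted_fold": fold,
            "mean_wildtype": mean_wt, "mean_mutant": mean_wt * fold,
            "k9_mean": float(k9_mean),
        })
    cols = ["copy_id", "family", "chrom", "start", "end", "strand", "category",
            "derepressed", "planted_fold", "mean_wildtype", "mean_mutant",
            "k9_mean"]
    return pd.DataFrame(rows, columns=cols).set_index("copy_id")


# ---------------------------------------------------------------------------
# tracks and counts

def simulate_tracks(truth: SyntheticTruth, condition: str
                    ) -> list[tuple[BinnedTrack, int]]:
    """Per-replicate raw coverage tracks plus spike-in read counts.

    Bin values are ``expm1(N(mean[state], sd[state]) + N(0, noise_sd))``
    clipped at 0, then divided by the replicate's spike-in scale factor so
    that applying :func:`perichrom.tracks.normalize_track` recovers the
    planted signal scale.
    """
    cfg = truth.config
    if condition not in truth.states:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = list(truth.states).index(condition)
    means = np.asarray(cfg.emission_means)
    sds = np.asarray(cfg.emission_sds)
    out = []
    for rep in range(cfg.n_replicates):
        rng = np.random.default_rng([cfg.seed, _S_TRACKS, cond_idx, rep])
        spike = int(cfg.spike_read_counts[rep])
        factor = cfg.spike_constant / spike
        values = {}
        for chrom, st in truth.states[condition].items():
            z = rng.normal(means[st], sds[st])
            if cfg.replicate_noise_sd > 0:
                z = z + rng.normal(0.0, cfg.replicate_noise_sd, size=len(st))
            values[chrom] = np.maximum(np.expm1(z), 0.0) / factor
        track = BinnedTrack(cfg.layout, cfg.bin_size_bp, values,
                            {"condition": condition, "replicate": rep,
                             "normalization": "rpkm"})
        out.append((track, spike))
    return out


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _sample_frame(cfg) -> pd.DataFrame:
    names, conds, reps = [], [], []
    for cond in CONDITIONS:
        for r in range(cfg.n_rna_replicates):
            names.append(f"{cond}_rep{r + 1}")
            conds.append(cond)
            reps.append(r + 1)
    return pd.DataFrame({"condition": conds, "replicate": reps},
                        index=pd.Index(names, name="sample"))


def _simulate_matrix(cfg, means_by_cond: dict[str, np.ndarray], index,
                     rng) -> CountsMatrix:
    samples = _sample_frame(cfg)
    depth = cfg.depth_multipliers or (1.0,) * len(samples)
    if len(depth) != len(samples):
        raise ValueError("configuration error: depth_multipliers must have "
                         "one entry per RNA sample")
    cols = {}
    for j, (name, row) in enumerate(samples.iterrows()):
        mu = means_by_cond[row["condition"]] * depth[j]
        cols[name] = _nb_draw(rng, mu, cfg.nb_dispersion)
    counts = pd.DataFrame(cols, index=index)
    return CountsMatrix(counts, samples)


def simulate_counts(truth: SyntheticTruth) -> tuple[CountsMatrix, CountsMatrix]:
    """Negative-binomial RNA count tables for genes and TE copies."""
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed, _S_RNA])
    genes = _simulate_matrix(
        cfg,
        {"wildtype": truth.genes["mean_wildtype"].to_numpy(),
         "mutant": truth.genes["mean_mutant"].to_numpy()},
        truth.genes.index, rng)
    te = _simulate_matrix(
        cfg,
        {"wildtype": truth.te["mean_wildtype"].to_numpy(),
         "mutant": truth.te["mean_mutant"].to_numpy()},
        truth.te.index, rng)
    return genes, te


def simulate_k9_counts(truth: SyntheticTruth) -> CountsMatrix:
    """H3K9me2 counts on TE copies, proportional to planted state signal."""
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed, _S_K9])
    k9 = truth.te["k9_mean"].to_numpy()
    return _simulate_matrix(cfg, {"wildtype": k9, "mutant": k9},
                            truth.te.index, rng)
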