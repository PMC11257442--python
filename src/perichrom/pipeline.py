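"""End-to-end orchestration of the domain-calling analysis.

A single :class:`AnalysisConfig` is the home of every analysis cutoff: the
spike-in constant (30,000), the two track resolutions (1 kb and 10 kb), the
4 HMM states, the consensus support rule, the 5-TPM expressed threshold,
the 2-fold / alpha 0.05 gene rule and the 10-fold per-copy TE rule.

``run_pipeline`` executes the synthetic-mode pipeline: generate truth,
simulate replicate tracks per condition, spike-in normalize, fit the HMM
per replicate, decode and segment domains, build the per-condition
consensus, compute domain statistics and sharing, gene assignment / TPM /
expressed fractions, and per-copy TE derepression calls. All outputs are
plain text (bedGraph, BED, TSV, JSON) under the output directory, and the
run is byte-reproducible given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .analytics import condition_sharing, domain_stats
from .consensus import consensus_filter, multi_intersect
from .genes import GeneModel, assign_genes, expressed_fraction, tpm
from .hmm import decode_states, fit_hmm, label_states, segment_domains
from .intervals import DomainSet
from .synthetic import (CONDITIONS, SynthConfig, generate_truth,
                        simulate_counts, simulate_k9_counts, simulate_tracks)
from .te import call_derepressed, k9_on_copy_sets, TECopy
from .tracks import (DEFAULT_SPIKE_CONSTANT, average_replicates,
                     compute_scale_factor, normalize_track, write_bedgraph)

log = logging.getLogger("perichrom")


@dataclass
class AnalysisConfig:
    """All analysis thresholds, plus the synthetic generator settings."""

    seed: int = 0
    fine_bin_bp: int = 1_000
    analysis_bin_bp: int = 10_000
    spike_constant: int = DEFAULT_SPIKE_CONSTANT
    hmm_states: int = 4
    hmm_restarts: int = 3
    hmm_max_iter: int = 100
    hmm_tol: float = 1e-2
    consensus_min_support: int = 2
    expressed_tpm: float = 5.0
    gene_fold_threshold: float = 2.0
    gene_alpha: float = 0.05
    te_fold_threshold: float = 10.0
    te_alpha: float = 0.05
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("fine_bin_bp", "analysis_bin_bp", "spike_constant",
                     "hmm_states", "consensus_min_support", "expressed_tpm",
                     "gene_fold_threshold", "gene_alpha", "te_fold_threshold",
                     "te_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def synth_config(self) -> SynthConfig:
        kwargs = dict(self.synthetic)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("bin_size_bp", self.analysis_bin_bp)
        kwargs.setdefault("spike_constant", self.spike_constant)
        return SynthConfig(**kwargs)

    def param_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def call_replicate_domains(tracks_with_spike, config: AnalysisConfig,
                           seed_offset: int = 0) -> list[DomainSet]:
    """Spike-in normalize, fit/decode the HMM and segment, per replicate."""
    domain_sets = []
    for i, (track, spike) in enumerate(tracks_with_spike):
        scale = compute_scale_factor(spike, config.spike_constant)
        norm = normalize_track(track, scale)
        model = fit_hmm(norm, n_states=config.hmm_states,
                        seed=config.seed + seed_offset + i,
                        max_iter=config.hmm_max_iter, tol=config.hmm_tol,
                        n_restarts=config.hmm_restarts)
        labeling = label_states(model)
        path = decode_states(model, norm)
        domain_sets.append(segment_domains(path, labeling, track.layout))
    return domain_sets


def run_pipeline(config: AnalysisConfig, outdir) -> dict:
    """Synthetic-mode end-to-end run; returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_times: dict[str, float] = {}
    outputs: list[str] = []

    def _done(stage: str) -> None:
        stage_times[stage] = round(time.time() - t0 - sum(stage_times.values()), 3)
        log.info("stage %s finished (%.1fs)", stage, stage_times[stage])

    def _write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        outputs.append(name)

    try:
        scfg = config.synth_config()
        truth = generate_truth(scfg)
        _write("truth.json", truth.manifest)
        _write("genes.bed", truth.genes_bed)
        _write("te_copies.bed", truth.te_bed)
        for cond in CONDITIONS:
            _write(f"planted_domains_{cond}.bed",
                   truth.planted_domains(cond).to_bed)
        _done("simulate")

        consensus: dict[str, DomainSet] = {}
        for ci, cond in enumerate(CONDITIONS):
            sim = simulate_tracks(truth, cond)
            for i, (track, spike) in enumerate(sim):
                _write(f"track_{cond}_rep{i + 1}.bedGraph",
                       lambda p, t=track: write_bedgraph(t, p))
            reps = call_replicate_domains(sim, config, seed_offset=1000 * ci)
            for i, ds in enumerate(reps):
                _write(f"domains_{cond}_rep{i + 1}.bed", ds.to_bed)
            part = multi_intersect(reps)
            _write(f"support_{cond}.tsv", part.to_tsv)
            consensus[cond] = consensus_filter(part, config.consensus_min_support)
            _write(f"consensus_{cond}.bed", consensus[cond].to_bed)
            norm = [normalize_track(t, compute_scale_factor(s, config.spike_constant))
                    for t, s in sim]
            avg = average_replicates(norm)
            _write(f"track_{cond}_averaged.bedGraph",
                   lambda p, t=avg: write_bedgraph(t, p))
        _done("domains")

        layout = scfg.layout
        stats = {c: domain_stats(ds, layout) for c, ds in consensus.items()}
        _write("domain_stats.tsv", lambda p: _stats_tsv(stats, p))
        sharing = condition_sharing(consensus, mode="bp")
        _write("sharing_bp.tsv", sharing.to_tsv)
        _done("stats")

        gene_models = [GeneModel(i, r.chrom, r.start, r.end, r.strand)
                       for i, r in truth.genes.iterrows()]
        gene_counts, te_counts = simulate_counts(truth)
        _write("gene_counts.tsv", gene_counts.to_tsv)
        _write("te_counts.tsv", te_counts.to_tsv)
        assignment = assign_genes(gene_models, consensus["wildtype"], layout)
        _write("gene_assignment.tsv",
               lambda p: assignment.to_csv(p, sep="\t", index_label="gene_id"))
        tpm_mat = tpm(gene_counts, gene_models)
        _write("gene_tpm.tsv",
               lambda p: tpm_mat.to_csv(p, sep="\t", index_label="gene_id"))
        fractions = expressed_fraction(assignment, tpm_mat, gene_counts.samples,
                                       "wildtype", config.expressed_tpm)
        _done("genes")

        te_models = [TECopy(i, r.family, r.chrom, r.start, r.end, r.strand)
                     for i, r in truth.te.iterrows()]
        calls = call_derepressed(te_models, te_counts, "wildtype", "mutant",
                                 config.te_fold_threshold, config.te_alpha)
        _write("te_calls.tsv", lambda p: calls.to_csv(p, sep="\t"))
        k9 = simulate_k9_counts(truth)
        _write("te_k9_counts.tsv", k9.to_tsv)
        k9_cmp = None
        if (calls["called"] == "up").any():
            k9_cmp = k9_on_copy_sets(k9, calls, "wildtype")
        _done("tes")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "outputs": outputs,
        "stage_seconds": stage_times,
        "summary": {
            "coverage_fraction": {c: stats[c].coverage_fraction for c in stats},
            "median_contiguous_bp": {c: stats[c].median_contiguous_bp for c in stats},
            "shared_all_fraction": sharing.shared_all_fraction,
            "expressed_fraction": fractions,
            "n_te_up": int((calls["called"] == "up").sum()),
            "k9_up_vs_unchanged_p": None if k9_cmp is None else k9_cmp.p_value,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return manifest


def _stats_tsv(stats, path) -> None:
    with open(path, "w") as fh:
        fh.write("condition\tclass\tcount\ttotal_bp\tmin_bp\tmedian_bp\tmax_bp\t"
                 "coverage_fraction\tmedian_contiguous_bp\n")
        for cond, st in stats.items():
            for klass, row in st.per_class.iterrows():
                fh.write(f"{cond}\t{klass}\t{int(row['count'])}\t{int(row['total_bp'])}\t"
                         f"{row['min_bp']}\t{row['median_bp']}\t{row['max_bp']}\t"
                         f"{st.coverage_fraction:.6f}\t{st.median_contiguous_bp}\n")
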