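# perichrom

Quantitative analysis of H3K9me2 chromatin domains from spike-in-controlled
CUT&RUN coverage: genome segmentation with a four-state hidden Markov model,
replicate consensus domains, cross-condition domain accounting, and the
downstream gene- and transposon-level consequences of domain residence.

H3K9me2 is a heterochromatin mark that blankets much of the genome in broad,
kilobase-to-megabase domains, largely coinciding with lamina-associated
domains at the nuclear periphery. `perichrom` is for groups studying how
those domains move, expand or lose repressive power across cell states and
genetic perturbations — e.g. comparing wild-type cells against mutants in
which heterochromatin is displaced from the nuclear envelope, or naive
pluripotent cells against their primed derivatives.

## What it computes

**Track preparation.** Binned coverage (1-kb and 10-kb bedGraph/bigWig) is
spike-in normalized by the scale factor `30000 / spike_reads` per library,
rebinned, and averaged across replicates.

**Domain segmentation.** A four-state HMM with Gaussian emissions on
log1p-transformed 10-kb signal is fitted per replicate by Baum–Welch.
States, labeled by ascending emission mean, are background, intermediate
density ("class 1"), high density ("class 2"), and aberrantly high artifact
signal ("blacklist"). Because coverage is floored at zero, emissions are
left-censored at 0 by default (a Tobit-style EM), which keeps the
background mean unbiased. Viterbi decoding yields maximal class runs as
BED domains.

**Consensus and analytics.** Replicate domain calls are merged by multi-way
interval intersection with support counting (`min_support` of n replicates,
majority class). Domain statistics (counts, bp, genome coverage fraction,
median contiguous tract length), UpSet-style sharing between conditions (bp
or reciprocal-overlap domain mode), scaled meta-domain density profiles,
and within-region signal dispersion follow.

**Genes.** Genes are assigned to outside / class 1 / class 2 by majority
gene-body bp; expression is TPM (`rate_g = count_g / length_kb`, scaled to
10⁶ per sample) with "expressed" meaning mean TPM ≥ 5 across a condition's
replicates; gene flow between two cell states is cross-tabulated
(constitutive / gained / lost / never in-domain). Count tables are
normalized by median-of-ratios size factors. H3K9me2 levels across gene
sets are compared with the tie-corrected Kruskal–Wallis test and Dunn's
pairwise post-hoc z tests (Holm-adjusted by default).

**Transposable elements.** Individual TE copies (uniquely-assignable
counts; e.g. the young LINE-1 family L1MdA_I) are called derepressed
between two conditions when the size-factor-normalized fold change
`(mean_B + 1)/(mean_A + 1)` is ≥ 10 and the difference is significant
(Welch test on log1p normalized counts, Benjamini–Hochberg, padj < 0.05).
H3K9me2 on up-called versus unchanged copies is then contrasted.

A synthetic-data generator (`perichrom.synthetic`) plants all of this
structure — sticky-Markov domain maps, censored-Gaussian tracks with
spike-in factors, negative-binomial count tables with domain repression and
a marked ≥10-fold-induced TE subset — and returns the ground truth every
stage is scored against.

## Worked example

```python
from perichrom.pipeline import AnalysisConfig, run_pipeline

cfg = AnalysisConfig(seed=1, hmm_restarts=2,
                     synthetic={"n_chromosomes": 2,
                                "chrom_length_bp": 25_000_000})
manifest = run_pipeline(cfg, "run1")
s = manifest["summary"]
print(f"genome coverage (wildtype): {s['coverage_fraction']['wildtype']:.1%}")
print(f"median contiguous domain:   {s['median_contiguous_bp']['wildtype']/1e3:.0f} kb")
print(f"shared across conditions:   {s['shared_all_fraction']:.1%}")
print("expressed fraction:         outside {outside:.2f} | class1 {class1:.2f} "
      "| class2 {class2:.2f}".format(**s['expressed_fraction']))
print(f"TE copies called >=10-fold: {s['n_te_up']}")
print(f"K9 up-vs-unchanged p:       {s['k9_up_vs_unchanged_p']:.2e}")
```

prints

```
genome coverage (wildtype): 60.0%
median contiguous domain:   1170 kb
shared across conditions:   99.9%
expressed fraction:         outside 0.91 | class1 0.81 | class2 0.61
TE copies called >=10-fold: 32
K9 up-vs-unchanged p:       1.29e-11
```

Reading this: the consensus domain calls recover the planted 60% genome
coverage; the two simulated conditions share essentially all domain bp
(they carry the same planted map); genes inside high-density class 2
domains are expressed less often (61%) than genes outside domains (91%),
the planted repression gradient; 32 TE copies pass the ≥10-fold call, and
those copies carry significantly more H3K9me2 than unchanged copies.

The same stages are available as a CLI
(`perichrom simulate|normalize|hmm|consensus|stats|genes|tes|all`), e.g.

```bash
perichrom all --seed 1 --out run1/
```

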