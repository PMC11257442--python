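# Methods

## Model and pipeline

`perichrom` treats binned H3K9me2 coverage as the observable of a hidden
four-state process along each chromosome. The states are background (no
enrichment), intermediate-density domains (class 1), high-density domains
(class 2), and rare artifact regions of aberrantly high signal (blacklist).
Biologically, class 1 and class 2 correspond to the broad heterochromatin
domains that coincide with lamina-associated regions; the blacklist state
absorbs mapping artifacts so they do not contaminate domain calls.

### Spike-in normalization

Each library's coverage is multiplied by `constant / spike_reads` with
`constant = 30,000` and `spike_reads` the properly paired reads mapped to
the spike-in genome. The factor is exactly inversely proportional to
spike-in yield, making signal comparable across libraries and conditions.
RPKM (or any other per-bin unit) is assumed to be applied upstream by the
coverage tool; because both normalizations are multiplicative, their order
is irrelevant, and the pipeline is agnostic to the upstream unit. Bins with
no signal are 0, matching bedGraph gap semantics.

### Emission model: censored Gaussian on log1p signal

Emissions are univariate Gaussians on log1p-transformed signal. Coverage
cannot be negative, so empty bins sit at exactly 0; on the transformed
scale this is a point mass that a plain Gaussian cannot represent — fitting
one anyway biases the background mean upward by `E[max(Z,0)] - E[Z]`
(about +0.2 for a background state at mean 0, sd 0.5). We therefore treat
observations at 0 as left-censored: they contribute `Phi((0 - mu)/sd)` to
the likelihood, and in the M-step their sufficient statistics are the
conditional moments of the truncated normal (Tobit EM). This is a proper
EM — the observed-data log-likelihood is monotone, which the fitter asserts
on every iteration — and it recovers planted emission means unbiasedly.
Passing `censored=False` restores the plain Gaussian HMM; the exact
forward-recursion oracle tests and the cross-check against an external HMM
library run in both modes.

### Fitting, decoding, segmentation

Baum–Welch treats each chromosome as an independent observation sequence
using scaled forward/backward recursions. Initialization anchors the
ordered-state interpretation: emission means at the 20/50/80/99.5 signal
percentiles (the 99.5th targets the rare blacklist state), uniform initial
distribution, and a sticky transition prior (0.95 self-transition).
`n_restarts = 3` seeded restarts jitter the means and keep the best
likelihood; convergence is a log-likelihood gain below `tol = 0.01` (in
log-likelihood units), `max_iter = 100`. Emission sds are floored at 1e-3
to prevent variance collapse. A track with fewer distinct transformed
values than states is rejected as degenerate.

Decoding is Viterbi by default (hard paths are required for BED export),
with ties broken toward the lower state index; posterior (per-bin argmax)
decoding is available as `method="posterior"`. States are labeled by
ascending emission mean; tied means are broken by smaller sd, then state
index, with a warning. Maximal class 1/class 2 runs become 0-based
half-open BED intervals; background and blacklist bins are excluded, so a
blacklist bin splits a domain. `min_domain_bins = 1` and `max_gap_bins = 0`
by default — no post-filtering — both exposed as parameters; gap merging
never bridges across an intervening domain run of the other class.

### Replicate consensus

Replicate BED calls are merged by partitioning the genome at every interval
boundary (multi-way "multiinter" semantics) and annotating each fragment
with per-replicate class cover. The consensus keeps fragments supported by
at least `min_support` replicates (default 2 of 3 — majority). The exact
authorial merge rule is not specified by any convention we could adopt
outright, so both limits remain available: `min_support = 1` is the union,
`min_support = n` the intersection, and these identities are tested.
Fragment class is the majority class among supporting replicates, ties
resolved to the weaker call (class 1), which is conservative on class 2.

### Domain analytics

Coverage fraction is exact integer bp over the assembled genome; the median
contiguous length is over class-agnostic tracts (touching class 1/class 2
intervals coalesce, since they are one H3K9me2 domain at two densities).
Cross-condition sharing partitions the union of (coalesced) domain sets by
membership pattern; bp mode is the default, and a domain mode counts whole
domains shared at ≥ 50% reciprocal overlap (configurable). Meta-domain
profiles rescale each domain body to a fixed number of positions by linear
interpolation of 1-kb bin values and append fixed-width native-resolution
flanks; positions beyond chromosome ends are excluded from the mean, and
the profile is linear in any multiplicative rescaling of the track.
Signal dispersion is the population sd over bins whose (clipped) midpoints
fall inside a region set; evaluating any condition's averaged track inside
a *fixed reference* domain set (e.g. wild-type domains) is the supported
way to compare densities when per-sample segmentation quality varies.

### Genes

Domain residence is decided by majority gene-body bp (ties: class 2 beats
class 1; a domain class beats outside), with an any-overlap rule as an
alternative. Gene span is the default effective length for TPM; exon-union
lengths can be supplied per gene. "Expressed" means mean TPM across a
condition's replicates ≥ 5 — the mean, rather than a per-replicate rule,
keeps the threshold stable at triplicate scale. Flow between two cell
states collapses class 1/class 2 to "in-domain" before cross-tabulation
into constitutive / gained / lost / never; the four counts always sum to
the gene universe. Size factors are median-of-ratios against the geometric
mean reference over features positive in all samples, rescaled so the
median factor is 1 (so unperturbed libraries sit at exactly 1.0 and a
doubled library at 2.0). Group comparisons use the tie-corrected
Kruskal–Wallis test with Dunn's pairwise z statistics from the pooled
tie-corrected rank variance; the multiplicity correction is Holm by
default (Bonferroni and Benjamini–Hochberg selectable).

### TE copies

Only uniquely-assignable per-copy counts are handled; family-level
reassignment of multi-mapping reads is upstream of this package, and the
counts table is the interface boundary. A copy is called derepressed when
the normalized fold change `(mean_B + 1)/(mean_A + 1)` (pseudocount of one
normalized count, since zeros are common at copy level) reaches the fold
threshold — inclusive by default, matching "at least 10-fold", with a
strict variant — AND the copy is significant after BH adjustment. The
built-in significance screen is deliberately plain: Welch's t on log1p
size-factor-normalized counts. It is a stand-in, not a dispersion-shrinkage
DE engine; an externally computed DE table can be injected instead.

## Synthetic data: what it emulates, and what it does not

The generator plants the exact structure the analysis assumes, then hands
back the truth for scoring.

* **State maps.** A sticky three-state Markov chain (self-transition
  `stickiness = 0.99`; off-diagonal mass proportional to the target
  stationary distribution) is sampled per chromosome, then run edges are
  converted until the planted domain fraction hits
  `target_domain_fraction` (default 0.60, class 2 share 0.40) to the bin.
  Blacklist bins (0.5%) are planted as isolated 1–2 bin runs inside
  background stretches, which leaves the domain fraction untouched. Both
  conditions share one planted map, mirroring the observation that domain
  positions are largely preserved across the perturbations of interest.
* **Tracks.** Per bin, `expm1(N(mean[state], sd[state]) + N(0,
  replicate_noise_sd))` clipped at 0, divided by the library's spike-in
  factor so that applying the pipeline's normalization recovers the
  planted scale. Planted transformed means are (0, 1, 3, 8) with sd 0.5 —
  unit-separated domain states and a far-out artifact state. Three
  replicates with spike counts (30k, 20k, 40k).
* **Counts.** Negative-binomial with dispersion 0.02 and three replicates
  per condition, the regime of isogenic cell-line triplicates at good
  depth. Domain-resident genes are repressed in both conditions —
  `repression_effect` (default 0.1) for class 2 residents and its square
  root for class 1, encoding that repression strength tracks H3K9me2
  density. A marked subset (20%) of class-2-resident L1MdA_I copies is
  additionally induced in the mutant by a per-copy fold drawn log-uniform
  on `[derepression_fold, 10x derepression_fold]` — the planted induction
  is *at least* the threshold, with the order-of-magnitude spread real
  per-copy inductions show. TE baseline expression is log-uniform on
  [500, 5000] before repression. Per-copy H3K9me2 counts scale with the
  raw signal of the copy's planted state and its length.
* **Determinism.** Every generator draws from substreams derived from
  `SynthConfig.seed`; identical configs give byte-identical outputs.

What the generator does **not** emulate: read-level sampling (fragment
lengths, GC bias, mappability), multi-mapping ambiguity between TE copies,
chromosome-scale heterogeneity of domain density, cross-condition domain
remodeling, and correlated replicate artifacts. Passing tests therefore
demonstrate that the pipeline's inference is correct *when its model
assumptions hold*; they do not certify performance on real libraries where
those assumptions bend.

## Validation problem sizes

The study-scale validation uses a 500-Mb-equivalent genome — five 100-Mb
chromosomes, 50,000 10-kb bins — with three replicates, fitted with 2
restarts and `max_iter = 60` (the fits converge in 15–30 iterations from
percentile initialization; the extra restart guards against rare bad
jitter). Observed recovery: emission means within 0.04 of truth, consensus
vs planted bp-Jaccard ≈ 0.998, called coverage within 0.1 percentage
points of the 60% target. Expression-side checks run on a 50-Mb genome
with 2,000 genes; TE sensitivity/precision use a 1,500-copy universe
(~120 planted derepressed copies), with depth-multiplier distortions
(0.5–2.0x) planted only in the size-factor experiment — TPM is
depth-invariant, and mixing depth distortion into the TE experiment would
measure the stand-in test's power at half depth rather than the calling
rule.

## Numerical choices and degenerate inputs

* Scaled (not log-space) forward/backward with per-bin emission offsets;
  exact to 1e-9 against exhaustive path enumeration on short sequences.
* Viterbi ties break to the lower state index (first-argmax), making
  decoding deterministic.
* sd floor 1e-3; transition rows renormalized after each M-step;
  likelihood decrease beyond 1e-8 relative aborts the fit as a bug.
* Empty domain sets: coverage 0 with a missing (NaN) median length;
  meta-profiles of empty sets are an error.
* Partial terminal bins: rebinning averages over available source bins
  only; bin membership uses the clipped bin midpoint; domain ends are
  clipped to chromosome length.
* Constant tracks are rejected as degenerate rather than fitted.
* Features with zero counts in some sample are excluded from the
  size-factor reference (standard median-of-ratios behavior); a matrix
  with no all-positive feature is an error.

## Known limitations

* The HMM is univariate and first-order Markov: no duration modeling, so
  very short state excursions are smoothed over at high stickiness.
* The significance stand-in (Welch + BH) is underpowered below triplicate
  depth ~50 counts/copy; with marginal data, inject a DE table from a
  dispersion-shrinkage engine instead.
* Domain-mode sharing depends on the reciprocal-overlap threshold when
  domain length distributions differ strongly between conditions; bp mode
  is the robust default.
* Per-copy TE analysis is only as good as the uniquely-assignable counts
  it is given; young, highly identical copies are under-counted upstream.
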