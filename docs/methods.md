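# Methods

## The model

`reoscore` implements qualitative transcriptional signatures built from
within-sample **relative expression orderings (REOs)**. For two genes *i*
and *j* measured in one sample, the only information used is whether
*G_i* > *G_j* or *G_i* < *G_j*. Because within-sample ranks are a strictly
increasing function of the measured values (up to ties), every quantity in
the pipeline is invariant to any monotone transform applied per sample —
scaling, log-transformation, quantile shifts, platform response curves.
This is the core robustness property: scores computed from an FPKM profile
and from an array-intensity profile of the same biology agree without any
cross-sample normalization.

### Signature construction

Given a normal cohort and a cancer cohort per platform:

1. **Stable pairs.** A pair is stable in a cohort if one direction holds
   in at least a threshold fraction *t* (default 0.90, boundary inclusive)
   of the evaluable samples. The denominator is
   `n_greater + n_less + n_tie`: a missing measurement removes the sample
   from the denominator, while a tie stays in it but supports neither
   direction. Ties are penalized rather than split because the ordering
   claim "*G_i* > *G_j*" is strict; this is the conservative choice.
2. **Reversal pairs.** Pairs stable in both cohorts with opposite
   directions. The stored direction is the cancer-cohort one, so the
   signature reads as "the orderings that characterize cancer".
3. **Cross-platform intersection.** Pairs detected on every platform with
   the same cancer direction; conflicting directions are excluded.
4. **Consistency filter.** Pairs whose cancer direction holds in at least
   *t* of the evaluable samples of each additional cancer cohort
   (e.g. RNA-seq cohorts), each cohort judged separately — the stricter
   of the possible readings.

Within a platform the gene universe is the intersection of the normal and
cancer gene sets; pair enumeration is canonical (lexicographically smaller
gene first) and chunked over pair blocks, so genome-scale universes
(2×10⁸ pairs at 20,000 genes) stream through bounded memory. The chunk
size is a memory knob only; results are independent of it (tested).

### Risk scoring

For a sample and a signature of directed pairs, *m* counts the pairs with
both genes measured and not tied, *n* counts those matching the cancer
direction, and

    score = n / m ∈ [0, 1].

Normal tissue scores near 0, carcinoma near 1, and precancerous lesions in
between in proportion to how far their transcriptome has moved. *m*
excludes ties and missing genes because they carry no directional
evidence; the reported `coverage = m / |signature|` plus a
`low_coverage_flag` (default threshold 0.5) makes panel-restricted samples
visible instead of silently scored. A sample with *m* = 0 is an error in
single-sample mode and a logged skip in cohort mode. Reversing every
signature direction maps each tie-free score to 1 − score (tested as an
algebraic invariant).

### Statistics

Group comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration when the combined sample size is ≤ 20 and tie-free, otherwise
the normal approximation with tie and continuity corrections
(`scipy.stats.mannwhitneyu` is the engine; an independent permutation
oracle checks it in the tests). Published p-values from other
implementations may differ in trailing digits through the
exact/approximate switch; group medians are the primary summary. Pathway
enrichment is the upper-tail hypergeometric probability P[X ≥ k] with
parameters (N = universe, K = pathway ∩ universe, n = query ∩ universe,
k = overlap), Benjamini–Hochberg adjusted across pathways
(statsmodels). The universe defaults to the union of all pathway genes;
both raw and adjusted p are reported so either cutoff convention can be
applied.

## The synthetic generator

Real training data for this kind of signature are multi-cohort microarray
and RNA-seq collections; the generator reproduces the *statistical
structure* the cascade relies on, not the data themselves:

* Each gene gets one latent base value (Uniform(0, 50)), shared across
  samples and classes — a stable global expression ordering.
* Each planted pair shares a base inside its own protected interval above
  the non-planted range; the high gene sits `separation · noise_sd` above
  its partner, and which gene is high swaps between classes. The
  intervals are separated by a margin of `2·gap + 6·noise_sd`, so a
  planted gene's swing cannot cross any bystander gene: the planted pairs
  are exactly the reversal ground truth (deterministically at zero noise).
  At zero noise the separation-in-noise-units parameterization degenerates,
  so the offset falls back to `separation` on the arbitrary latent scale.
* Independent Gaussian noise (SD `noise_sd`) per gene, sample and
  platform on the latent scale; a planted pair therefore shows its class
  direction with probability q = Φ(separation/√2) per sample
  (≈ 0.921 at the default separation 2).
* Each platform then applies its own random strictly increasing transform
  (`a·x + d·tanh(x/20) + c`, a > 0, d ≥ 0). Distorting after the noise
  keeps q exactly at the closed form above while making absolute values
  platform-specific; adding further noise on the distorted scale would
  change the flip probability per platform and break that closed form,
  so platform-specific measurement error is modelled entirely by the
  platform's independent latent noise draw.
* Progression samples at level θ carry each planted pair in its cancer
  orientation independently with probability θ, so the expected score
  against the true signature is θ·q + (1 − θ)·(1 − q) — linear in θ with
  baseline 1 − q.

Everything is reproducible bit-for-bit from the seed.

**What the generator does not emulate:** realistic count or intensity
distributions, gene–gene correlation beyond the planted pairs, dropout,
overlapping signature pairs, cohort-specific sample quality. Passing
tests therefore demonstrate correctness of the algorithms and their
invariances under the generator's assumptions, not clinical performance
on real tissue.

## Default study conditions and problem sizes

The generator defaults — 500 genes, 50 planted pairs, two platforms,
40 normal + 40 cancer samples per platform, separation 2, noise SD 1,
threshold 0.90 — are the conditions under which all end-to-end properties
are evaluated, and were chosen to mirror a multi-cohort training design
of tens of samples per class per platform. The oracle-equivalence tests
run on instances up to 100 genes × 100 samples, where exhaustive
brute-force recomputation is cheap.

A consequence worth understanding: at separation 2 the per-sample
direction probability is q ≈ 0.921, so with 40 samples a planted pair
clears the 90% stability bar in one cohort with probability ≈ 0.80, and
survives all four cohort filters (2 platforms × 2 classes) with
probability ≈ 0.40. The noisy build therefore recovers roughly 40% of
planted pairs while keeping false positives at zero — the cascade is
precision-oriented by construction, exactly like fixed-threshold
stable-pair selection on real cohorts, where the surviving pair list is
a conservative core rather than an exhaustive catalogue. Raising recall
requires larger cohorts, larger separation, or a signature threshold
below the per-pair direction probability.

## Numerical and design choices

* Threshold boundary inclusive (≥), uniformly across stable-pair
  detection and the consistency filter.
* Canonical pair storage: lexicographically smaller gene first; files are
  emitted in sorted pair order, so reruns are byte-identical.
* Missing values are NA on disk and NaN in memory, distinct from zero;
  probe collapsing averages over non-missing probe values only.
* Probe collapsing keeps exactly the probes mapping to one gene and
  averages them arithmetically on the provided scale; no log decision is
  made at this layer.
* The consistency filter drops a candidate pair missing a gene in any
  cohort (it cannot reach the threshold there); a cohort in which no
  candidate pair is present at all is an error rather than a silent pass.
* No dichotomization threshold is defined on the score; downstream
  comparisons are by group statistics (medians, rank-sum tests) only.

## Known limitations

* Recall of the build cascade degrades quickly once the within-class REO
  frequency approaches the stability threshold (see above); the pipeline
  reports per-stage pair counts so this is visible.
* The exact Wilcoxon path requires tie-free data; heavily tied small
  samples fall back to the approximation.
* All-pairs tallies for genome-scale universes are streamed, but
  *materializing* them (`count_pair_directions` without a restriction
  set) is the caller's memory responsibility; the cascade itself filters
  block-by-block.
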