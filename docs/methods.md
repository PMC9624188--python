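# Methods

This note documents the statistics `gramprod` computes, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not establish about real transcripts.

## Data model

A *token* is one usage event: a lemma (the lexical item whose combinatorial
spread is measured, e.g. a verb stem) paired with a surface marker (an affix
such as `-en` or a subject pronoun such as `she`). Tokens form an ordered
multiset: repeated identical events are counted separately, and no operation
reorders, drops or deduplicates tokens except the explicitly filtering ones.
Lemmas are casefolded on read by default (transcript exports capitalize
sentence-initial words); a flag disables this.

A *paradigm* is an ordered set of K agreement slots plus an allomorph map
from surface markers to slots. Creativity is counted over **slots, not
surface strings**: Spanish `-as`/`-es` are one second-singular cell, English
`she`/`he` one third-singular cell. This is what makes the ceiling K = 6
hold for both built-in paradigms — at surface granularity the Spanish
present indicative would have twelve "forms". Marker matching is
case-insensitive after Unicode NFC normalization, with diacritics preserved
(`áis` ≠ `ais`) and a single leading hyphen ignored, so `com_o` and
`com_-o` parse identically. Unmapped markers raise in strict mode and pass
through (folded) otherwise; pass-through exists because third-party token
lists may already be slot-coded in a private scheme. In pass-through mode
the `[1, K]` bound is not enforceable — the paradigm cannot bound codes it
does not know.

The English `en-prog` paradigm keys slots by subject pronoun. Bare *you* is
slot-ambiguous on the surface; the map expects the disambiguated codes
`you_sg`/`you_pl` that a morphological-tier extraction produces. `it` is
included as a third-singular alias alongside `she`/`he`.

## Estimators

Per-lemma creativity in a single sample is the number of distinct slots the
lemma is attested with, an integer in `[1, K]`. Sample-level:

* **CRE** = mean of per-lemma creativity across lemma *types*
  ("inflections per verb"); the accompanying sd is the descriptive
  across-lemma standard deviation with the n−1 denominator (a convention
  choice; nothing downstream depends on it).
* **TRI** = 100 × (#lemmas attested in exactly one slot) / (#lemma types).
  The denominator is lemma types: this is the reading under which the
  reported percentages and verb counts of published tables are arithmetically
  consistent (e.g. 53.79% of 145 is exactly 78 one-form verbs).

### Lexical-hazard control (LH)

Both samples are restricted to tokens whose lemma occurs in both. This is a
pure filter: order-preserving, idempotent, and symmetric in which lemmas
survive. An empty intersection is an error, not an empty result.

### Sample-hazard control (SH)

The larger sample (sample 2 by convention) is reduced to the reference size k
by drawing `n_subsamples` (default 1,000) uniform random subsamples
**without replacement** and averaging each lemma's per-draw distinct-slot
count. Without replacement is deliberate: a subsample is a subset of the
observed corpus, which guarantees the monotonicity property that a lemma's
averaged creativity never exceeds its full-sample creativity, and makes the
average a Monte-Carlo estimate of the multivariate-hypergeometric
rarefaction expectation

    E[D_v] = Σ_m (1 − C(n − c_vm, k) / C(n, k)),

where `c_vm` counts tokens of lemma v in slot m and n is the filtered sample
size. The test suite checks the Monte-Carlo machinery against this closed
form (implemented independently, with its exact variance for the standard
error) on enumerable fixtures.

Order of controls: LH first, then SH — lemmas absent from one sample are
removed before subsampling.

Open choices, resolved as follows:

* **Match size `k` defaults to sample 1's *unfiltered* token count**
  (`prefilter_sample1`). In published reports of this design the token count
  of the size-matched row equals sample 1's raw size in every comparison,
  so that is the default; `postfilter_sample1` and an explicit integer are
  available as flags.
* **`absent_policy` defaults to `zero`**: a draw containing no token of
  lemma v contributes 0 to v's average, which makes the average an unbiased
  estimate of the expected creativity at size k (a lemma you would not even
  catch at that sample size contributes no creativity). `skip` (average
  only over draws containing the lemma) is offered; under `skip` with k = 1
  every average is exactly 1. A lemma missed by every draw under `skip`
  reports 0 — only possible for very rare lemmas at tiny k.
* **TRI under LH+SH is taken from the full filtered sample**, not from the
  subsamples: subsampling does not change which lemmas are one-form, so the
  LH and LH+SH rows carry identical TRI by construction (and the suite
  asserts it).

### Difference vector and bootstrap

After LH both profiles cover the same lemmas, so differences are paired:
`delta_v = CRE_2(v) − CRE_1(v)`, lexicographically ordered, with sample 2 the
averaged (adult / later) profile. The mean difference M is the target of
inference.

Ordinary nonparametric bootstrap: R = 10,000 resamples of the delta vector
with replacement, statistic = mean. Intervals:

* **Percentile**: type-1 (inverse-ECDF / nearest-order-statistic) empirical
  quantiles at α/2 and 1 − α/2. The quantile dialect is recorded because
  implementations differ; endpoint agreement with other software is
  therefore expected only to Monte-Carlo precision.
* **BCa**: bias correction `z0 = Φ⁻¹(#{θ* < θ̂}/R)` and acceleration
  `a = Σ(θ̄−θᵢ)³ / (6 [Σ(θ̄−θᵢ)²]^{3/2})` from the jackknife of the mean;
  adjusted levels `α_j = Φ(z0 + (z0+z_j)/(1 − a(z0+z_j)))` indexed into the
  same replicate order statistics.

Degenerate inputs are contracts, not crashes: a constant delta vector yields
the interval `[c, c]` with a `degenerate` flag; if every replicate falls on
one side of the observed mean, the z0 count is clamped to `[1, R−1]` and
flagged. With z0 = 0 and a = 0 injected, BCa reproduces the percentile
interval exactly (asserted in the suite). Both methods are computed from one
shared replicate set per comparison. One numerical detail: order-statistic
indices are computed as `ceil(round(q·R, 8)) − 1`, because the float
round-trip `Φ(Φ⁻¹(q))` can otherwise shift an exact integer boundary by one
replicate.

The whole pipeline consumes a single seeded generator in documented order —
subsample draws first, bootstrap resamples second — so a (files, config,
seed) triple reproduces reports byte for byte.

## Synthetic-data generator

The generator emulates exactly the two statistical features the estimator is
sensitive to:

* **Zipfian lemma frequencies**: lemma probabilities ∝ rank^(−s), default
  exponent s = 1 (the classic slope of word-frequency distributions; the
  realized log-log rank-frequency slope is checked to within 0.1 at 10⁵
  tokens).
* **Per-lemma usage spread**: each lemma receives a private slot distribution
  drawn once from Dirichlet(concentration × base probabilities). The
  concentration is the single interpretable knob: 0.01 locks lemmas onto
  single slots (TRI → 100), large values approach the base distribution for
  every lemma (CRE → K, TRI → 0). The base defaults to uniform; a skewed
  preset putting half the mass on the third-singular slot (the workhorse
  cell of colloquial speech) is provided for power studies. The
  Dirichlet-over-slots form is the minimal model nesting both extremes of
  usage — fully trite and fully productive — and is a modeling choice of
  this package, not an empirical claim.

Tokens are i.i.d. given these distributions, with transcript indices
assigned in consecutive blocks (default 10) so chronological splitting can be
exercised. Paired designs share `ceil(fraction × min(n_lemmas))` lemmas,
which occupy the top Zipf ranks of both inventories (frequent verbs are the
ones both speakers use); private lemmas populate the tail, so the LH filter
removes a small fraction of tokens, as in real child–caregiver data.

What the generator does **not** emulate: discourse and utterance context,
burstiness/topic clustering of lemmas, acquisition dynamics within a sample,
transcription errors, or any correlation between a lemma's frequency and its
slot spread. Passing calibration on synthetic pairs therefore shows that the
estimator and its intervals behave correctly **under the model's own
assumptions** (i.i.d. tokens, stationary usage); it cannot certify coverage
on real transcripts, where tokens are autocorrelated.

## Calibration study sizes

The acceptance suite runs a seeded frequentist check of the full pipeline:
200 null pairs (identical concentration 2.0, 60 lemmas, Zipf 1.0, 1,000 vs
1,300 tokens, full lexical overlap) must give 95% BCa coverage of zero
within 95% ± 4%; 100 alternative pairs (concentration 0.4 vs 6.0, 5,000 vs
6,000 tokens) must exclude zero positively in at least 90% of runs. The null
design uses sample sizes close enough that the zero-contribution of draws
missing a rare lemma is negligible against the standard error of the mean
difference; the repeated runs use 300/200 subsamples and R = 2,000
replicates, sizes at which the Monte-Carlo error is far below the interval
widths being checked while the whole study runs in well under a minute on
one CPU.

## Known limitations

* Creativity is bounded by K, so the measure saturates for very productive
  speakers in small paradigms; differences near the ceiling are compressed.
* The `zero` absence policy slightly depresses the averaged creativity of
  lemmas that are rare in the larger sample relative to the match size; this
  is a property of rarefaction itself (rare lemmas genuinely contribute
  little at small sample sizes), but it means the mean difference is not
  exactly centered when the two samples' lemma-frequency profiles differ
  strongly.
* Token lists are taken at face value: no lemmatization, no error filtering,
  no handling of homophonous forms — disambiguation belongs to the upstream
  extraction from annotated transcripts.
* BCa endpoints on small lemma sets (n ≲ 30) inherit the usual small-sample
  wobble of bootstrap intervals; the percentile interval is reported
  alongside precisely so the two can be compared.
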