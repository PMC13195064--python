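# Methods

## The task and the model

A 2AFC translation-matching trial shows two Czech words and, below them,
their two translations in a language the participant does not know; the
participant links each Czech word to one translation.  With the pairing
random, a guesser is right with probability ½.  The analysis asks how much
each *cue* — cognacy, length alignment, phonological resemblance, frequency
alignment, semantics, plus design variables — shifts the log odds of a
correct answer.

Correctness of participant *p* on trial *t* is modelled as

    correct_pt ~ Bernoulli(σ(η_pt)),
    η_pt = β₀ + Σ_k (β_k + b_pk) · x_ptk  (+ β_age·age_p + β_gender·gender_p)

with participant random components b_p ~ N(0, diag(σ²)).  Analyses are per
language pair; trial-level covariates are standardized (mean 0, SD 1 within
the language's dataset).  For unrelated language pairs the cognate covariate
is identically zero and is dropped from that language's model.

### Estimation

`fit_mixed_logistic` maximises the Laplace-approximated marginal
likelihood.  For a candidate vector of random-effect scales, fixed effects
and the participant modes are found jointly by penalised iteratively
reweighted least squares; the participant-block structure of the Hessian is
exploited (per-participant q×q blocks, Schur complement on the fixed
block), and the Laplace log-determinant correction is accumulated block by
block.  The scales are optimised on the log scale by Nelder–Mead.  Inner
tolerance is 1e-6 on the gradient norm with at most 200 Newton steps; the
convergence flag combines inner and outer status and is never silently
true.  Wald 95% intervals and normal p-values for the fixed effects
condition on the estimated scales (as in lme4's summary); random-effect
covariance is diagonal — with 34 trials per participant a full covariance
is not identifiable.  A model with no random terms falls back to an
ordinary logistic GLM (statsmodels).  Coefficients larger than 10 in
absolute value attach a separation warning.

The choice of an own Laplace implementation (rather than a Bayesian
variational or MAP approximation with priors) keeps the zero-variance limit
exactly equal to the plain GLM and makes the estimator the conventional
frequentist GLMM; it is cross-checked in the test suite against lme4's
`glmer` (Laplace, nAGQ=1) on the random-intercept model and against the
plain GLM when the generating random-effect variance is zero.

### Baseline (residual) correctness

The standardized intercept answers "how well do participants do at *average*
cue values", not "with no cues".  `baseline_correctness` therefore takes a
re-fit on raw-scale cue covariates — cognate, semantic distance, both
phonological similarities, length agreement (uncentered), log-frequency
agreement (centered, as its raw zero is not meaningful) — without
demographic or design terms, and returns the inverse-logit of its intercept
and interval bounds.  Passing a standardized fit is a contract error.

### Uncertainty

Pooled correctness uses a participant-wise bootstrap: participants are
resampled with replacement (default B = 10,000; percentile 95% interval).
Percentile is the plainest defensible choice; the interval is degenerate
when participants are identical, which the tests assert.  Per-translation
accuracies get exact Clopper–Pearson intervals from beta quantiles; a
translation is flagged "significantly above chance" when the lower bound
exceeds ½.  Each response counts toward both words shown in the trial.

## Phonological distances

### Segmentation and the feature table

Words are segmented by greedy longest match against the packaged inventory
(40 segments: the Czech transliteration alphabet, long vowels as single
length-marked segments, affricates as single segments).  The table assigns
21 standard articulatory features (syllabic, sonorant, consonantal,
continuant, delayed release, lateral, nasal, strident, voice, spread/
constricted glottis, anterior, coronal, distributed, labial, high, low,
back, round, tense, long) with values −/0/+, plus one strictly positive
salience weight per feature on the levels {1, ½, ¼, ⅛}.

Substituting segment a for b costs the sum of weights of features on which
they differ; inserting or deleting a segment costs the weighted sum of its
specified (non-zero) features; the distance is the minimum-cost monotone
alignment (dynamic programming).  The metric is symmetric and non-negative
but deliberately *not* a metric in the triangle sense — weighted feature
edit distances need not satisfy it, and the tests assert only symmetry and
non-negativity.

**Calibration.**  The transliterated stimuli admit more than one defensible
IPA reading, and the salience weighting is not fully determined by theory.
Both were fixed *once* against published worked values of this metric
family (0.5, 14.5, 11.875, 23.5 for den–din, den–djena, den–hi,
směr–hōkō): transcriptions follow the Czech *loanword reading* of the
transliterations (no palatalisation of d/t/n before i, h = [ɦ], short i =
[ɪ], mě = [mj], macron vowels long) — exactly what the packaged
rule-based transcriber produces — and the weight levels were selected by an
exact search (integer program over the four levels per feature, with
constraints that every alignment cost at least the target and one achieves
it).  The result puts full weight on the major class features and on
stridency and backness, ½ on vowel height and tenseness, ¼ on voicing,
anterior and distributed, ⅛ elsewhere.  The calibration is a package-level
constant; nothing downstream depends on the particular levels beyond these
anchors.

### The 12-feature vector metric

Each word is summarised by the proportion of its segments falling in twelve
phonological classes: obstruent, nasal, liquid, fricative, sibilant,
labial, coronal, dorsal, high vowel, low vowel, front vowel, rounded vowel
(each class is a predicate over the feature table, so the set is swappable;
`sum` and binary `presence` aggregations are provided as alternatives to
the default mean).  Word distance is the Euclidean distance of these
profiles.  With mean aggregation this reproduces the published values
0.4055 (= √37/15) and 1.1667 (= 7/6) for den–djena and den–hi; the class
set was selected once from phonologically natural candidates to match
those two anchors and is documented here precisely because the underlying
feature list is not fully specified by its source.

### Distance summaries

`distance_summary` reports (i) the median matched-pair distance between
each foreign word and its own Czech target, and (ii) for each Czech word
the median distance to *all* foreign words, and the median of those
medians.  Medians use the midpoint convention for even counts; row order is
irrelevant (asserted by a permutation property test).

## Experiment design

Sessions pair the 68 concepts by an independent uniform random perfect
matching per participant (each unordered pair occurring with probability
1/(n−1), chi-square-checked in the tests), shuffle trial order, and invert
exactly half the trials (17/17).  Exact balancing makes the inversion
effect orthogonal to participants; an independent-coin-flip mode exists for
sensitivity checks since the original balancing procedure is not described
beyond "equal".  Each participant draws from an independent child stream of
the master seed, so generation is reproducible and order-independent.
Scoring: choosing the diagonal mapping is correct exactly on inverse
trials.

## The synthetic generator

The generator emulates the study materials' structure, not their content:

* Czech log frequencies come from three occurrence strata (22 low / 23 mid
  / 23 high per 68 concepts, uniform in log within stratum, upper stratum
  up to 3·10⁴ occurrences);
* lengths follow a shifted binomial on {2..12} phonemes, linked to
  frequency by a latent correlation of −0.45 (Zipf's brevity law);
* foreign lengths and log frequencies correlate with Czech through a
  Gaussian copula at the per-language targets (lengths 0.67/0.45/0.46/0.41
  and log frequencies 0.84/0.72/0.55/0.59 for Latvian/Hindi/Japanese/
  Turkish); the latent correlation is inflated by ≈4% to offset
  discretisation loss, and for related pairs the copula target is
  discounted by the cognate share (cognates copy the Czech string and
  contribute near-perfect length correlation of their own);
* forms are CV-alternating strings over language-biased inventories
  (disjoint enough that non-cognate edit distances are large, matching the
  observed medians above 20); cognates (Latvian ≈18% full + 7% partial,
  Hindi ≈4% + 6%, none for Turkish/Japanese) perturb the Czech segment
  string by 1–2 edits (3–4 for partials, coded 0.5);
* embeddings are anisotropic Gaussian (default dimension 50, covariance
  spectrum ∝ k^(-1.5)) so pairwise distances have the ~30% relative spread
  of real word-embedding spaces — an isotropic draw makes all distances
  nearly equal, which both misrepresents real embeddings and leaves the
  baseline intercept ill-identified; there is still no semantic structure;
* responses follow the logistic model above with per-language coefficient
  profiles at the published magnitudes and the intercept at the logit of
  the observed pooled correctness; random-effect SDs default to 0.3
  (intercept) and 0.1 (slopes), values the sources do not state, chosen
  once as moderate heterogeneity; age and gender are simulated with zero
  true effect.

What passing tests on this material do **not** show: that real participants
behave like the generator (no semantic structure, no phonotactic reality
beyond CV bias, no learning or fatigue, independence of trials given the
random effects).  They do show that the pipeline recovers what it assumes:
generated coefficients are re-estimated with correct signs and near-nominal
CI coverage at the study's scale.

The four packaged `lexicon_synthetic_*.tsv` fixtures are one draw of this
generator (seed 68).  Their distance-summary medians — Japanese
target-median 22.1, Hindi median-of-medians 21.4, Latvian 24.0 — sit in the
published 20–27 range but are properties of the synthetic draw, not of the
original word lists.

## Numerical and interface choices

* IPA is NFC-normalised everywhere; combining marks attach to the
  preceding base symbol via longest-match segmentation.
* Phoneme counts are stored and validated against the segmentation;
  mismatch is an error, not a warning.  Generated forms are canonicalised
  by re-segmentation (adjacent sampled segments may merge into affricates).
* Standardization is per language dataset, ddof = 0; constant covariates
  raise by name.  sign(0) = 0 in the agreement metrics.
* Lexicons are tab-separated UTF-8 (transliterations contain commas next
  to diacritics); floats are written at 6 significant digits (embeddings
  at 4), making write∘read a byte-level fixpoint.
* Bootstrap and generator randomness derive from `numpy` SeedSequence
  spawning; identical (config, seed) gives byte-identical output.
* Replicate counts in the acceptance checks (15 full-scale recovery
  replicates, 150 bootstrap cohorts) are the package's default desk-scale
  settings; the estimator itself has no Monte Carlo component.

## Known limitations

* The Laplace approximation is first-order; with 34 trials per participant
  its fixed-effect bias is small but not zero (the recovery tests bound it
  in practice).
* The grapheme-to-phoneme transcriber implements the loanword reading only;
  native-Czech orthographic subtleties (voicing assimilation, syllabic
  liquids) are out of scope, and fixture IPA is authoritative where it
  exists.
* The vector metric's class set matches its two published anchors exactly,
  but other 12-feature sets are consistent with them; the set is
  configuration, not a claim about the original feature list.
* Cognate codings in real materials are expert judgements; the generator's
  cognates are mechanical perturbations.
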