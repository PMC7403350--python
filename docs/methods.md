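# Methods

This note documents the models, statistics and design choices behind
`orthopop`, in the order the pipeline runs them.

## Stimuli

Strings are four-letter words (drawn from a packaged list of 959 common
four-letter English words) and pseudowords generated under the
one-vowel/three-consonant rule, with letters sampled by coarse English
letter frequencies so that generated pseudowords span common and rare
bigrams.  Every string is rendered under 3 letter sizes × 2 cases; single
letters are rendered at each of the four string slots under the same six
variations.

Rendering uses a monospaced font (DejaVu Sans Mono, located at run time
through matplotlib) on a square pixel grid: 32 px per degree of visual
angle, an 8° (256 px) canvas, letter heights of 0.8°/1.2°/1.6°
(small/medium/large).  The glyph advance equals the letter height in
degrees, so a four-letter string spans 3.2°/4.8°/6.4° and inter-letter
spacing is proportional to letter size.  Anti-aliased intensities are
binarized at half the peak intensity, which makes masks bit-exact and
rendering deterministic.  A tiny synthetic bitmap font whose b/d and b/p
glyphs are exact horizontal/vertical mirror pairs ships in source form for
tests of the reflectivity statistic and of mirror-symmetric tuning.

**Bigram frequency.** A string's mean bigram frequency is the arithmetic
mean of its three adjacent-bigram frequencies, in counts per million bigram
tokens.  The packaged table is frozen in the repository and was computed
once, by the shipped `build_bigram_table`, from the packaged word list; it
is a stand-in for corpus statistics, adequate because the analyses use only
the *ranking* of strings by frequency (decile binning), never absolute
counts.

**Reflectivity.** R is the pixel intersection-over-union of one letter mask
with the other letter mask mirrored about its own bounding-box centre
("horizontal" = left-right, the b/d contrast; "vertical" = top-bottom, the
b/p contrast).  Binary pixels are used, and the two bounding boxes are
aligned at their centres before the overlap is taken (the registration rule
is otherwise undetermined; centre alignment makes R independent of where
the letter sat on the canvas).  Masks are internally upsampled 2× so centre
alignment is exact, which makes R symmetric in its arguments to machine
precision.  Identity pairs are excluded from all pair-level analyses
because most letters are more horizontally than vertically self-symmetric,
which would bias the mirror-symmetry analysis; 26 letters give C(26,2) =
325 pairs.  Lower case is the canonical basis for pair reflectivity (the
classic mirror pairs b/d and p/q are lower-case forms).

## Synthetic populations

The generator is a stand-in whose contract is to realize the statistical
structures the analyses assume; it is not a biophysical model.  Per site:

- **Letter tuning** is template matching on glyph pixels: each site carries
  a sparse nonnegative mixture over three template letters and responds to a
  letter by the bounding-box-aligned IoU between its glyph and the
  templates.  Similar-looking letters therefore evoke similar responses,
  which is what gives letter decoders visually structured confusions.  The
  z-scored similarities pass through exp(z/τ) with temperature
  τ = 0.3 + 4(1 − s), where s = `tuning_sparsity` ∈ [0, 1] maps onto
  near-uniform (s = 0) to near-one-hot (s = 1) tuning; the default 0.5
  yields the broad tuning regime.
- **Mirror-symmetric sites** (fraction `mirror_symmetric_fraction`, default
  0) use the reflection-invariant similarity max(IoU(a, t), IoU(mirror(a),
  t)), so two glyphs that are exact horizontal mirrors evoke identical
  expected responses.
- **Position tuning**: a preferred slot softened by `position_tolerance`
  (1 = position-invariant, 0 = one-slot), mean-one normalized, then scaled
  by `contralateral_bias` (default 1.5) on the two slots contralateral to
  the site's hemisphere (slots 1–2 for right-hemisphere sites).
- **String responses** are the sum of the four letter-at-slot responses
  (so with no conjunctive terms, string rate = Σ letter rates − 3 ×
  baseline exactly), plus `nonlinearity_weight` × random conjunctive terms
  for the three adjacent letter pairs (default 0.25 — some, but not
  dominant, nonlinear structure).  Letter-string encoding analyses recover
  exactly this planted decomposition.
- **Word selectivity**: a fraction `frac_word_selective` (default 0.1) of
  sites receives an additive lexical-class offset.  Because an additive
  offset leaves within-class variances untouched, the offset realizing a
  target d′ is available in closed form, δ = (d′_target − d′_baseline) ×
  pooled SD of the noise-free stimulus means, where d′_baseline is the
  class separation the site already shows through its letter tuning (word
  and pseudoword strings differ slightly in letter statistics).  Targets
  are drawn uniformly from `word_dprime_range` (default 0.15–0.45, keeping
  |d′| < 0.5) with random sign.  Repetition noise attenuates the realized
  repetition-averaged d′ slightly below target; at the default 32
  repetitions the attenuation is small.
- **Windows and noise**: the early window (70–170 ms) carries the drive,
  the late window (170–270 ms) the same drive at half amplitude; baseline
  activity is emitted per trial for the visual-drive screen.  Default noise
  is `poisson_like` (spike counts in a 100 ms window, variance ≈ mean);
  `gaussian` with configurable SD exists for analytic tests.  Baseline rate
  10 spikes/s, gain 10 spikes/s per unit drive — evoked rates of tens of
  spikes/s.
- **Geometry**: sites fill 10 × 10 grids (unique cells per array), arrays
  alternate hemispheres.  Planted selectivity is spatially unstructured, so
  topography tests see a true null by default.

**Reference behavior** emulates a pool of subjects classifying words vs
pseudowords: P(choice = word) is a lapse-mixed logistic with a class term
(default weight 0.9, i.e. ≈ 71% accuracy before lapses) plus a
bigram-frequency slope applied to pseudowords only (default 0.8 per log10
count/million).  A slope shared by both classes would cancel in the per-bin
d′ and flatten the signature; applying it to pseudowords makes the
false-alarm rate rise with bigram frequency, which is the difficulty
structure the consistency analyses compare against.  Subjects share
parameters and differ only by independent Bernoulli trial noise, so the
subject-pool hold-out consistency approaches 1 with enough trials.

What the generator does **not** emulate: temporal dynamics beyond the two
windows, correlated noise across sites, adaptation across repetitions,
eccentricity/receptive-field structure, or any difference between
multi-unit and single-unit activity.  Passing tests therefore demonstrate
that the *analysis machinery* is correct and calibrated under the planted
structure — not that real cortical populations behave this way.

## Screens and features

Decoding features are the repetition-averaged rates of the two windows
concatenated site-wise (each site contributes two features); single-site
analyses use the early window only.  The visual-drive screen is a two-sided
Wilcoxon signed-rank test of trial-wise evoked minus baseline rate at
α = 0.001 (the test statistic is otherwise unspecified; signed-rank is
distribution-free on rates).  The letter-reliability screen computes the
Pearson correlation of two random repetition-half mean response patterns
over the letter stimuli, averaged over 20 resplits, at α = 0.01.
Significance uses the one-sided Pearson p of a single seeded split: testing
the resplit-*average* against a naive null is anti-conservative because
resplits share repetitions (measured false-positive rate ≈ 0.10 at nominal
0.05 in a Monte-Carlo check), while a single split is one genuinely
independent-halves comparison and calibrates at α (verified in the suite).

## Decoding battery

Tasks are binary discriminations solved by L2-regularized logistic
regression (a weighted sum plus threshold) with ten-fold stratified
cross-validation over stimuli; features are standardized using
training-fold statistics only; class probability > 0.5 is the choice, with
ties resolved to the negative class.  The regularization strength C = 1 was
frozen once after a nested-validation sweep (C ∈ {0.01, 0.1, 1, 10}) on a
synthetic pilot population, where accuracy plateaus from C = 1 upward.
Reported performance is always balanced accuracy.  Site sampling repeats
the whole procedure over independent random site subsets (both window
features of a site move together); fold plans depend only on (labels,
seed), so external feature matrices are scored against identical folds.

The default battery is 20 invariant letter-identification tasks + 8
invariant bigram-identification tasks + 2 word-classification variants
(canonical views of the base set; the 40 + 40 × 5-variation invariant
subset of 400 stimuli).  Which 20 letters and 8 bigrams is not prescribed,
so the default picks the most label-balanced tokens deterministically
(alphabetical tie-break), overridable explicitly.

## Behavioral signature and consistency

Words and pseudowords are independently rank-binned into ten
bigram-frequency deciles; bin i pools word decile i (hits) with pseudoword
decile i (false alarms), and d′ uses all trials in the bin with rates
clipped to [1/(2N), 1 − 1/(2N)].  The decile pairing is one reading of an
ambiguous construction ("ten equally sized bins separately for words and
pseudowords" feeding a ten-dimensional pattern); rank-matched pairing keeps
every bin populated with both classes by construction.

Consistency ρ̃ = ρ(m, p) / √(ρ(m, m) ρ(p, p)) is computed per trial
resplit: both systems' trials are halved within stimulus; the raw ρ is the
mean Pearson correlation of the four cross-system half pairs; the
reliabilities are the within-system half correlations; ρ̃ is averaged over
10 resplits.  All terms use the same number of trials, so no
Spearman–Brown extrapolation is needed.  A resplit with a non-positive
reliability is reported as undefined, never coerced.  The estimator is
consistent but, being a ratio, carries a Jensen-type upward bias when
reliabilities are noisy; the parameter-recovery test therefore runs in the
well-powered regime.  For decoders, "trials" are independent
cross-validation repeats with different fold plans — decoder outputs are
deterministic given folds, and resampling folds restores trial-like
variability.

## Single-site statistics

Bootstrap selectivity test: stimuli are resampled with replacement within
class (100 draws by default), and the two-tailed exact p is
2 · min(P(boot ≤ 0), P(boot ≥ 0)) with add-one smoothing of the tail
fractions — without smoothing, the min of two noisy tail estimates makes
the test anti-conservative at small bootstrap counts.  Degenerate resamples
(zero pooled variance) are dropped and counted, not fatal.

Sparsity nulls preserve repetition noise.  Uniform: category labels are
shuffled across all trials, then averaged — a noise-free uniform site
scores SI = 0.  One-hot: the top category is inferred from one repetition
half; on the other half the top category keeps its measured trials while
every other category is replaced by its own mean-removed residuals
(rectified at zero) — a noise-free one-hot site scores SI = 1.  This
construction is the package's definition of the one-hot null, chosen to
meet the noise-free endpoints while fixing trial variability.  Population-level
comparisons use a permutation test of medians: the null median distribution
is the per-permutation median of null SIs across sites.  Negative
repetition-averaged rates (possible under Gaussian noise) are rectified at
zero before SI.

Moran's I uses rook adjacency with row-standardized weights on each 10 × 10
grid (the weight scheme is not prescribed; rook/row-standardized is the
common default and makes a perfect checkerboard score exactly −1), averaged
over arrays, with a joint permutation null (100 shuffles of site values
across occupied cells per array) and a one-sided (clustering) p by default.
Binomial proportion tests are exact (scipy): one-sided for the selective
fraction against p₀ = 0.05, two-sided for hemisphere bias against the
hemisphere sampling fraction.

## Encoding models

Per site, the response to each string is regressed (OLS with intercept) on
that site's own repetition-averaged responses to the constituent letters at
the corresponding slots, ten-fold cross-validated over strings.  Substring
models (best 1/2/3 of the 4 slots) select the subset by exhaustive search
on the training fold only (lowest residual sum of squares, ties to the
lowest slot indices), keeping selection and testing independent.  The bag-
of-letters model applies one fixed random slot permutation to all strings.
Letter predictors are matched at canonical case/size (upper, medium by
default).

The noise adjustment divides the cross-validated prediction–measurement
correlation by the square root of the Spearman–Brown-corrected split-half
reliability of the measured string responses, 2r/(1 + r) converting
half-data to full-data reliability.  Model predictions are deterministic
given predictors, so only the measurement side needs adjusting — this
realizes the contract that a fully predictive model scores ≈ 1 at any
repetition count (the two-noisy-systems consistency formula does not apply
here, and no exact formula is prescribed).  Model medians are compared by
a one-tailed exact test on medians bootstrapped jointly over sites.

## Mirror-symmetry analysis

A 26-way multinomial logistic decoder maps each letter stimulus to a
26-vector of class probabilities.  Cross-validation is
leave-one-position-out: the decoder embedding position p's stimuli is
trained on the other three positions, so no stimulus is embedded by a
decoder trained on its own position instance (the cross-validation unit is
not prescribed; position hold-out prevents trivial memorization and tests
position tolerance).  Embeddings are averaged over the case/size variations
at each position.  r_IT for a letter pair is the Pearson correlation of the
two 26-vectors at one position, averaged over the four positions.

The ΔR analysis sorts the 325 pairs by ΔR = R_H − R_V, computes a
five-pair boxcar rolling average of r_IT, cuts ΔR into three equal-range
bins, and reports per-bin mean ± SE, one-tailed one-sample t-tests of a
positive mean in each extreme bin, and a one-tailed Welch two-sample t-test
of rightmost > leftmost.

**Known limitation.** With pixel-template tuning, letters in the rightmost
ΔR bin (b/d, p/q in lower case) also share substantial *raw* overlap, so
even a population with no mirror-symmetric tuning shows some similarity
structure along ΔR; the planted-effect check is therefore the directional
contrast under `mirror_symmetric_fraction = 1`, where reflection-invariant
tuning makes exact mirror pairs maximally confusable.

## Problem sizes

Default study conditions: 200 sites, 32 repetitions per image, 150 + 150
strings × 6 variations, the full 26 × 4 × 6 letter set, six reference
subjects at 40 trials per stimulus.  Tests and calibration checks run the
same machinery at reduced sizes (tens of sites, 8–32 repetitions, hundreds
of null replicates), chosen as the smallest problems at which the checked
property is unambiguous.

## Tensor container

HDF5 with datasets `rates` (windows × sites × stimuli × repetitions,
spikes/s), `baseline_rates`, `stimulus_ids`, `window_labels`, a `site_meta`
group (site_id, array_id, grid_row, grid_col, hemisphere) and an optional
`ground_truth` group recording the planted per-site structure; attribute
`schema_version` (major-version compatibility enforced on read).
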