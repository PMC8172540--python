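# Methods

## The analysis

`strinit` implements an analysis of transcription initiation at short tandem
repeats (STRs, microsatellites): many STRs behave as transcription start
sites, with strand-specific, class-dependent initiation that is predictable
from local sequence. The pipeline has five layers:

1. **Signal quantification.** Given strand-specific 1-bp CAGE-like 5'-end
   coverage and an STR catalog (HipSTR BED dialect, (+)-strand normalized),
   the initiation signal of an STR is

   S = ( Σ_{p ∈ [start−5, end+5)} cov[p] ) / (L + 10),  L = end − start.

   The ±5 bp window is half-open, which is exactly what the L + 10
   denominator implies; with uniform coverage c the statistic equals c for
   any L, removing the length dependence that raw tag sums have (spurious
   unit counts accumulate along long repeats). Every catalog STR is
   evaluated in both orientations — the (−) orientation's class key is the
   reverse-complemented motif, and its 3' end is the STR start (1-based
   start + 1; on (+) it is the 1-based end). Transcription directionality
   per locus is D = (S⁺ − S⁻)/(S⁺ + S⁻) ∈ [−1, 1], undefined when both
   signals are zero (D is computed whenever either strand has signal; the
   extreme values ±1 are meaningful and do occur).

2. **Capped-5'-end validation.** Reverse transcription of the
   7-methylguanosine cap adds a template-mismatched G at tag 5' ends. A tag
   is "first-base mismatched" when its MD descriptor starts with a 0-length
   match ((+) strand) or, symmetrically, ends with a substitution ((−)
   strand; the printed command of the original analysis counted (+) tags
   only, so a strict `plus_only` mode is provided). Capped tag sets show a
   strong G excess among mismatched first bases; uncapped controls do not.
   Tags with indel descriptors are skipped and counted. Both normalizations
   (share of all intersecting tags, share of mismatched tags) are reported
   because the choice is ambiguous in figure legends of this kind.

3. **Sequence models.** Examples are 101-bp windows centered on the 3'-end
   base (the center column *is* the 3'-end base, making offset 0
   well-defined), reverse-complemented for (−) orientations, one-hot
   encoded (rows A,C,G,T; N = all-zero column). Masking schemes: the 7
   bases immediately downstream of the 3' end can be replaced by Ns (they
   may contain repeat-motif bases that are trivially learnable), and a
   flank-only layout replaces the entire STR by 9 Ns regardless of its
   length — 50 bp upstream flank + 9 N + 7 N + 43 bp downstream flank = 109
   positions. Because the upstream flank lies beyond the STR 5' start, the
   flank-only layout is re-extracted from the genome rather than cut from
   the centered window. The model is a small convolutional network: one
   convolution stage (50 filters, width 12), ReLU, max-pooling (width 4),
   two fully connected stages (64, 16) with dropout 0.30, and a single
   output unit — linear for regression, sigmoid for pairwise
   classification. Regression targets default to the natural signal scale
   (the 0.2 error threshold used downstream is on that scale); a log1p
   switch is provided, and the shipped end-to-end study uses it because
   the signal noise is multiplicative lognormal, which makes log-scale
   squared error the natural loss — natural-scale MSE is dominated by the
   irreducible noise of the largest signals and starves early stopping.
   Rank metrics are invariant to the monotone transform, and predictions
   are mapped back with expm1 wherever the natural scale matters. The two tasks differ only in that last unit.
   Training: Adam (lr 1e-3, batch 256), mean squared error / binary
   cross-entropy, early stopping with patience 5 on the validation loss,
   best-validation weights retained. "Stops when the validation loss drops
   for five consecutive epochs" is read as standard patience (five epochs
   without improvement); the literal reading would stop on improvement,
   which is not a stopping rule. Splits (70/15/15 by default — the split
   fractions are conventional, not prescribed) are made before training,
   persisted as JSON manifests, and reload to the identical partition.
   For pairwise classification the majority class is downsampled to the
   minority size (seeded). Identical windows are not deduplicated before
   splitting. The network is implemented directly in numpy (im2col
   convolution, manual backpropagation); training is deterministic given
   the seed, and models persist as an npz archive of spec + weights +
   training log.

4. **Interpretation.** Filter influence: zero one first-layer filter's
   activation map (no retraining, no renormalization), recompute the test
   metric, influence = baseline − ablated; when ablation leaves a constant
   predictor the metric is undefined and influence counts as total loss.
   The significance threshold retrains the model ten times, takes the
   t-based 95% CI of the accuracies (the interval type is our choice; "CI
   length" means the full width), and sets τ = log2(CI length / 2);
   influences are reported in raw units and in log2 (non-positive values
   floored at a configurable epsilon). PWMs are built from aligned
   sequences with pseudocount 0.5 and scanned as log-odds against a uniform
   background, keeping the per-sequence maximum; N contributes 0. The
   external scanner's p-value machinery is deliberately not reproduced —
   only max scores are needed downstream. In-silico mutagenesis draws
   positions uniformly over the window and alternative bases uniformly
   from the three non-reference bases; the impact at a position is the
   variance of the prediction deltas (reference − mutated) observed there,
   indexed relative to the 3'-end column. Positional event distributions
   are compared with a two-sample Kolmogorov–Smirnov test on raw offsets.

5. **Variant effects.** Only SNVs are scored (indels would misalign the
   window; they are counted and skipped). A variant is applied on the (+)
   genome strand; windows are re-extracted per orientation, so (−)
   orientations automatically see the complementary allele. For eQTLs the
   pipeline keeps STR orientations within 1 kb of the target gene's start,
   eQTL SNVs within −15/+30 bp of the 3' end in transcript orientation
   (position 0 = the 3'-end base), deduplicates on (variant, STR, gene),
   compares sign(predict(alt) − predict(ref)) with the slope sign,
   stratifies by reference-genome prediction error ε ≤ 0.2 versus ε > 0.2,
   and applies a binomial test against p = 0.5 per stratum — one-sided by
   default since the claim is directional (two-sided available).
   Zero-slope records carry no direction and are excluded. Group contrasts
   (e.g. by clinical-significance label) use one-way ANOVA plus all ordered
   one-sided Mann–Whitney tests with Benjamini–Hochberg adjustment;
   label enrichment uses two-sided Fisher exact tests, BH-adjusted across
   labels. Binomial proportion intervals are Wilson (the interval type is
   unspecified upstream; Wilson behaves well at extreme proportions).

## The synthetic world

The generator produces a toy genome (default 2 chromosomes × 1 Mb) with
10,000 STRs placed on a non-overlapping slot grid — 10,000 rather than more
because each example needs a ~200-bp footprint (body + both 50-bp flanks +
biased background) and two orientations per STR already give 20,000
examples. Four default classes (AC, AG, AAC, AGAT) are assigned
round-robin with repeat counts 4–12. Each class has:

* a **flank GC composition** (0.35 / 0.45 / 0.55 / 0.65) written into ±60 bp
  of background around the repeat, making flank-only classification
  learnable;
* a **baseline log signal** (−1.0 / −0.6 / −0.2 / 0.2);
* a **directionality type**: AAC and AGAT are directional (a strand motif,
  ACGATTCG, effect +3.0, is planted on exactly one randomly chosen
  orientation, giving expected |D| = tanh(1.5) ≈ 0.905), AC and AG are
  bidirectional (motif content planted identically on both orientations, so
  D is noise-only).

The sequence→signal closed form: for an oriented STR,

    mu(window) = baseline(class)
               + 0.5 · (min(L, 50) − 24) / 10
               + Σ_m effect(m) · [motif m present at its fixed downstream
                 offset],

where L is the repeat length — a term readable only from the STR body
(always 9 Ns in flank-only inputs), so the generative function genuinely
uses both the body and the flanks and masked models sit strictly below
full-window models —

with fixed-offset flank motifs TGACGTCA (+1.0 at offset +10, planted with
probability 0.4) and CACGTG (−0.8 at +25, probability 0.4), both outside
the 7-bp downstream mask so masked models retain them. Observed signals are
exp(mu + ε), ε ~ N(0, 0.35²) — multiplicative lognormal noise because
CAGE-like signals are nonnegative and right-skewed, and because it yields
an exact Bayes-optimal predictor: exp(mu), computed by re-scanning the
final genome (the truth table can therefore never disagree with the
sequence). With these defaults the Bayes-optimal held-out Spearman is
≈ 0.95. Motif offsets are fixed (not drawn per locus) so the mutagenesis
variance profile has well-defined peaks, mirroring how positional impact
profiles are read in practice.

Coverage realizes each orientation's signal as mass S·(L+10) spread over
five 1-bp bins at the 3' end (weights 0.1/0.2/0.4/0.2/0.1, all inside the
evaluation window — with σ = 0 and no scatter the recomputed signal equals
the truth exactly), plus unit-count scatter along the STR body at 0.02 per
bp per strand, emulating the low-count artifact real CAGE data shows along
repeats. Alignment fixtures place read 5' ends inside anchor intervals and
introduce first-base G mismatches at a stated rate with MD descriptors
consistent with the stored sequences. Variants are SNVs that either hit a
planted motif instance (closed-form nonzero effect) or draw their offset
from p(o) ∝ exp(−|o−5|/10) on [−15, 45]; eQTL slopes equal the true effect
with an optional sign-flip probability.

What the generator does **not** emulate: mappability artifacts, repeat
polymorphism between individuals, library-to-library variation (only the
mean track is consumed), GC sequencing bias, homology between training and
test windows beyond the two orientations of one locus, and any realistic
human genome structure. Passing recovery tests therefore demonstrate
correctness of the machinery and identifiability under the stated
generative law — not performance on real FANTOM/ENCODE/GTEx data, whose
headline numbers require the full multi-GB inputs and are out of desk
scope.

## Numerical choices and degenerate inputs

* Spearman uses average ranks for ties; a constant vector is reported as
  undefined (NaN with a note), never silently 0.
* AUC is exact: P(score⁺ > score⁻) + ½·P(tie), computed via average ranks.
* The shuffle operation reimplements the placement contract (length
  multiset preserved, exclusions avoided, chromosome chosen proportional to
  placeable space, seeded); bit-identity with any external binary's RNG is
  not promised. Placement failure after 1,000 tries per interval is an
  error naming the interval.
* Coverage reading rejects overlapping bedGraph records and negative
  values; absent positions are zero; window sums clip at chromosome edges
  while the nominal L + 10 denominator is retained.
* Early stopping compares against the best validation loss so far; ties do
  not count as improvement. Non-finite losses abort with diagnostics.
* Per-stage seeds derive from the global seed by stable hashing of the
  stage name, so stages are individually reproducible.
* Shuffled-label nulls permute all targets, retrain, and evaluate held-out
  performance against the permuted targets (the standard permutation
  null). Evaluating a null model against the true labels instead would
  leak the class↔flank-composition association through the near-constant
  model's residual output structure.
* Sign concordance skips zero-slope records — a slope of 0 carries no
  direction to compare (measured eQTLs are nonzero by definition).

## Problem sizes used in the shipped checks

The default test-and-acceptance study uses the default world (10,000 STRs,
20,000 oriented examples), 40 training epochs maximum for regression (20
for classification) with patience-5 early stopping, 400 mutagenesis windows
× 20 mutations, 400 generated eQTLs, and 10 permutation replicates for the
randomized baseline. These sizes were chosen so the whole study trains
comfortably on one CPU in minutes while leaving the recovery margins wide
(Bayes ≈ 0.95 vs the 0.9 floor; trained models clear the 0.8 floor).

## Known limitations

* The numpy network is CPU-only and single-threaded apart from BLAS; very
  large grids or widths are out of scope.
* The grid search trains every combination with a shared seed; it does not
  do successive halving or random search.
* JASPAR reading covers the standard 4-row PFM layout only.
* BigWig coverage must be converted to bedGraph externally; BAM must be
  converted to text SAM (headers included) for the cap-bias check.
* Cross-species transfer is supported only as cross-application of trained
  models to a second prepared dataset; orthology mapping is out of scope.
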