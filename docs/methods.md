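# Methods

## The measurement problem

EEG recorded during continuous listening time-locks to speech. The package
quantifies that tracking with the match-mismatch (MM) paradigm: a classifier
sees one EEG segment and two speech-feature segments — the *matched* one
synchronized with the EEG, the *mismatched* one taken from the same feature
streams but starting one second after the end of the matched segment — and
must say which is which. Classification accuracy is the neural-tracking
measure. Tracking of lexical-segmentation features (unit pulses at phoneme
or word onsets, PO/WO) reflects acoustic-temporal processing; any *extra*
accuracy gained by adding a linguistic feature — cohort entropy (CE) at
phonemes, word frequency (WF) at words — reflects lexical processing and is
interpreted as a marker of comprehension. The statistic of interest is
therefore the added value `L − C`: the MM accuracy of the linguistic model
minus that of its matched control, compared within subject across
comprehension conditions (paired two-sided Wilcoxon signed-rank, zero
differences dropped, at least six pairs).

## Linguistic features

The lexicon is a phonemized vocabulary with prior probabilities. The *active
cohort* of a phoneme prefix is the set of lexicon words beginning with it; a
prefix index makes the query O(|result|), and a brute-force linear scan is
kept as an independent oracle. Cohort entropy at the i-th phoneme of a word
is the Shannon entropy (bits) of the active cohort of its first i phonemes,
with priors **renormalized within the cohort** so the value is a proper
entropy in `[0, log2 |cohort|]`. Renormalization is a deliberate choice: the
raw priors of a cohort do not form a probability distribution, and without
it the quantity would not be an entropy (its lineage in incremental
word-recognition work uses the within-cohort distribution). Word frequency
is `-log10 p(word)`. Words absent from the lexicon contribute zero-amplitude
pulses for both CE and WF (the standard missing-word convention), and CE at
a word's first phoneme uses the length-1 prefix.

Feature streams are sampled pulse trains at 64 Hz: onset times are rounded
to the nearest sample (ties to even), silence contributes nothing, and two
units rounding to one sample keep a single pulse (pulses encode presence,
not counts). Intervals are half-open `[start, end)` with 0-based samples.

## EEG preprocessing

The chain order is fixed: anti-aliased polyphase downsampling to 128 Hz →
multichannel Wiener filter (MWF) eyeblink removal → common-average
re-reference → 0.5–25 Hz band-pass → downsampling to 64 Hz. The band-pass is
a cascade of least-squares FIR filters: a high-pass of order 5000 with
transition band [0.45, 0.5] Hz and a low-pass of order 500 with transition
[25, 27.5] Hz (10 % below/above the respective edges), applied with reflect
padding and 'same' alignment so the linear-phase group delay is compensated
and length is preserved. Recordings must exceed the longest filter (~39 s at
128 Hz). Channel z-scoring is applied per train/validation/test split,
never across splits.

The MWF is spatial (single-lag): artifact and clean covariances are
estimated from annotated versus remaining samples and jointly diagonalized
(GEVD); components are kept where the artifact-to-clean eigenvalue ratio
exceeds a data-calibrated null edge, and the Wiener artifact estimate is
subtracted everywhere. The null edge comes from a split-half GEVD of the
clean data rescaled to the artifact sample count: EEG is strongly
autocorrelated, so an i.i.d. (Marchenko–Pastur) bound underestimates the
eigenvalue spread and a bare ratio-above-1 rule would "remove" artifact from
recordings that contain none. With the calibrated edge, annotated-but-clean
recordings pass through bit-exactly, while genuine blinks (an order of
magnitude above background) exceed it by a large factor. Blink annotations
come from the generator's ground truth for synthetic data; a |z| > 4 frontal
-channel detector is provided for recordings without annotations.

## The match-mismatch network

The MICNN is a two-branch convolutional network. Each branch is a 1×1
(spatial) convolution into F filter channels, four dilated temporal
convolution blocks (kernel 3, dilations 1/3/9/27, tanh after every
convolution), and a 1×1 output projection to P channels with tanh. The
speech branch is applied to both candidates with shared weights. Cosine
similarity between the EEG embedding and each candidate embedding is
computed per projection channel over each of 8 aligned time blocks, and the
head is antisymmetric by construction:

```
logit = w · (sim(EEG, cand₀) − sim(EEG, cand₁)),    p = σ(logit)
```

so swapping the candidates maps p to 1 − p exactly (a required symmetry of
the task). With the default word-level configuration (64 EEG channels, 10 s
windows, F = 70, P = 29) the linguistic model has 127,270 trainable
parameters and the control model 127,200 — both round to the documented
127k. The exact internals of the published architecture are not public;
this configuration is a declared stand-in from the same dilated-convolution
family, pinned to the two facts that are public (multi-input structure and
the 127k parameter count). The network and its training loop are implemented
directly in numpy (explicit forward/backward passes, float32 arithmetic,
Adam); gradients are verified against finite differences in the test suite.

Training minimizes binary cross-entropy with Adam at learning rate 1e-3 for
up to 50 epochs, restoring the weights of the best validation-loss epoch.
Two parameters the source description leaves open are fixed as: batch size
16 (constant across pretraining and both fine-tuning modes) and early-
stopping patience 10 epochs. Both were set from training-curve diagnostics
at desk scale, where datasets are a few hundred examples: batch 64 yields
fewer than ten updates per epoch, and patience 5 frequently stops on an
early noise-driven validation minimum while the network is still improving.

Model input convention: feature streams are scaled to unit peak before
entering the network. Raw CE pulses reach ~10 bits while onset pulses are 1;
unscaled, the first tanh saturates on the linguistic stream and blocks
exactly the amplitude information the linguistic model exists to exploit.
Scaling by the maximum preserves all within-stream amplitude structure.

## Fine-tuning and splits

Pretraining uses a 60/20/20 train/validation/test layout per recording and,
in the full fine-tuning pipeline, a *separate* synthetic pretraining cohort
(fresh subjects and story; at least 12 subjects) standing in for the large
independent corpus the study pretrains on — so no evaluation recording ever
overlaps pretraining material.
Language fine-tuning (FTL, subject-independent) trains one model per
held-out subject on the other subjects' recordings — first and last 30 %
train, then 20 % validation and 20 % test — and evaluates on the held-out
subject's entire recording. Subject fine-tuning (FTS, subject-dependent)
continues from the FTL model on the subject's own recording: first and last
12.5 % train, next 25 % validation, middle 50 % test (so evaluation uses up
to half of the shortest recording). Split pieces never share samples; MM
windows and their mismatched segments must lie inside one piece in the
fine-tuning modes (in pretraining the mismatched segment may cross a piece
boundary); window hops default to the window length with denser hops
available per split. An audit utility counts cross-split window overlaps
and held-out-subject contamination; both are asserted to be zero.

## Condition classification

Per subject, condition and level, four MM accuracies — (control, linguistic)
× (FTL, FTS) — form the feature vector of an RBF-kernel SVM solving one-vs-
one condition classification. Nested cross-validation: leave-one-subject-out
outer folds (both of a subject's vectors leave together, since they are
dependent), and a grouped 5-fold inner search over C ∈ {0.01, 0.1, 1, 10,
100} and kernel width ∈ {0.1, 1, 10} × the variance-scaled default, selected
by accuracy. Feature standardization is fit on inner-training folds only.
Outer-fold decision scores are pooled into one ROC; AUC is trapezoidal;
accuracy, F1, sensitivity and specificity are computed at threshold zero
with the first-listed condition as the positive class. Statistical floor:
a permutation null obtained by randomly swapping each subject's two
condition labels and re-running the full nested CV.

## The synthetic-data generator

Real recordings for this paradigm are not publicly distributable, so every
experiment runs on synthetic cohorts with known ground truth. The generator
emulates: a lexicon (random distinct phoneme sequences, Zipf-distributed
priors; a foreign lexicon shares the phoneme inventory with disjoint
vocabulary); stories as first-order Markov word sequences with lognormal
phoneme durations (median 80 ms, σ = 0.25) and Bernoulli pauses (p = 0.2,
median 0.3 s); three comprehension conditions — coherent, scrambled (a
seeded permutation of the coherent story's word tokens that preserves the
token multiset, word-internal durations and inter-word gaps) and foreign.
Default condition durations mirror a 10/9/7-minute session design.

EEG follows the linear forward model the MM paradigm assumes: for each
feature, the pulse train is convolved with a subject-specific temporal
response function (white noise low-pass filtered below 8 Hz over 0–600 ms
lags, unit norm, with a per-channel topography), each clean component is
normalized to unit RMS so gains are comparable power knobs, components are
mixed with per-condition gains, and 1/f ("pink") noise is added at a
configured SNR. By default the SNR is defined against the condition's own
clean power (and is then exact by construction); setting
`snr_reference_condition` instead fixes the noise floor at one condition's
nominal clean power (sum of squared gains) for *all* conditions, so a
condition with fewer active features carries less signal rather than louder
renormalized components — the physically sensible choice when comparing
conditions, and the one the experiment battery uses. Each subject's TRF
shape and topography mix a
population-shared component with a subject-specific one
(`trf_subject_similarity`, default 0.7; the population component is pinned
by a cohort-independent `population_seed`). The shared component encodes the
physiological fact that evoked-response morphology is conserved across
people — without it, decoding an unseen subject (what language fine-tuning
evaluates) would be impossible by construction. Comprehension is encoded in the linguistic gains: the
default configuration gives coherent and scrambled full CE/WF gains and the
foreign condition 25 % of them, with onset gains equal everywhere. Optional
eyeblinks add a Gaussian-envelope template to frontal channels at Poisson
times, with ground-truth annotations. Everything is a pure function of its
arguments including the seed.

What the generator does **not** emulate: acoustic waveforms, realistic
phonotactics, nonlinear or adaptive cortical dynamics, latency jitter,
inter-trial nonstationarity, channel-specific noise spectra, or artifacts
other than the stereotyped blink. Passing tests therefore show that the
pipeline recovers structure injected under the linear-TRF assumption — not
that it would attain any particular accuracy on real EEG.

## Reproduction battery and operating points

`lextrack.experiments` freezes the desk-scale study replicas (all sizes are
the package's own choices for single-CPU runtimes):

- Reduced network: F = 8 filters, P = 4 projections, dilations 1/3/9/27,
  8 similarity blocks; 16-channel EEG; phoneme level (PO/CE, 5 s windows).
- **Chance control**: all gains zero (pure 1/f noise EEG), a control model
  trained on 6 subjects × 3 min and evaluated on 1020 examples from six
  held-out noise subjects; accuracy must stay inside the binomial 95 % band
  around 50 %.
- **Signal detection**: onset gains 1 at +5 dB SNR, 6 subjects × 3 min; the
  control model must exceed 70 % test accuracy within 50 epochs.
- **Added-value recovery**: 26 subjects × 150 s at −10 dB SNR; condition A
  has CE/WF gains of 3, condition B gains of 0, onset gains 1 in both. One
  C/L model pair is trained on condition A and the *same* pair evaluated on
  both conditions, so model-quality fluctuations cancel in the
  within-subject A−B contrast of L − C; per-subject differences are averaged
  over 5 seeds and tested with the Wilcoxon signed-rank across subjects.
  The −10 dB / gain-3 operating point was calibrated once so that MM
  accuracies sit between chance and ceiling (the added value is
  statistically invisible at saturation and drowned at very low SNR).
- **Type-I control**: the trained pair is held fixed and evaluated on 20
  fresh 8-subject A/A cohorts — both condition labels carry the same story
  and the same gains and differ only in the EEG noise realization — and the
  same test's rejection rate at α = 0.05 must stay near nominal. Retraining
  per replicate is computationally out of reach and unnecessary: under this
  null the per-subject contrasts are exchangeable around zero for any fixed
  evaluator. The A/A construction is deliberate: when the two conditions
  carry *different* stories (even word-shuffles of the same text), story-
  level difficulty acts as an across-subject common offset and the
  subject-level Wilcoxon is anticonservative — a confound the real paradigm
  shares, since conditions are necessarily confounded with stimulus
  material (see Known limitations).
- **Classifier recovery**: 6 subjects × 150 s, three conditions through the
  complete pretrain → FTL → FTS pipeline — a coherent story with full
  linguistic gains, a *repeat* presentation of the same story with the same
  gains (the exchangeable gain-identical pair), and a foreign story with
  none (the gain-distinct pair). The SVM's AUC must exceed the 95 %
  permutation-null quantile for the gain-distinct pair and stay within it
  for the gain-identical pair. The permutation null swaps each subject's two
  condition labels (identity pattern excluded; all 63 non-identity patterns
  are enumerated at n = 6).

## Known limitations

- The MM accuracies of the reduced battery are not comparable in magnitude
  to accuracies on real EEG; only the recovery *contrasts* are meaningful.
- Conditions are confounded with stimulus material: one story per condition,
  heard by every subject, so story-difficulty differences contribute a
  common across-subject offset to condition contrasts. Measured at this
  package's desk scale, that offset alone drives the subject-level Wilcoxon
  to ~25% false rejections when two different stories carry identical gains
  — the reason the type-I control uses an A/A design, and a caution that
  applies to the real paradigm as well (its scrambled condition, a word
  shuffle of the comprehensible story, is the closest the design gets to
  controlling it).
- The EDF exporter requires the optional `edfio` backend; the package's
  native interchange format is a lossless float container (.npy + JSON
  sidecar).
- The 8192 Hz acquisition-rate stage is implemented and tested, but
  synthetic cohorts are generated at 128 Hz directly.
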