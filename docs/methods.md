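# Methods

## Pipeline

A recording (channels × samples, fixed sampling rate, subject label) is
windowed into non-overlapping 10-second segments (default six per
record). Optionally each segment is denoised with a zero-phase IIR notch
at the mains frequency and a zero-phase Butterworth band-pass. Each
channel of each segment is then summarized by a fixed-length feature
vector, and per-segment vectors are averaged within a record so that one
record contributes one row of the feature matrix. Columns are grouped
into contiguous per-channel blocks; restricting the matrix to a channel
mask removes whole blocks. A wrapped classifier trained on the masked
training rows and scored on the validation rows defines the objective
that the optimizers maximize; the winning mask is retrained on the
training rows and scored once on the test rows.

## Features

**Autoregressive.** Channel signals are modelled as
x_t = ρ₁x_{t−1} + … + ρ_p x_{t−p} + ε_t and the coefficients are
estimated by solving the Yule–Walker autocovariance equations
(`statsmodels`' least-squares/"mle" variant, biased autocovariances).
Orders 5, 10 and 20 are supported (`AR5`/`AR10`/`AR20`). An AR(5) fit on
a single 10-second segment at 160 Hz recovers generator coefficients
with RMSE well below 0.1, and the error shrinks with signal length — the
test suite checks both.

**Wavelet.** `WT` features are statistics of a multi-level discrete
wavelet decomposition. The wavelet family, depth and statistics are not
dictated by the problem, so the defaults are a deliberate choice:
Daubechies-4, 4 levels, and per-sub-band {energy, mean absolute value,
standard deviation}, giving (4+1) × 3 = 15 features per channel. All
three are configurable.

**Scaling.** Features are z-scored inside the classifier pipeline using
training-set statistics only; the RBF-SVM objective is scale sensitive
and leakage through the scaler would optimistically bias validation
fitness.

## Objective

Identification decisions are tallied one-vs-rest over the K enrolled
subjects: each validation sample contributes one genuine trial (its own
identity) and K−1 impostor trials. Summing true accepts (TA), true
rejects (TR), false accepts (FA) and false rejects (FR) over classes
(micro-aggregation) gives the accuracy rate

    Acc = 100 · (TA + TR) / (TA + TR + FA + FR),

plus sensitivity TA/(TA+FR), specificity TR/(TR+FA) and
F-score 2TA/(2TA+FA+FR). For K = 2 these are the ordinary binary
confusion quantities. For K > 2 the micro-aggregated Acc is a strictly
increasing affine function of plain sample accuracy *a*:
Acc = 100·((K−2) + 2a)/K. Two consequences are worth stating explicitly:
(i) maximizing Acc ranks channel subsets identically to maximizing
sample accuracy, so the choice of aggregation never changes which mask
wins; (ii) the chance level is not 100/K but 100·((K−2) + 2/K)/K —
78.125 for K = 8 — and the label-shuffling test asserts chance at that
value via micro recall (= sample accuracy). No aggregation of per-class
counts can make the Eq. above equal sample accuracy for K > 2 while TA,
TR, FA, FR remain the plain one-vs-rest sums; we keep the counts
honest and document the affine map instead.

The split is 50% train / 30% validation / 20% test, stratified by
subject with largest-remainder allocation of the integer counts, so a
100-row table splits exactly 50/30/20. The optimizer only ever sees
validation fitness; test rows are touched once per run.

## Optimizers

All three optimizers share one RNG seeded from the config, a repair rule
(an all-zero mask gets one uniformly random bit set, since an empty
subset cannot be scored), and a memoizing fitness cache keyed on the
mask bit-string. The `evaluations` counter counts cache misses only,
which is the currency used for matched-budget comparisons
(`max_evals` caps it).

**Binarization.** bit_i = 1 iff σ(x_i) > U(0,1). The transfer function
direction matters: a large positive component must mean a high selection
probability, so the comparison is σ against the uniform draw, not the
reverse.

**Lévy steps.** Global pollination uses the Mantegna construction with
exponent λ = 1.5 and step scale 0.01 (both configurable). With a sigmoid
transfer the absolute scale is almost immaterial: real positions remain
in a soft-probability regime and plain FPA explores diffusely — at a
matched budget it performs on par with uniform random search on sharp
toy objectives. This is not a defect of the implementation but the
stagnation that motivates the hybrid; the test suite asserts parity with
random search for plain FPA and strict gains for the hybrid.

**Pollen replacement.** Plain FPA uses the standard greedy update: a
pollinated-and-binarized solution replaces its pollen only if its
fitness is not worse. The hybrid instead refines every binarized
solution with an inner β-hill-climbing loop (default 20 iterations of
N-operator followed by β-operator with β = 0.5, accepting ties — ties
enable neutral drift across accuracy plateaus) and the refined solution
replaces the pollen unconditionally; the refinement itself can only
improve fitness, and the global best is updated on strict improvement
only, which keeps the reported best mask stable under ties.

**Defaults.** Switch probability p = 0.8, population N = 64, T = 100
outer iterations, β = 0.5. The solution dimension D always equals the
channel count. Real positions are initialized U(−1, 1) and are not
box-clamped after pollination — the sigmoid tolerates any scale.
Standalone β-hc runs T outer iterations of N accept/reject steps from
one random mask, an evaluation budget equivalent to one FPA run.

## Synthetic cohorts

The generator emulates a multi-subject identification corpus at desk
scale: by default 8 subjects × 6 records of 10 s at 160 Hz over 16
channels, of which 3 (indices 2, 7, 11) are informative. Each
informative channel of each subject carries a stationary AR(5) process
whose coefficients are drawn once per (subject, channel) by sampling
reflection coefficients uniformly in (−0.95, 0.95) and mapping them
through the Levinson recursion — stationarity holds by construction. All
remaining channels share one cohort-level AR process. White observation
noise (σ = 10, against AR innovations of unit variance) is added to
every channel. Seeds fan out through per-(subject, channel, record)
substreams, so enlarging the cohort along one axis never perturbs
existing recordings.

The noise default deserves a note. Reflection-coefficient sampling makes
subject signatures so distinct that at low noise a single informative
channel already yields perfect validation accuracy and every mask
containing any informative channel ties — channel selection would be
trivial. At σ = 10 (roughly −10 dB SNR, a realistic scalp-EEG regime)
the landscape is graded: one informative channel gives ≈ 91% validation
accuracy, the full planted set ≈ 98%, all 16 channels ≈ 88% (noise
blocks dilute the SVM), and non-informative masks sit at the chance
level. This is the regime in which a selection method has something to
do, and it was fixed as the generator default before any end-to-end
evaluation.

What the generator does **not** emulate: volume conduction and channel
correlations, non-stationarity across records and sessions, artifacts
(blinks, EMG, line interference), and 1/f spectral shape. Passing the
planted-recovery tests therefore shows that the search machinery finds
discriminative channels under a known ground truth — not that any
particular accuracy carries over to real EEG corpora.

Because the generator plants no mains interference, the experiment
driver applies segmentation only by default; the notch/band-pass stage
is enabled by passing a `PreprocessConfig` and exists for real
recordings. Filter defaults (60 Hz notch, Q = 30; 0.5–50 Hz band-pass,
4th order, forward–backward) are implementation choices, as no single
convention is universal.

## Experiment protocol and problem sizes

An experiment is n independent runs (default 25); run r uses seed
base_seed + r for both the optimizer and the split, so splits resample
across runs (a fixed-split mode exists). Arms compared on the same
cohort share per-run seeds, and per-run test accuracies are compared
with a paired t-test and the Wilcoxon signed-rank test at α = 0.05
(identical vectors are reported as no difference rather than an error);
unpaired arms fall back to Welch's t-test.

The shipped tests and the acceptance script run at desk scale — e.g.
population 10 with 12–50 outer iterations, 10–25 runs, and 16-channel
cohorts, where one fitness evaluation is an SVM fit on ≤ 24 rows —
chosen so the full suite completes in minutes on one core while every
comparison retains enough runs for the rank tests. The default
OptimizerConfig (N = 64, T = 100) reflects the full-scale setting and is
what a user with a real 64-channel corpus would start from.

## Known limitations

- The wrapper objective is single-criterion; the accuracy/channel-count
  trade-off is not optimized jointly (no multi-objective mode).
- A single train/validation/test split per run can overfit the
  validation set; k-fold wrapping is left to the caller (the split and
  fitness machinery are composable).
- The Optimum-Path Forest classifier sometimes used in this literature
  is not bundled; `ClassifierConfig` covers SVM (RBF/linear), LDA, kNN,
  a one-hidden-layer MLP, Gaussian naive Bayes and a decision tree, and
  the pipeline accepts any scikit-learn-style estimator via the same
  interface.
- Micro-averaged sensitivity equals micro F-score on full eval sets by
  construction; macro-averaged variants are not implemented.
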