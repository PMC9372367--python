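# Methods

This note documents the models, reconstructions and numerical choices
behind `fetalcoupling`, in the spirit of a methods appendix: what is
computed, under which assumptions, and what the synthetic benchmarks do and
do not demonstrate.

## The problem

During gestation the fetal heart rhythm can transiently phase-lock to the
maternal rhythm in small-integer ratios m:n — m maternal beats co-occurring
with n fetal beats in a repeating pattern. With maternal rates around
80 bpm and fetal rates around 120–160 bpm, the observable ratios are
[1:2], [2:3] and [3:5]. The package quantifies this coupling from paired
R-peak event trains on 1-minute segments, three ways:

1. **Phase-occurrence counting** (`coupling_label`) — the rule-based
   ground-truth labeler;
2. **Phase coherence index λ_p** (`phase_coherence`) — the conventional
   circular-statistics strength measure;
3. **Deep coherence** (`deepmodel` + `deep_coherence`) — a 1-D CNN
   classifier over binary spike grids whose Grad-CAM attention yields a
   per-minute coupling-strength signal.

## Data model and conventions

A `BeatSeries` holds strictly increasing beat times (seconds); RR
intervals below 0.2 s violate the cardiac refractory period and are
rejected at load. Records are segmented into non-overlapping 60-s windows
starting at t = 0; a trailing partial window is discarded because all
downstream computations assume a fixed window length. A segment is
analyzable with ≥ 4 maternal beats (the 3-maternal-beat counting window
needs them) and ≥ 2 fetal beats. All windows are half-open
`[start, start + length)`; all indices 0-based.

The spike-grid encoding places a 1 at sample `round_half_up((t − window_start)·fs)`
(clamped into the grid) on a `(2, window_length·fs)` zero matrix — row 0
maternal, row 1 fetal; 60,000 samples at the native 1 kHz. Round-half-up
rather than banker's rounding keeps the encoding deterministic and
platform-independent. Colliding beats merge into a single 1.

## Phase-occurrence labeling

For each m ∈ {1, 2, 3}, windows `[R_i, R_{i+m})` slide by **one** maternal
beat (overlapping for m > 1) and the fetal beats in each window are
counted with exact equality against n. The prevalence of ratio (m, n) is
the percentage of m-beat windows containing exactly n fetal beats,
normalized **within window class m**. Prevalences of different ratios
therefore need not sum to 100 — three scenarios can simultaneously be
~60–70% prevalent in the same segment, which is exactly what makes the
labeling problem nontrivial. The label is the argmax over the three
supported ratios; ties break toward smaller m (deterministic, logged); a
segment where none of the three occurs is labeled `other` and filtered
out, with the retention fraction reported.

The per-class normalization is a deliberate reconstruction: a pooled
denominator across classes would cap the prevalences' sum at 100, which
contradicts the jointly-high values the method is designed to report.

## Phase coherence index

For a candidate m:n ratio, maternal beats are tiled into non-overlapping
m-beat cycles `[t_{jm}, t_{(j+1)m})` (cycle index k). A fetal beat at t in
cycle k has unbounded instantaneous phase

    φ = 2π (t − t_k) / (t_{k+m} − t_k) + 2πk,

and relative phase of occurrence Ψ = (φ mod 2π)/2π ∈ [0, 1). The
synchrogram (Ψ against time) shows n horizontal bands under m:n locking.

The windowed coherence index at each fetal-beat record is

    λ_p = ‖ (1/N_eff) Σ_j exp(i·2π·n·Ψ_j) ‖²,

over a symmetric window of up to N = 15 consecutive records (N suits 1-min
segments), truncated and renormalized by the actual member count N_eff at
segment edges. λ_p ∈ [0, 1]: exactly 1 under perfect locking, expectation
1/N for independent uniform phases. Two scaling choices are deliberate:

* the **2π angular factor** — Ψ itself spans only one radian, so averaging
  `exp(iΨ)` would be nearly degenerate (λ ≈ 1 always);
* the **harmonic factor n** — an m:n-locked segment has n equally spaced
  Ψ bands; without the factor n their unit vectors cancel symmetrically
  and perfect locking would score λ ≈ 0 instead of 1.

The bare formula (`exp(iΨ)`, fixed 1/N denominator) remains available via
`mode="printed"` for comparison. The per-minute summary is the arithmetic
mean of λ over the segment.

One scale subtlety: λ = 1 to machine precision requires the cycle tiling
to start at a true cycle boundary. A mid-record segment whose first
maternal beat falls mid-cycle re-tiles from a shifted origin; with
maternal RR variability this leaves λ ≈ 0.98 even at zero phase jitter.
This is a property of the measure, not an artifact.

## Synthetic generator

The generator is a phase-locking point process, not a biophysical
conduction model — it realizes exactly the m:n structure the labeler
counts and λ_p measures.

* Maternal RR ~ truncated normal, mean 0.75 s (≈ 80 bpm), sd 0.02 s,
  clipped to [0.4, 1.5] s.
* Coupled mode: maternal beats grouped into m-beat cycles; each cycle
  emits n fetal beats at fractions `offset_i + jitter` of the cycle span,
  jitter ~ N(0, `phase_jitter_sd`) per beat (units: cycle fraction).
  Beats violating monotonicity or the refractory floor are resampled up
  to 10 times, then dropped; > 5% drops abort generation.
* Default offsets are `(0.2 + k)/n`, k = 0..n−1 — equally spaced 1/n
  apart with the first at 0.2/n of a cycle. Equal spacing makes the
  fetal rhythm even (and the harmonic-n coherence exact); the 0.2/n
  lead-in keeps every offset clear of maternal-beat window boundaries,
  so small jitter does not flip beats between adjacent counting windows.
* Uncoupled controls draw fetal RR independently (mean 0.42 s ≈ 143 bpm,
  sd 0.03 s, clipped to [0.25, 0.8] s).
* Trains are generated past the requested duration and truncated, so the
  locked pattern covers the trailing counting windows exactly.
* The cohort generator draws gestational age uniformly in 20–40 weeks,
  assigns each subject a ratio from the mix (default skewed toward [1:2],
  the dominant scenario in real cohorts), and can plant a coupling-vs-age
  trend via `phase_jitter = base + slope·(ga − 30)` clipped at 0. Drawn
  record durations are floored to whole minutes (+2 s margin) so every
  window is fully covered. All randomness flows from one integer seed;
  identical seeds give bitwise-identical trains.

What the generator does **not** emulate: heart-rate variability structure
(no autocorrelation or respiratory modulation — RR draws are i.i.d.),
ectopy, detection errors or missed beats, episodic coupling that switches
ratio mid-record, and any waveform-level phenomena. Passing tests
therefore demonstrate correctness of the *methods* under clean m:n
locking with Gaussian phase jitter, not performance on clinical data.
Real-data jitter levels are unknown; the defaults are calibration choices.

## The CNN classifier

Architecture, on the `(2, L)` spike grid (L = 60,000 at 1 kHz):
conv(2→8 filters, kernel 1024, stride 1, same padding) → batch-norm →
ReLU → conv(8→12, kernel 512, stride 1, same padding) → batch-norm →
ReLU → flatten → fully-connected(3) → softmax, classes ordered
([1:2], [2:3], [3:5]). The printed kernel shape `[2, 1024]` is read as a
1-D convolution over time spanning both input channels; the second
block's `[2, 512]` likewise spans its 8 input channels (a literal
height-2 kernel is shape-inconsistent after block 1). Same padding keeps
the final activation aligned 1:1 with input samples, which the Grad-CAM
overlay requires; no pooling.

Training: class-weighted cross-entropy (inverse-frequency weights
w_c = T/(3·T_c), mean-1 normalized), ADAM with lr 0.001, L2 1e-4 on conv
and dense weights (as a λ·w gradient term, i.e. (λ/2)‖w‖² in the loss),
mini-batch 12, up to 15 epochs, per-epoch reshuffle from the run seed.
No early stopping or validation split. After training, batch-norm
inference statistics are re-estimated over the full training set (the
momentum-averaged running estimates are far from converged after ≤ 15
epochs on small sets); inference then uses fixed population statistics,
making prediction deterministic and batch-size invariant.

The layers are implemented directly on numpy/scipy with explicit
forward/backward passes; convolutions are evaluated in the frequency
domain (real FFTs of length ≥ L + k − 1, hence exact), which is far
cheaper than direct sliding products at these kernel lengths. Gradients
are verified against central finite differences in the test suite. Conv
biases are retained for fidelity to the stated architecture even though
the following batch-norm makes them null directions.

**Grid-rate scaling.** When the spike grid is resampled to fs′, kernel
lengths scale by fs′/1000 rounded to the nearest even integer, so
receptive fields keep their physical duration (1.024 s and 0.512 s). The
benchmark rate is 250 Hz (L = 15,000, kernels 256/128).

**Cross-validation.** `loo_cv` supports one-fold-per-segment (matching an
iteration count equal to the number of training samples) and
one-fold-per-subject grouping; folds whose training split loses a class
are skipped and logged. A scale caveat: with only a handful of distinct
records per class the model memorizes record-specific beat placements and
held-out-record LOO accuracy is poor; reliable generalization appears
with many distinct records (the 300-segment benchmark reaches ≥ 90%
held-out accuracy). Desk-scale LOO runs therefore exercise the fold
mechanics, not headline accuracy.

## Grad-CAM and deep coherence

Grad-CAM weights each channel of the final convolutional activation A by
α_c, the spatial mean of ∂(target-class pre-softmax score)/∂A_c, and maps
attention as `relu(Σ_c α_c A_c)`, normalized by its maximum (zero maps,
never NaN, when the maximum is 0). Because the head is linear in A, the
gradient is exactly the corresponding head-weight row — the tests confirm
the implementation against finite differences. Attribution targets the
predicted class by default.

The per-minute "deep coherence" scalar of a record is the mean of each
segment's attention map after rescaling all maps by the record-wide
maximum raw (pre-normalization) value, so minutes within a record are
mutually comparable and lie in [0, 1]. This mapping from attention to a
scalar is one defensible choice among several; its agreement with λ_p
(RMSE, Bland–Altman) is an empirical question per dataset.

## Evaluation statistics

Confusion matrices (rows = truth) with per-class sensitivity TP/truth and
precision TP/predicted (0 + flag when a class is never predicted),
accuracy = trace/total; one-vs-rest AUROC by the rank statistic with a
stratified bootstrap percentile 95% CI (B = 1000, seeded — the CI method
is a package choice); Bland–Altman agreement (mean difference, SD, limits
mean ± 1.96·SD, difference-vs-average OLS line); and coupling-vs-
gestational-age trends by OLS with Pearson R, the two-sided slope t-test
(n − 2 df) and a 95% mean-prediction band. Trend analysis treats segments
as independent observations (pooled across subjects); a subject-clustered
variant is out of scope.

## Problem sizes used by the bundled benchmarks

The test suite and `scripts/acceptance.py` run entirely on generated
data: the coherence checks use 10⁴ independent 15-phase windows; the
labeler oracle check uses 200 random segments; the classifier benchmark
uses 300 one-minute segments (100 per ratio, jitter 0.02) at 250 Hz with
a stratified 80/20 split; the trend-recovery check uses a 50-subject
cohort. Unit tests use further-reduced grids (50 Hz and below) where only
mechanics, not accuracy, are asserted.

## Known limitations

* The generator's i.i.d.-RR model understates real heart-rate structure;
  all accuracy figures are synthetic-benchmark figures.
* λ_p's harmonic-n correction assumes the n fetal beats are equally
  spaced in the cycle; strongly uneven planted offsets lower λ even at
  perfect lock.
* The deep-coherence scalar depends on the record-max normalization
  choice; comparisons across records use a per-record scale.
* Only beat times are modeled; everything upstream of R-peak detection
  (waveform filtering, source separation, peak picking) is out of scope.
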