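# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind the pipeline. Nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Encoding model

The delta-band signal of channel *c* is modeled as a sum of lagged,
linear responses to stimulus features,

    y_c(t) = Σ_f Σ_k x_f(t − τ_k) β_f(τ_k, c) + η(t),

with lags τ_k on a uniform grid from −200 ms to +1000 ms at the signal's
sampling rate (241 lags at 200 Hz). The window is chosen so that response
kernels extending to ~600 ms remain fully inside it even after a
latency shift of 150–200 ms, with a short pre-onset segment as a
sanity region. Stacking lagged copies of all features column-wise
(feature-major blocks) gives the design matrix `X ∈ R^{N×KF}`; the TRF
coefficients are the ridge solution `β̂ = (XᵀX + λI)⁻¹XᵀY`, computed by a
Cholesky solve of the regularized normal equations. A single scalar λ is
shared across channels and features. Columns are not re-standardized
inside the solver: regressor values are scaled by their pooled standard
deviation when the tracks are built, and all impulse-type regressors are
smoothed with the same unit-sum Gaussian kernel (σ = 15 ms, truncated at
±4σ), which gives them spectral content comparable to the continuous
envelope regressor (reciprocal-convention spectral SD 1/(πσ) ≈ 21.22 Hz)
so a shared λ is meaningful.

### Cross-validation

Model selection and scoring use nested cross-validation over contiguous
segments: 9 outer folds (mirroring a recording cut into 9 story
segments), and inner folds (default 4) formed by contiguously grouping
the outer-training segments. λ is chosen per subject on the inner folds
by mean validation correlation across channels; outer folds score a model
fit at that λ on the outer-training data only; the final TRF is refit on
all data at the per-subject modal λ (ties toward the smaller λ, i.e.
toward less smoothing). Lagging is performed *within* fold blocks with
zero padding, so no sample leaks between training and validation through
the lag structure; the cost is discarding lag context in the first K
samples of each block (~4 % at the default sizes).

Because every subject hears the same stimulus, the design matrix — and
each fold's Gram matrix XᵀX — is shared across subjects. Per-segment
Grams are accumulated once and reused for every fold, λ and subject,
which is what keeps the multi-subject grid fits cheap (one Cholesky per
fold × λ serves all subjects simultaneously).

At the recovery scale used in the tests and the acceptance script
(8 subjects × 16 channels × 9 × 30 s at 200 Hz) the λ grid is
{0.1, 10, 1000}; a wider 9-point grid (`DEFAULT_LAMBDA_GRID`,
10⁻²…10⁶) is available and used identically, the 3-point grid being this
package's scaling choice for routine runs — on the simulated data the
inner CV consistently selects the interior of the grid.

## Stimulus features

* **Node counts.** From bracketed parses: top-down assigns every
  non-terminal node (pre-terminals included) to its *leftmost* terminal
  descendant, bottom-up to its *rightmost*, left-corner builds a
  pre-terminal at its own terminal and any other node once its first
  child's subtree is complete. Each strategy assigns every node to
  exactly one terminal, so per-sentence counts always sum to the tree's
  node total — the central structural invariant, asserted on random
  trees. Unary chains are counted node by node; category labels are
  irrelevant to the counts. Trace terminals (token prefix `*`,
  configurable) have no acoustic correlate: their counts are added to the
  next overt word, or to the preceding one when the trace is
  sentence-final (the backward rule is this package's choice; it
  preserves the per-sentence sum exactly).
* **Trigram surprisal and entropy.** Single-discount interpolated
  Kneser–Ney of order 3, one discount per order,
  D = n₁/(n₁ + 2n₂) from that order's count-of-counts, clamped to
  [0, 0.999]; lower orders use continuation (distinct-history) counts;
  the unigram level interpolates with a uniform distribution over the
  vocabulary plus an explicit unknown symbol, so unseen words get finite
  surprisal. Sentences are padded with two start symbols and one end
  symbol; probabilities are never computed across sentence boundaries.
  Entropy sums over the full prediction vocabulary (end-of-sentence and
  unknown included). Logarithms are base 2 throughout (bits). Modified
  KN (three discounts per order) was deliberately not used: the simpler
  estimator has fewer unstated parameters and is checked exactly against
  a brute-force oracle.
* **Word frequency** enters as log₁₀ occurrences per million with a
  floor of 0.301 for out-of-lexicon words (in the simulator, drawn
  Zipf-like per word type).
* **Impulse trains.** Word-level values are placed at
  `round(onset·fs)` (rounding minimizes quantization bias); coinciding
  samples accumulate. Values are divided by their pooled SD across all
  stimuli *without* centering — centering would move event mass into the
  baseline. Split features (low/high surprisal) partition the scaled
  values of the intact feature, so the two split tracks sum exactly to
  the intact track.
* **VIF screening.** Variance inflation factors are the diagonal of the
  inverted correlation matrix of the z-scored per-word values, verified
  against the regression definition 1/(1−R²).

## Inference

* **Cluster-based permutation test.** Paired t maps over (channel, time)
  with sensor adjacency (plus temporal adjacency); clusters form
  separately from t > +1.714 and t < −1.714 — the one-sided p = .05
  critical value at df = 23, kept as the package default — with cluster
  mass the signed sum of t inside the cluster. The null permutes
  condition labels by sign-flipping subject difference maps (the correct
  exchangeability scheme for paired designs); p-values are add-one
  Monte-Carlo, `(1 + #{max |mass| ≥ |observed|})/(1 + n_perm)`, so p = 0
  is impossible at finite permutations. Accuracy topographies
  (channels × 1) reuse the same machinery with the same threshold.
* **Histogram-overlap duration matching.** Word durations are binned
  (100 bins over 0–1.25 s); each bin keeps
  min(count_low, count_high) words per condition, drawn uniformly at
  random within the bin, making the matched histograms identical
  bin-for-bin. Out-of-range words are dropped with a warning.
* **Cross-correlation latency.** Per sensor, the full cross-correlation
  of the two grand-average TRF waveforms is normalized by its maximum
  and the lag of the maximal positive peak recorded; the *modal* peak
  lag across sensors (sample grid, no interpolation, ties toward the
  smaller absolute lag) is the latency estimate. The low waveform is
  shifted by the modal lag and correlated with the high waveform per
  sensor (Pearson over the overlap). Significance: the mean shifted
  correlation is compared with n_null re-computations for random sensor
  subsets of the same size and random lags drawn uniformly over the
  lags where the correlation is defined (overlap ≥ 3 samples).

## The synthetic twin

The simulator emulates the study conditions of a naturalistic-listening
MEG experiment with 24 subjects, 9 story segments, 791 sentences of
mean length ≈ 10 words, and a positive duration–surprisal association:

* **Stimuli.** A fixed toy PCFG (≈20 productions; NP/VP/PP recursion,
  optional relative clauses whose subject position holds a trace) with a
  Zipf-ish lexicon. The trigram model is trained on an independent
  sample from the same grammar (1,500 sentences by default), standing in
  for an external training corpus.
* **Events.** Word durations follow
  `log d = log 0.16 + 0.10·surprisal + N(0, 0.25)`, clipped to
  [0.05, 1.2] s — the coupling 0.10 log-s/bit yields a Spearman
  correlation between duration and surprisal of ≈ 0.5, in the range
  reported for natural speech. Sentences are laid into segments with
  short word gaps and longer sentence pauses.
* **Kernels.** Per feature and channel, sums of 2–3 Gabor atoms
  (centers within 0–600 ms, widths 40–90 ms, carriers 1–3 Hz — inside
  the analysis band so band-pass filtering distorts them minimally) with
  random channel topographies, tapered to vanish outside 0–600 ms. The
  high-surprisal node-count kernel is the low-surprisal kernel delayed
  by the planted shift, *sample-exactly* (kernel shift, not onset shift:
  the hypothesis is a delayed structure-building response). The
  word-frequency kernel is shared by both surprisal conditions, which is
  what the word-recognition control should detect as a null shift.
* **Signal.** Per subject, the clean signal is the sum of feature tracks
  convolved with their kernels; every feature's contribution is
  equalized in overall RMS (otherwise the continuous envelope dominates
  the variance and sparse impulse features would be unmeasurable at any
  stated SNR — the simulator assumes each modeled response is
  detectable), with a small per-subject gain jitter (SD 5 %). Noise is
  1/f-shaped Gaussian; both are band-passed 0.5–4 Hz with a zero-phase
  symmetric FIR (Hamming, transition width lo/2, DC gain nulled
  exactly), and the noise is scaled so the clean/noise power ratio
  within the band equals the configured SNR.

### What the simulation does and does not show

Passing recovery tests shows the pipeline correctly estimates TRFs,
detects waveform differences, and measures latency shifts under
realistic collinearity (shared word onsets across regressors,
surprisal-correlated durations, 1/f noise). It does not show that real
cortical responses are linear, that sensor noise is 1/f, that real
parses match any single strategy, or anything about effect sizes in real
MEG — the simulator's kernels and SNR are stipulations, not measurements.

## Degenerate inputs and numerical choices

Zero-SD value vectors, all-trace sentences, empty duration-histogram
overlap, singular correlation matrices (VIF), rank-deficient designs at
λ = 0, folds shorter than the lag count, and adjacency/channel
mismatches all raise immediately with a named cause. Constant channels
score as NaN with a warning rather than an arbitrary correlation.
Band-pass filtering requires the signal to be at least three filter
lengths long; simulation therefore generates one continuous recording
per subject (segments are fold boundaries, not separate arrays).

## Known limitations

* The cluster test assumes subjects are exchangeable under the null;
  group structure would need a different permutation scheme.
* The modal lag lives on the sample grid; sub-sample shifts are not
  estimated (no peak interpolation, by design — matching the discrete
  reporting convention).
* The left-corner strategy defines "building" a node at the completion
  of its first child; arc-eager variants would differ on right-branching
  structures.
* Long-context (transformer-derived) surprisal is ingested as a
  precomputed column when present; this package never computes it.
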