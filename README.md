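# syntrf

Delta-band encoding-model analysis of **syntactic structure building under
lexical surprisal**, with a forward simulator providing ground truth for
every stage.

## The scientific problem

During naturalistic listening, the low-frequency (delta, 0.5–4 Hz) M/EEG
signal tracks both the *distributional* properties of words (how
predictable a word is in context) and the *structural* operations of
incremental parsing (how many syntactic nodes a parser closes or predicts
at each word). The question this pipeline addresses is whether these two
factors interact: **is the neural readout of structure building delayed
when a word is unpredictable?**

The analysis machinery, aimed at researchers working with continuous
speech encoding models:

- **Incremental node counts** from bracketed parses under top-down,
  bottom-up and left-corner strategies (trace counts folded onto overt
  words);
- an **interpolated Kneser–Ney trigram model** giving per-word surprisal
  `I(w) = −log₂ P(w | w₋₂ w₋₁)` and lexical entropy
  `H = −Σₖ P(k|h) log₂ P(k|h)` in bits;
- **temporal response functions (TRFs)**: the encoding model
  `y_c(t) = Σ_f Σ_k x_f(t−τ_k) β_f(τ_k, c) + η(t)` estimated by
  closed-form ridge regression `β̂ = (XᵀX + λI)⁻¹XᵀY` with nested
  cross-validation over contiguous segments, scored as per-channel
  Pearson correlation between held-out data and reconstruction;
- **split-based interaction analyses**: the node-count regressor split at
  the median of surprisal (random split as control, histogram-overlap
  subsampling to match word-duration distributions);
- **spatio-temporal cluster-based permutation tests** (paired t maps,
  threshold 1.714 = one-sided p .05 at df 23, signed summed-t cluster
  masses, sign-flip null);
- **cross-correlation latency estimation** between split TRF waveforms
  with a Monte-Carlo null over random sensor subsets and lags;
- a **forward simulator**: toy-grammar stimuli, surprisal-coupled word
  durations, Gabor-atom response kernels with a planted +150 ms shift of
  the high-surprisal node-count kernel, 1/f noise, band-passed signals.

Real MEG recordings are not part of this package; all analyses run on
simulated data whose generative truth is known, so recovery of the
planted effect validates the machinery end to end.

## Worked example

```python
from syntrf import simulate as sim, pipeline as pl

cfg = sim.SimConfig(n_subjects=8, n_channels=16, segment_duration=30.0,
                    n_segments=9, snr=1.0, planted_shift=0.150, seed=1)
res = pl.recover_latency_shift(cfg, lambda_grid=pl.FAST_LAMBDA_GRID,
                               n_perm=500, n_null=1000)
lat = res["interaction"]["latency"]
print(f"node-count split modal lag: {res['modal_lag_bottomup']*1000:.0f} ms")
print(f"frequency  split modal lag: {res['modal_lag_frequency']*1000:.0f} ms")
print(f"shifted-waveform correlation: {lat.mean_corr:.2f} (p={lat.p_value:.3f})")
```

prints

```
node-count split modal lag: 150 ms
frequency  split modal lag: 0 ms
shifted-waveform correlation: 0.98 (p=0.005)
```

i.e. the TRF of the bottom-up node-count feature for high-surprisal words
lags the low-surprisal one by exactly the planted 150 ms, while the
word-frequency feature — a lexical marker fitted with the same split
machinery — shows no shift: the delay is syntactic, not lexical, in
origin.

The numbered drivers under `analysis/` run the full sequence
(`01_simulate` → `02_main_effects` → `03_interaction` →
`04_duration_control` → `05_frequency_control`) and write their tables
under `results/`.

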