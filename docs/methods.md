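# Methods

This note documents the models and procedures implemented in `auscult`, the
assumptions behind them, the parameters that matter, and what the synthetic
data do and do not demonstrate.

## 1. Frame-level detector

**Task.**  Multi-label sound-event detection: each audio frame may carry any
subset of the seven classes {wheeze, rhonchi, fine crackle, coarse crackle,
inspiration, expiration, noise}.  Classes genuinely co-occur (a wheeze rides
on an expiration), so the head is seven independent sigmoids, not a softmax.

**Architecture.**  Waveform → spectrogram front-end → conv stack → BiGRU
stack → linear head.

* *Front-end*: a strided convolution whose kernels are a Hann-windowed DFT
  basis (cosine and sine banks); magnitude + `log(·+ 1e-3)` compression.
  Window 64 ms, hop 32 ms.  Frame `i` covers samples `[i·hop, i·hop + win)`
  with zero padding so the frame count is `ceil(n_samples / hop)`.  The basis
  is fixed by default (`frontend_trainable=False`), in which case it
  contributes no trainable parameters.
* *Conv stack*: 3×3 convolutions (same padding), stride 2 on the frequency
  axis and 1 on time, each followed by batch normalization and ReLU.
* *BiGRU stack*: bidirectional GRU layers over time on the flattened
  (channel × frequency) features.
* *Head*: per-frame linear map to 7 logits.

**Presets.**

| preset | rate | conv channels | BiGRU | trainable params |
|---|---|---|---|---|
| `full` | 8 kHz | 32, 64, 64, 128, 128, 256, 256, 512 | 3 × hidden 288 | 7,612,999 |
| `small` | 4 kHz | 8, 8 | 1 × hidden 16 | 27,999 |

The `full` preset reproduces the clinical-scale layer inventory (eight conv
blocks, three BiGRU layers, ≈7.4 M parameters); its exact widths are a design
choice pinned by a test on the parameter count.  The `small` preset is the
desk-scale variant used for CPU training experiments.

**Training.**  Per-frame, per-class binary cross-entropy on logits, Adam
(lr 3e-3, betas 0.9/0.999), batch size 16, 25 epochs by default, all
randomness from one integer seed.  Targets are rasterized from interval
annotations at the internal 32 ms hop: frame `f`, class `c` is 1 iff an
annotation of class `c` overlaps `[f·hop, (f+1)·hop)` by any amount.  Only
recordings of identical length are batched together (no padding/masking).
The network is written directly on numpy with explicit forward/backward
passes (im2col convolution, batch-norm, backpropagation through time for the
GRUs); everything is float64 and bit-deterministic given the seed.

**Inference.**  Audio is resampled (polyphase) to the preset's rate.  The
internal 32 ms raster is reduced to the uniform 0.1 s output hop by taking
the max over the internal frames starting inside each output frame — max, not
mean, so 5 ms crackles survive the hop change.  Output frame count is
`ceil(duration / 0.1 s)`.

## 2. From raster to the seven indexes

**Operating points.**  A trained detector's probability *ranking* is stable
across training runs but its absolute scale is not, so fixed activity
thresholds are unreliable.  After training, `select_class_thresholds` picks a
balanced (sensitivity ≈ specificity) ROC operating point per class on the
annotated training data; classes with a single outcome keep the 0.5 default.
The thresholds travel with the model checkpoint and feed both the quality
stage and the intensity computation.

**Raw intensity.**  A frame is *active* for a class when its probability
reaches the class threshold (the calibrated operating point, 0.5 when none is
available).
Noise-active frames are discarded; *breathing* frames are those active for
inspiration or expiration.  The raw intensity of phenomenon *p* is the
fraction of usable breathing frames that *p* covers.  This is the simplest
construction that uses exactly the three ingredients available — detected
phenomena, detected breathing cycle, detected noise.  If no usable breathing
frame remains the scores are defined as 0 and the recording is flagged as
undefined quality.

**Calibration.**  The 3-point ordinal severity labels anchor the intensity
scale at 0 → 0.0, 1 → 0.5, 2 → 1.0; isotonic regression of the anchors on the
raw scores yields a non-decreasing map [0,1] → [0,1], so calibration can
never reorder recordings.  With fewer than two distinct levels the map
degenerates to the identity (with a warning).  In the end-to-end pipeline the
same construction is applied once more at the examination level.

**OWA aggregation.**  Per-recording values are sorted descending and combined
with geometric rank weights `w_i ∝ decay^i`, normalized to sum 1.
`decay = 1` is the arithmetic mean; `decay → 0` approaches the maximum.  The
default `decay = 0.5` encodes the clinical intuition that one loud recording
among twelve matters more than the average chest location.  Joint indexes
combine constituents per recording by max (a chest location is "continuous
phenomena positive" if either wheezes or rhonchi are present) before the OWA.
Bad-quality recordings are excluded before aggregation; an examination with
no good recording is uncomputable, and examinations with fewer than four good
recordings are filtered out entirely (configurable).

**Quality proxy.**  The clinical quality judgment (human acoustician) is
proxied by the detector's own channels: reject when breathing-active frame
fraction < 0.1 (`no_breath`) or noise-active fraction > 0.5 (`too_noisy`).
These thresholds are proxies, not measured constants.

## 3. Evaluation

AUC is computed as the normalized Mann–Whitney U via midranks: concordant
pairs count 1, ties 0.5 — exactly brute-force pair enumeration, which the
tests assert on random instances.  The positive class is the first-listed
group of each comparison, so AUC < 0.5 means reversed correlation.  The four
reported comparisons are AA vs AN, AN vs NN, AA vs NA, NA vs NN; cross
comparisons (AA vs NN, AN vs NA) are not computed because a difference there
cannot be attributed to either factor.  Balanced operating points are chosen
among midpoints of adjacent sorted unique scores by minimizing
|sensitivity − specificity|, ties broken by higher Youden's J, then by the
lower threshold; with a single unique score that score is the only candidate.
Group statistics are population moments (ddof = 0).  No confidence intervals
or multiple-testing corrections are produced.

## 4. Synthetic data

### Audio level

The generator emulates what the detector needs to learn, not airway physics:

* **Breath cycle**: band-passed white noise (80–900 Hz) shaped by
  raised-cosine envelopes; inspiration occupies 40 % of the cycle, expiration
  40 % (expiration at 0.7 amplitude), with short pauses between.  Default
  period 4 s (resting adult), default recording length 14.6 s (the mean
  clinical recording length), default rate 8 kHz.
* **Wheeze**: tonal segment, 0.1–1.2 s, centre 100–1000 Hz, slow (±4 %)
  random frequency modulation; placed preferentially in expiration.
* **Rhonchi**: like a wheeze but with fundamental ≤ 200 Hz and a 1 : 0.5 : 0.25
  harmonic stack (snoring quality).
* **Crackles**: exponentially damped sinusoids — fine ≈ 5 ms at ≈ 650 Hz,
  coarse ≈ 15 ms at ≈ 350 Hz (standard respiratory-acoustics conventions);
  placed preferentially in inspiration.
* **Level**: events are scaled to a target SNR (default 10 dB) against the
  local breath-noise RMS.

Every inserted event yields exactly one annotation with exact timestamps;
inspiration/expiration annotations tile the cycles.  Identical config + seed
gives bit-identical output.

Not emulated: chest-wall transmission, heart sounds, device coloration,
annotator disagreement, and free-field background noise events (the `noise`
class is never annotated in synthetic data).  Detector scores on this corpus
therefore bound the *machinery* (architecture, training loop, index chain),
not clinical performance.

### Index level

Per-examination index tables are drawn per group (AA/AN/NA/NN) from
[0,1]-truncated normals.  Because clipping shifts moments, the underlying
(μ, σ) are solved numerically so that the *truncated* mean matches the target
exactly and the truncated SD matches in the least-squares sense (the family
cannot reach every printed SD: a mean of 0.30 caps the attainable SD near
0.25).  The default archetypes carry the group moments of a published
four-group validation cohort.

**Printing-resolution pooling.**  The archetype table is printed to two
decimals.  Two groups whose printed mean *and* SD agree within one printing
unit (0.01) are statistically indistinguishable at that precision, so their
cells are pooled (averaged) and share one distribution
(`effective_index_targets`, `print_resolution=0.01`, set 0 to disable).
Without pooling, a one-unit rounding difference between two near-zero cells
(0.01 vs 0.00) would fabricate an order-of-magnitude mean ratio and hence
strong spurious separation between groups that the source cohort found
inseparable.  Pooling affects the AN/NN pair on every index and the AA/NA
rhonchi cell; resolved cells (differences above one printing unit) are never
pooled.

Remaining artifact: a group whose printed SD is 0.00 becomes a point mass,
so any continuously distributed group separates from it perfectly (e.g. the
coarse-crackles AA-vs-AN cell simulates to AUC 1.0 where the cohort reported
0.565).  Moment pairs with mean 0.00 and positive SD are infeasible on [0,1];
the mean is clamped to 1e-3.

## 5. Desk-scale study conditions

The test suite and the acceptance script use: 200 training and 50 held-out
synthetic recordings of 4 s at 4 kHz and 10 dB SNR for detector training
(small preset, 25 epochs, seed-pinned); 10 examinations per group × 4
recordings for the end-to-end study; 500 examinations per group for the
index-level simulation.  These sizes keep a full run in the minutes range on
a single CPU while leaving the measured quantities (frame AUC, group AUCs)
well away from their decision boundaries.

## 6. Known limitations

* The detector trained here sees only synthetic audio; no claim is made about
  clinical recordings, and the certified clinical model's weights are not
  reproduced.
* The raster→intensity formula, OWA weight family and calibration family are
  reconstructions of qualitatively described steps; each is the simplest
  member of its class and is configurable.
* Class thresholds default to 0.5; under-confident detectors (e.g. very few
  training epochs) can push all crackle probabilities below threshold, giving
  zero transient intensities.
* The index-level simulator draws indexes independently within an
  examination, ignoring the correlation between indexes that share
  constituents (overall vs wheezes, etc.); pairwise single-index AUCs are
  unaffected, but joint analyses across indexes would be.
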