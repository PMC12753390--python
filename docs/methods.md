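# Methods

This note documents the models, default parameters, numerical choices, and
known limitations of `eeg2bold`, in the spirit of a package methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing

**BOLD.** Region series are obtained by unweighted voxel averaging on an
integer maximum-probability label map (background = 0; an atlas region with
no voxels yields a NaN sentinel column plus a warning rather than an error,
so partial-coverage volumes still run). Each region series is then, in this
fixed order: (1) linearly detrended by least squares — scanner drift grows
roughly linearly over a session, and detrending first keeps the trend from
inflating the variance estimate; (2) z-scored with the population SD
(ddof = 0, configurable) — deterministic and scale-exact for short series;
(3) outlier-corrected at |z| > 3. The region count defaults to 49 (a
maximum-probability cortical parcellation) but is configuration, not code:
distributions of cortical atlases vary in region count.

**EEG.** The recording is cut into TR-long segments aligned to scan onsets
(segment *t* covers [t·TR, (t+1)·TR); trailing samples are dropped; a too
short recording is an error naming the shortfall). Per segment and channel,
Welch PSD with 1-s Hamming windows at 50% overlap — parameters chosen to
fit a 2-s segment at the common 1 Hz resolution; configurable. Band power
is the trapezoid-rule integral of the density over the band; with
contiguous bands each shared edge frequency (4, 8, 12, 16 Hz) contributes
half its density to each neighbor, so total power is conserved and nothing
is double-counted. Powers are absolute (µV²); z-scoring downstream removes
scale anyway. Normalization is per channel-band pair (the alternative —
pooling a channel's bands — is achievable by reshaping before the call);
outlier threshold |z| > 4.

**Outlier replacement.** Flags are computed once on the input values;
replacement then sweeps left to right, so consecutive outliers collapse
onto the last clean value. A flagged first time point has no predecessor
and is left unchanged (still flagged in the report). There is no
re-detection and no re-normalization after replacement. This previous-value
rule is deliberately conservative: it corrects rare spikes without
introducing interpolated temporal structure.

## Features and targets

The feature vector at scan *t* concatenates the normalized band powers at
scans *t−5 … t* in (time step, channel, band) order — the order is fixed so
persisted models stay portable. Five lags at TR = 2 s give a 10 s window,
covering the HRF peak. The first five scans yield no sample (no padding).
The classification target at scan *t* is the sign of *y(t) − y(t−1)*; ties
(Δ = 0) are labeled *increase*. Ties are measure-zero on continuous data
but do occur after previous-value outlier replacement (≈0.3–0.6% of
scans); the convention slightly favors the constant-increase baseline and
is visible as a percentage-point-scale conservatism of the null rejection
rate (see "Statistical layer"). The regression target is *y(t)* itself.
For the raw-signal path, the sample at scan *t* stacks the raw segments
*t−5 … t* along time with channels as the leading axis.

## Synthetic studies

The generator emulates a simultaneous EEG-fMRI neurofeedback study:
9 subjects × 3 conditions, 49 regions, 64 channels at 200 Hz, TR 2 s,
200 scans of alternating 20-scan rest/task blocks. Defaults:

- **Latent band powers**: per channel-band AR(1) with coefficient 0.5 and
  unit stationary variance (plausible scan-to-scan autocorrelation); the
  first 25% of channel-band pairs gain +1.0 during task blocks.
- **Coupling**: each region couples to 3 random channel-band pairs with
  weights ±`coupling_gain` (default 1.0); the zero tensor is the exact null.
- **HRF**: double-gamma (peak delay 6 s, undershoot delay 16 s, unit
  dispersions, undershoot ratio 1/6, 32 s support), unit peak, zero at
  t = 0. BOLD = causal convolution of the coupled latent sum (truncated at
  the session start — no pre-session history) + linear drift with
  per-region slope ~ N(0, 0.002 z/s) + white noise (SD 1.0).
- **Outliers**: both modalities receive ±6 SD spikes at rate 5·10⁻⁴,
  exercising the replacement rule at realistic (sub-percent) rates.
- **Raw EEG** (optional): per scan, one sinusoid per band at the band
  center frequency whose squared amplitude matches twice the rectified,
  offset latent power, plus broadband noise — so Welch band powers recover
  the latents (a Parseval-style identity checked in the tests).
- **Seeds**: one master seed; every (subject, condition, stage) draws from
  its own `SeedSequence` substream, so adding subjects or conditions never
  changes existing data.

What the generator does **not** emulate: gradient/ballistocardiogram EEG
artifacts, head motion, volumetric smoothing, spatial correlation between
regions, non-linear neurovascular coupling. Passing tests therefore show
that the pipeline recovers planted linear-convolutional structure and is
calibrated under its null — not that real EEG predicts real BOLD.

## Model suites

Classical families wrap scikit-learn (logistic/linear, KNN, decision tree,
random forest, RBF-kernel SVM) and XGBoost, behind one fit/predict
contract with seeds recorded. `tune()` is an exhaustive grid search on
validation accuracy/MAE whose exact ties resolve to the simplest model
(fewest neighbors, shallowest tree) by evaluating grid points in
complexity order and requiring strict improvement.

Neural families run on an in-repo numpy reverse-mode autodiff stack
(gradients verified against finite differences in the test suite): MLP with
hidden layers (64, 32); a 1-D CNN over raw EEG windows (three strided
convolution blocks 16/32/32, kernels 7/5/3, global average pooling) with
EEG channels as input channels; a single-layer GRU (width 64) over the six
lag steps; and a transformer encoder (2 blocks, 4 heads, width 32, learned
positional embeddings) over the same steps. All use ReLU hidden
activations, Adam (lr 10⁻³, batch 32), binary cross-entropy or MSE, at most
200 epochs with early stopping (patience 10) on the validation condition,
restoring the best-validation weights and recording loss curves. These
architectures and budgets are this package's choices; they are deliberately
small so that a full condition rotation stays a desk-scale computation.

## Cross-validation

`make_cv_plan` fixes the rotation direction: iteration *i* trains on
condition *i* and tests on condition *i+1* (cyclically); the rotation
property (each condition trains once and tests once) is what matters, the
direction is a convention. Classical families leave the third condition
out; neural families use it for validation. With 9 subjects and 49 regions
this yields 441 subject-region pairs per iteration, 1323 overall; pair
counts are conserved against explicitly logged exclusions (e.g. a
degenerate single-class training set).

## Statistical layer

**One-sided Wilcoxon signed-rank** (metric vs baseline per pair;
"greater" for accuracy, "less" for MAE). Zero differences are discarded
(classic signed-rank). For ≤ 25 informative pairs the null distribution of
the rank sum is enumerated exactly by subset-sum dynamic programming over
doubled (hence integer, tie-safe) ranks; above, a normal approximation with
tie-corrected variance and a 0.5 continuity correction. Effect sizes:
matched-pairs rank-biserial correlation (W⁺−W⁻)/(W⁺+W⁻) and
common-language effect size over all pairs with ties counting ½. Fewer
than 5 informative pairs, or none, is an error, not a number.

The null-calibration experiments (zero-coupling replicate studies through
the full pipeline) show a rejection rate near but slightly below the
nominal 5%: the tie→increase labeling convention hands the
constant-increase baseline the ≈0.3–0.6% of tied scans created by outlier
replacement, a small systematic advantage worth roughly one to two
percentage points of rejection rate at the replicate sizes used here. The
implementation itself is exactly calibrated on independent symmetric
inputs (checked against enumeration).

**Iterated McNemar vs a resampled baseline** (foundation models, which see
far fewer scans): each iteration draws one baseline label per scan from the
empirical truth distribution (invalids excluded beforehand), pools the 2×2
correctness table over subjects and regions, and computes a two-sided
McNemar p — the exact doubled binomial tail when discordant pairs ≤ 25,
otherwise continuity-corrected chi-square. Default 10,000 iterations
(1,000 for the analogous Wilcoxon path), summarized by the median p, the
proportion of iterations with p < 0.05, and a 20-bin histogram on [0, 1].

**Per-ROI tests** are reported with raw p-values (matching the study
design); a Benjamini-Hochberg q-value column is additionally emitted and
labeled as an extra of this package. The pairwise model-vs-model table is
one-sided in the direction "row model beats column model".

## Prompting harness

Prompt templates (single-channel, two-step chain-of-thought, multimodal,
five-channel hierarchical) are fixed strings with typed slots; numeric
values render with 2 decimals; band labels use the "Beta (16–30 Hz)" form;
the five-channel mode nests band dictionaries under electrode labels. The
default region→channel map covers a documented subset of cortical regions
by electrode proximity (Frontal Pole → Fpz, Cuneal Cortex → POz, …) and is
replaceable wholesale via TSV. The parser matches the stems
*increas-*/*decreas-* case-insensitively — covering all inflected forms —
and returns *invalid* when zero or both stems occur; it is total (never
raises), and backend failures are recorded as invalids. Real LLM inference
is out of the test path by design: the backend contract is one
deterministic `generate(prompt) -> str` method.

## Acceptance problem sizes

`scripts/acceptance.py` and the replicate-based tests use desk-scale
studies chosen once:

- **Null calibration**: 3 subjects, 8 regions, 120 scans, 4-channel
  montage, logistic classifier, 200–400 replicate studies. Four channels
  keep the lagged feature dimension (144) below the per-condition training
  size (114), and one replicate under a second.
- **Signal recovery**: gain 3.0, noise SD 0.5, 4 channels, 200 scans —
  sized so the training set (195 samples) exceeds the feature dimension
  (144); in an under-determined regime, estimation error rather than
  coupling strength caps accuracy, which is not the property this
  benchmark measures.
- **Gain monotonicity**: rejection rates at gains 0 / 0.5 / 3.0, 100
  replicates each.

## Known limitations

- The evaluation is across sessions within subject, never across subjects.
- Subject-region pairs are not independent (shared features within a
  session; shared conditions across iterations); the Wilcoxon treats them
  as exchangeable pairs, as the study design prescribes.
- The synthetic generator's linear-convolutional coupling is a best case
  for the models; real EEG-BOLD coupling is weaker and less stationary.
- The 1-D CNN path consumes synthetic raw EEG only; no artifact correction
  is implemented because the emulated recordings arrive preprocessed.
- Brain-surface rendering is out of scope; per-ROI results are tabular.
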