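# Methods

## Problem setting

`nvad` detects, frame by frame, whether a person is producing speech, using
only multichannel neural recordings (ECoG field potentials) — no acoustic
ground truth. The motivating scenario is a speech brain-computer interface
for users who cannot vocalize: supervised voice-activity detectors need
time-aligned audio, which such users cannot provide. The package instead

1. extracts high-gamma (70–170 Hz) log-power features,
2. segments each recording day into two temporally coherent clusters with
   Toeplitz Inverse Covariance-based Clustering (TICC),
3. names the minority-time cluster "speech" (the cued-word experiment design
   guarantees most of each session is silent),
4. uses those estimated labels to train conventional frame-wise classifiers
   (L1 logistic regression, a LeNet-like CNN, a two-layer LSTM), and
5. runs the trained classifier inside a streaming pipeline whose output is
   frame-identical to offline inference.

## Feature extraction

Per grid, bad channels are dropped and a common average reference is
subtracted at every sample. Each channel then passes a causal 4th-order
Butterworth band-pass (70–170 Hz) and a causal 4th-order Butterworth
band-stop (118–122 Hz, first line-noise harmonic), both realized as
second-order-section cascades with explicit filter state. Log power is
computed over 50 ms windows advancing by 10 ms: `log(mean(x²) + 1e-10)`;
the additive floor keeps silent windows finite. Features are z-scored per
day against a baseline (syllable-task surrogate) segment; standard
deviations below 1e-6 are floored and produce all-zero features.

All filtering is strictly forward (no zero-phase second pass). This choice
is what makes the offline and streaming paths bit-identical: a zero-phase
filter would read future samples offline that the streaming path can never
see. Frame `i` covers samples `[i·shift, i·shift + window)` (half-open,
0-based) and becomes available when its last sample does.

Classifiers without internal memory (logreg, CNN) see context-stacked
frames: lags (0, 5, 10, 15, 20, 25, 30) in 10 ms frames, i.e. seven
non-overlapping 50 ms windows spanning 300 ms of the past. Out-of-range
lags at a sequence start are zero-filled, which in z-scored space equals
the baseline mean.

## TICC

Each of K clusters (K = 2 here) is a Gaussian Markov random field over a
window of `w` feature frames spaced `dilation` frames apart, with mean μ_k
and a sparse precision Θ_k constrained to be symmetric, positive definite
and block-Toeplitz: the C×C block coupling window layers i and j depends
only on i−j, so cross-lag dependencies are time-invariant. `w = 1` (no
temporal context) is the default; `w = 5` and `w = 7` with dilation 5 reach
200 ms and 300 ms into the past.

Fitting minimizes the joint objective

    J = Σ_t NLL(x_t; μ_{c_t}, Θ_{c_t}) + β · #(label switches)
        + Σ_k λ · ‖Θ_k‖₁(off-diagonal)

by exact coordinate descent:

* **Assignment step.** Given the MRFs, the minimum-cost label path under
  per-frame negative log-likelihoods plus the switching penalty β is found
  by a forward dynamic program with backtracking (O(T·K)). Ties break
  toward the lower cluster index. β = 0 reduces to independent per-frame
  assignment; β → ∞ yields a single segment.
* **Update step.** Per cluster, `argmin (n_k/2)(−logdet Θ + tr(S_k Θ)) +
  λ‖Θ‖₁` over the block-Toeplitz PD cone, solved by ADMM: an eigenvalue
  proximal step for the log-det term, and a combined proximal step that
  soft-thresholds the mean of each Toeplitz equivalence class (the exact
  prox of the summed L1 + quadratic terms sharing one value; matrix
  diagonal unpenalized). The λ weight is per cluster, not per assigned
  frame, which is what makes both steps minimize the same J and the
  recorded objective trace provably non-increasing.

Initial assignments come from a full-covariance Gaussian mixture with
random-from-data responsibility initialization — k-means-style seeding
cannot separate clusters that differ in covariance but not mean.
Convergence is declared when the assignment is stationary, with a cap of
100 iterations. Because EM-style alternation is sensitive to its starting
point (a poor start can collapse one cluster), the fit restarts from five
diversified mixture initializations and keeps the run with the lowest final
objective; everything is deterministic given the seed.

Numerical choices: ADMM penalty starts at ρ = 1 with residual balancing
every 10 iterations (×2 / ÷2 with dual rescaling when primal and dual
residuals diverge by more than 10×) — a fixed ρ stalls on day-scale
covariance conditioning; stopping tolerances 1e-6 absolute / 1e-4 relative,
iteration cap 1000 (exceeding it raises with the residuals). Empirical
covariances get 1e-6 diagonal loading; the returned Z iterate is exactly
block-Toeplitz and is diagonally loaded to an eigenvalue floor of 1e-8 if
needed. A cluster emptied by the assignment step is rescued by reassigning
the 1% worst-fit frames to it; a rescue event restarts descent, so the
objective trace is guaranteed monotone only between rescues (rescues do not
occur on non-degenerate two-cluster data). Clusters with fewer than
max(20, wC/10) frames keep their previous parameters.

Default hyperparameters: β = 50 and λ = 11×10⁻⁴, the values selected by
grid search on calibration data (the package re-implements that grid search
over (β, λ) minimizing the median per-trial alignment error on a
calibration session with reference labels).

## Cluster → label inference

With two clusters and a cued-word design (2 s cue + 3 s inter-trial
interval per trial, ~1.2 s of speech), speech occupies a minority of each
session. The cluster with the smaller **total assigned duration** is
labeled speech. Mean run length is available as an alternative rule
(`rule="mean_run_length"`); total duration is the default because the
design argument is about total time, not run shape. Exact ties label the
lower cluster index speech with a warning. No post-hoc merging of adjacent
speech segments is applied.

## Classifiers

All three train on binary frame labels (estimated or reference) and emit
one class per 10 ms frame.

* **logreg** — scikit-learn LogisticRegression (liblinear, L1, strength
  1.0 by default) on 7-lag stacked frames.
* **cnn** — LeNet-like: two (3×3 same-padded convolution → tanh → 2×2 max
  pool, floor) stages with 32 then 64 feature maps on a channels × lags
  input image, then fully-connected 128 → 64 → n_out with tanh and a
  softmax cross-entropy readout. Adam, lr 1e-4, 10 epochs, shuffled
  minibatches of 256. The output layer defaults to 2 units (binary VAD);
  the width is configurable.
* **rnn** — two LSTM layers with 100 units and a linear 2-unit readout on
  unstacked frames. Adam, lr 3e-4, 20 epochs, truncated backpropagation
  through time with k₁ = k₂ = 50 frames (update every 50-frame chunk,
  hidden state carried across chunks but detached), keeping the weights of
  the epoch with minimum validation loss. Equal-length training sessions
  run as one batch.

The networks are implemented directly in numpy (forward, backward, Adam),
which keeps training bit-reproducible from a seed and the dependency
footprint minimal. Gradient correctness is verified against central finite
differences in the test suite.

`predict_offline` is **defined** as the fold of `predict_step` over the
sequence for all three architectures (the stacked models keep a lag ring
buffer in the streaming state; the LSTM keeps hidden state). Offline and
streaming inference therefore agree frame-for-frame by construction rather
than by floating-point coincidence, and the streaming tests exercise the
full preprocessing path on top of it.

## Evaluation

* **Alignment error** = 10 ms × Levenshtein distance between predicted and
  reference binary label strings (edlib; substitutions, insertions and
  deletions cost one frame each). Reported per trial over the window
  [cue onset, next cue onset), so both missed speech and spurious
  detections in the inter-trial interval count; the window choice matters
  because "per trial" alone does not fix boundaries.
* **Detection / false-alarm probability** = TP/(TP+FN) over reference
  speech frames and FP/(FP+TN) over reference non-speech frames; empty
  denominators are reported as absent, not zero.
* **Majority detection rate** = fraction of trials in which strictly more
  than 50% of reference speech frames are predicted speech. A trial is "not
  detected" when none of them are. Trials with alignment error above the
  mean speech duration are counted but never removed from the stored
  per-trial errors.
* **Leave-one-day-out cross-validation**: each day serves once as the test
  set; one further day is withheld for validation; each day is z-scored
  against its own baseline; training labels come from per-day TICC
  (`ticc`), the acoustic reference (`reference`), or a permuted reference
  (`shuffled` — a chance-level control); a designated development day can
  be excluded throughout. Evaluation is always against ground truth.
* **Channel contributions**: with K = 2, the element-wise absolute
  difference of the two precisions' lag-0 blocks gives a per-channel
  same-electrode term (diagonal) and a total interdependency (off-diagonal
  row sum); cross-lag blocks are summarized as a single mass separately,
  since the electrode-adjacency reading applies to the within-time block.
* **Reference VAD surrogate**: audio resampled to 16 kHz, 50 ms / 10 ms
  log-energy frames, trailing 5-frame moving average, speech when energy
  exceeds min(20th percentile + 10 dB, −20 dBFS). The percentile tracks
  the noise floor; the absolute cap keeps an always-loud signal detectable.
  This stands in for the acoustic VAD used to produce reference labels; any
  VAD with frame-level output can be substituted.

## Synthetic data

The generator emulates one recording day: a baseline segment (30 s by
default) followed by `n_trials` cued-word trials (2 s cue + 3 s ITI).
Speech onsets 0.2–0.6 s after the cue; durations are truncated normal
(mean 1.2 s, sd 0.25 s, min 0.3 s). Onsets/offsets are snapped to the
10 ms frame grid so frame labels and the trial table agree exactly.

The raw signal is per-channel pink noise plus a shared per-grid common mode
(so CAR does real work), a 120 Hz line-noise sinusoid with per-channel
phase (so the notch does real work), and a day-specific multiplicative
channel gain `exp(N(0, 0.1))` (so per-day z-scoring does real work).
During speech, a band-limited (70–170 Hz) latent envelope is mixed into a
subset of channels with per-channel loadings uniform(0.8, 1.5), scaled to
1.5× the in-band background RMS — both an amplitude and a spatial-
covariance signature, which is what TICC exploits. By default one in eight
channels of **each** grid carries modulation: concentrating all modulated
channels in one grid would make the per-grid CAR subtract their common
burst and leak an inverted copy onto the rest of that grid, blurring the
spatial structure; focal activation spread across grids is also the more
realistic configuration. The audio surrogate is 48 kHz white-noise bursts
(Tukey envelopes) over a −60 dBFS noise floor — only envelope timing
matters for the energy-based reference VAD.

What the generator does **not** emulate: non-stationary drift within a
day, behavioral variability in articulation effort across words,
electrode-specific noise spectra, acoustic contamination of neural
channels, or any real cortical geometry. Passing tests therefore show the
pipeline is correct and self-consistent under its own generative
assumptions, not that it reaches the error levels attainable on real
recordings.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen to exercise
every code path with comfortable statistical margins: 16-channel / 2-grid
sessions, 12–16 trials per day, 4-day cross-validation with the RNN at 3
epochs, feature-space recovery at T = 25000 frames, and 10-seed channel-
contribution replication. The defaults of `SessionConfig` (64 channels,
100 trials, 30 s baseline) reflect the full-scale protocol and are used
when generating datasets via the CLI with explicit overrides removed.

## Known limitations

* The minority-duration rule fails by construction if a session is mostly
  speech; it warns and emits the speech-time fraction as a diagnostic.
* TICC with many layers (w = 7) estimates O((wC)²) parameters per cluster
  and degrades on short sessions — consistent with temporal context not
  helping at realistic data sizes; `w = 1` is the default.
* The CNN/LSTM numpy implementations favor reproducibility over speed; at
  full-protocol scale a GPU framework would be the pragmatic substitute,
  at the cost of bit-reproducibility.
* Latency fields in streaming events are measured wall-clock values for
  reporting only; they are hardware-dependent and never asserted.
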