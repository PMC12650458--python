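# Methods

This note documents the models, estimators and design choices behind
`neurofuse`, in the spirit of a package's statistical reference manual.
It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic coupled EEG–fNIRS data

The generator emulates a video-elicited emotion protocol: each subject
watches 15 clips per emotion class (happy/fear/sad/calm analogues,
labelled 0–3) while EEG (200 Hz) and fNIRS hemoglobin series (11 Hz) are
recorded. Channel counts default to a desk-scale montage (8 EEG, 4
fNIRS); a full-scale 62-channel layout is a configuration change, not a
code change.

**EEG.** Class c draws a stationary VAR(1) process with coefficient
matrix `0.5·I + 0.3·P_c`, where `P_c` is the cyclic shift by `c+1`
channels — a distinct directed coupling graph per class whose companion
spectral radius is at most 0.8. A burn-in of 500 samples is discarded so
the retained segment starts from the stationary distribution; spec
validation rejects any coefficient set with spectral radius ≥ 1, naming
the radius. The broadband VAR output is recomposed from its four rhythm
bands with per-class gains (the class-c band is emphasised ×1.6),
mimicking class-dependent spectral power, then broadband measurement
noise (sd 0.3) is added. The EEG is thus band-limited to 4–45 Hz by
construction.

**fNIRS forward model.** Each optical channel averages the smoothed
(0.5 s moving average) power envelopes of its round-robin-assigned EEG
channels, convolves with a canonical double-gamma hemodynamic response
(gamma shapes 6 and 16 at 1 s scale — peak near 6 s, undershoot near
16 s, undershoot ratio 1/6, unit peak), scales by the neurovascular
coupling gain (default 1.0), and is resampled to 11 Hz. Cardiac
(1.2 Hz) and respiratory (0.3 Hz) sinusoids with random amplitude and
phase, plus white noise (sd 0.3), are superimposed — these sit inside
the 1–1.5 Hz and 0.2–0.4 Hz nuisance bands a real optical recording
contains. HbR is the coupled HbO2 component scaled by −0.4 plus its own
nuisance and noise, reproducing the qualitative HbO2/HbR opposition of
neurovascular coupling with a single parameter rather than a biophysical
oxygen-extraction model.

**What the generator does not emulate.** Volume conduction and channel
correlation structure of real montages, non-stationarity within clips,
ocular/motion artifacts, optode-skin coupling drift, subject-specific
hemodynamic response variability, and any realistic stimulus timing.
Passing tests therefore demonstrate that the estimators and the
classifier recover the *modelled* class structure, not that the method
attains any particular accuracy on real recordings.

## 2. Preprocessing

* **Filters.** All band-pass filters are 4th-order Butterworth applied
  forward–backward (`sosfiltfilt`), i.e. zero-phase; a pass-band tone's
  cross-correlation peak with its filtered copy is at lag 0. EEG is
  filtered to 4–45 Hz and split into θ/α/β/γ; fNIRS to 0.01–0.2 Hz, the
  task-related hemodynamic range.
* **Rate conversion.** Downsampling is polyphase and anti-aliased, with
  the per-channel mean routed around the filter because the designed
  FIR's pass-band gain is not exactly unity (a constant series must
  survive exactly). Upsampling (11 → 200 Hz) uses a quintic
  interpolating spline through the original samples: it is exact at the
  knots like a cubic, but its boundary error for a band-limited test
  tone is ≈ 4.6e-4 of amplitude versus ≈ 2.7e-3 for the not-a-knot
  cubic, comfortably inside the 1e-3 contract the resampler is tested
  against. For very short series the order falls back to cubic/linear.
* **Beer–Lambert.** Optical-density to chromophore conversion solves the
  2×2 system ΔOD(λ) = ε(λ,·)·[ΔHbO2, ΔHbR]·d·DPF(λ) per sample and
  errors on singular extinction matrices. The synthetic pipeline
  produces hemoglobin directly; `mbll` exists for ingesting raw-style
  optical data and is verified by forward-model round-trips.
* **Windowing.** 3 s windows with 1.5 s hop at 200 Hz (600 samples, hop
  300), 0-based half-open, trailing partial windows dropped; each
  window is baseline-corrected by removing the per-channel mean, which
  is also required for stable intercept-free AR fits. A 60 s clip yields
  39 windows.
* **Splits precede windowing.** Subject-dependent five-fold rotation
  holds out 1/5 of each (subject, class) cell's clips per fold (3 of 15
  under the standard protocol) using a seeded permutation; LOSO holds
  out one subject per fold. Overlapping windows from one clip can never
  straddle partitions, and `partition_bundles` re-validates this at use.

## 3. Granger causality

For target x and source y with order p, both models are ordinary least
squares on the identical effective sample (the first p samples are lost
to lagging), after mean removal and with no intercept:

* restricted: x(t) = Σ aᵢ x(t−i) + μ₁(t)
* full: x(t) = Σ a₁ᵢ x(t−i) + Σ a₂ᵢ y(t−i) + μ₂(t)
* F_{y→x} = ln( Var(μ₁) / Var(μ₂) ), residual variances with the plain
  denominator n_eff = n − p.

Nesting on a shared sample guarantees F ≥ 0 (tiny negative round-off is
clipped). Under independence the likelihood-ratio identity gives
n_eff·F → χ²(p); the test suite checks this calibration directly
(Kolmogorov–Smirnov distance < 0.1 over 500 replicates) and
cross-checks the statistic against `statsmodels`' Granger LR test.

**Degenerate inputs.** A fit whose residual variance falls below 1e-12
of the target variance raises a degenerate-fit error. Because the
contract fit is intercept-free on demeaned data, an exactly
deterministic recursion with nonzero mean (e.g. x(t)=0.9·x(t−1)) leaves
a small mean-leakage residual; when the intercept-free fit is
suspiciously good (relative residual < 1e-3) an intercept-augmented
re-fit is checked against the same 1e-12 floor so true determinism is
still caught.

**Matrix computation.** Within-EEG matrices (entry (i,j) = F_{i→j},
zero diagonal, one matrix per band) and cross-modal matrices share lag
Gram blocks across pairs: with L_c the lag block of channel c, every
pair's normal equations need only L_i᙮L_j and L_i᙮x_j, each computed
once. Residual sums of squares are always evaluated from explicit
residual series, never as TSS − b᙮β, which would cancel catastrophically
for strongly autocorrelated band-limited signals. The batched path is
tested to agree with the pairwise estimator to 1e-8 on well-conditioned
inputs.

**Order policy.** A single AR order per (band, direction) keeps matrix
entries comparable across pairs. The default selects per-pair BIC
orders on up to 20 randomly sampled pairs and shares the rounded mean;
a fixed integer policy is accepted everywhere. In the windowed pipeline
the search is capped at order 5: heavily oversampled narrowband series
(a 4–8 Hz rhythm sampled at 200 Hz) are so predictable that BIC runs to
any cap while the residual approaches machine precision, making higher
orders numerically meaningless.

**Cross-modal direction.** The classifier consumes the fNIRS→EEG
matrices (HbO2 by default; HbR available). The reverse EEG→fNIRS
direction is computed on request: after spline upsampling to 200 Hz the
hemodynamic series is locally polynomial and hence nearly deterministic
as a prediction *target*, so the pipeline restricts itself to EEG
targets; the EEG→fNIRS direction is exercised in tests at the native
11 Hz rate, where a longer AR history (order ≈ 25, i.e. ≈ 2.3 s) spans
enough of the hemodynamic delay to detect the coupling.

## 4. Classifier

Nine streams per window, in fixed order: four within-EEG GC matrices
(θ, α, β, γ), one fNIRS time-series block (HbO2 and HbR rows stacked,
600 samples), four cross-modal GC matrices. Each branch applies three
stride-1, padding-1 convolutions (32/64/128 filters; 3×3 for matrix
inputs, 3-tap temporal for the fNIRS block), ReLU between layers, no
pooling (spatial structure is preserved end to end), then flattening
and a 128-unit fully connected layer with dropout 0.3. The three
branches share weights across their band streams within a branch but
not across branches. The result is the 9×128 deep feature X.

**Attention.** Global average pooling over the feature axis gives the
9-vector descriptor s, partitioned 4/1/4. Each group passes through a
bias-free bottleneck W₂·ReLU(W₁·s_g) with hidden width 4 and a sigmoid
output, yielding one multiplicative weight per stream: 2×(4·4+4·4) + 
(4·1+1·4) = 72 trainable scalars — the unique small configuration
consistent with that parameter budget. The reweighted features are
flattened (1152) into the 4-way softmax classifier. An
`attention_scale` factor (default 1.0) multiplies the sigmoid output;
with weights in (0,1) by default, scale 2 with zeroed output layers
makes z ≡ 1 exactly, which the tests use to show the attention model
collapses bitwise onto the plain backbone. ReLU-then-sigmoid is used
(an all-ReLU bottleneck could not produce bounded per-stream weights).

**Branch heads.** Three lightweight linear softmax heads read the
*pre-attention* grouped features (EEG 4×128, fNIRS 128, cross 4×128).
They exist in every variant — so backbone variants with and without
branch supervision have identical parameter counts — and only the loss
wiring decides whether they train.

**Implementation.** No deep-learning framework is used: layers are
NumPy (im2col convolutions, explicit backprop), float32, with
Kaiming-uniform convolution and Xavier-uniform dense initialisation
drawn from a seeded generator. Attention parameters are initialised
last so backbone weights are bitwise identical across `use_mfa`
settings at a fixed seed. Adam (lr 0.005, β = 0.9/0.999) folds both
bias corrections into a scalar step size and updates in place.

## 5. Weighted multi-loss

L = L_global + μ·L_local with L_local = w_e·L_EEG + w_f·L_fNIRS +
w_ef·L_cross. Cross-entropies clamp the log at 1e-12 so exact 0/1
probabilities stay finite. Branch weights are proportional to running
branch accuracies, normalised to sum to one, with uniform 1/3 at cold
start (the ratio is undefined at zero denominator). Accuracies are
exponential moving averages (decay 0.9) updated once per epoch from
that epoch's training predictions, and are treated as constants in the
gradient — backpropagating through them would reward a branch for
lowering its own accuracy. μ defaults to 1.0. Setting μ = 0 recovers
plain global training; unit weights recover the unweighted multi-loss
variant; both identities hold bitwise in the trainer and are tested.

## 6. Protocols, variants and the desk-scale benchmark

Window-level metrics (each 3 s window is one sample): accuracy mean/SD
across folds, per-class accuracy and the 4×4 confusion matrix. Variants:
`backbone`, `backbone_mfa`, `backbone_wml`, `mfa_cnn_unweighted`,
`mfa_cnn`, differing only in attention presence and loss wiring; the
attention variants exceed the others by exactly 72 parameters.

The benchmark configuration used by the acceptance script and the
end-to-end tests is 2 subjects × 4 classes × 15 clips × 7.5 s at 8 EEG /
4 fNIRS channels, features at the BIC-shared order, and 5 training
epochs — sizes chosen so the whole generate→train cycle runs in minutes
on one CPU while keeping the clip-wise 12/3 split structure. Epoch
count is configuration-bound (package default 100 with early stopping,
patience 20, when a validation set is supplied); the benchmark's 5
epochs suffice because the separable features are nearly linearly
separable. The null benchmark (identical couplings for all classes) is
judged against the 95% binomial band around 25% computed at the
*clip* count, since windows within a clip are strongly correlated.

## 7. Numerical conventions and edge cases

* Seeds: every stochastic component (simulation, shuffling, dropout,
  initialisation, order-selection subsampling) draws from generators
  derived via `SeedSequence` from explicit integer seeds; identical
  configuration implies byte-identical datasets and bitwise identical
  trained parameters.
* Feature standardisation (one mean/sd per GC stream, per fNIRS row) is
  fitted on the training partition only.
* BIC ties break toward the smaller order; attention groups are fixed
  ordered slices (EEG 0–3, fNIRS 4, cross 5–8).
* Recordings reject non-finite values, duplicate channel labels and
  non-positive rates at construction; encoders reject inputs smaller
  than their kernels; clips shorter than one window produce an empty
  segment list with a warning.

## 8. Known limitations

* GC is pairwise and time-domain only: no conditional/multivariate GC,
  no spectral decomposition, no surrogate-based significance beyond the
  χ² null used in tests.
* Band-filtered, oversampled series make absolute GC magnitudes
  order-sensitive; only the shared-order policy makes matrix entries
  comparable, and values should be read as relative features rather
  than calibrated effect sizes.
* The cross-modal features at the aligned 200 Hz rate see ≈ 25 ms of
  history — far below hemodynamic delays — so class information is
  carried mainly by the within-EEG matrices; the cross-modal branch is
  structurally exercised but weakly informative at window scale.
* The hemodynamic model is linear and time-invariant with a fixed
  canonical response; only its amplitude varies.
* Training is single-threaded NumPy; full-scale 62-channel, 50-subject
  runs are possible but slow, and no GPU path is provided.
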