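# neurofuse

Granger-causal EEG–fNIRS fusion for emotion decoding.

`neurofuse` implements a complete multimodal physiological-signal
pipeline for four-class emotion recognition from simultaneously acquired
EEG and functional near-infrared spectroscopy (fNIRS):

1. **Synthetic neurovascular data.** A generator simulates multi-subject,
   multi-clip paired recordings with *known* directed structure: EEG is a
   stationary vector autoregression (VAR) whose coupling pattern and
   rhythm-band emphasis differ by emotion class; fNIRS oxyhemoglobin is
   the EEG band-power envelope convolved with a canonical double-gamma
   hemodynamic response, plus cardiac (1.2 Hz) and respiratory (0.3 Hz)
   nuisance and noise, with deoxyhemoglobin anti-correlated at a −0.4
   ratio.
2. **Preprocessing.** Band-pass filtering (EEG 4–45 Hz, fNIRS
   0.01–0.2 Hz), extraction of the θ (4–8), α (8–12), β (12–30) and
   γ (30–45 Hz) rhythms, modified Beer–Lambert conversion, rate
   alignment at 200 Hz, 3 s / 1.5 s sliding windows, and leakage-free
   clip-wise train/test splits.
3. **Granger causality (GC).** For a target series X and candidate
   source Y, nested intercept-free autoregressions give

   F_{Y→X} = ln( Var(μ₁) / Var(μ₂) ),

   the log ratio of restricted (X on its own past) to full (X on the
   past of X and Y) residual variances; F ≥ 0, and under the null
   n_eff·F ~ χ²(p). Per window the pipeline produces four within-EEG GC
   matrices (one per band) and four fNIRS→EEG cross-modal GC matrices.
4. **Classifier.** A three-branch convolutional network (three stride-1
   convolutions with 32/64/128 filters, no pooling, then a 128-unit FC
   per stream) encodes the 9 feature streams; a grouped
   modality–frequency attention module (groups 4 EEG / 1 fNIRS /
   4 cross-modal, bias-free two-layer bottlenecks, hidden width 4 —
   exactly 72 trainable scalars) reweights the streams before the
   softmax classifier. Training minimises a weighted multi-loss
   L = L_global + μ · (w_e·L_EEG + w_f·L_fNIRS + w_ef·L_cross) with
   branch weights w_k = a_k / Σa proportional to running branch
   accuracies. The network and its Adam trainer are implemented in
   NumPy with explicit backpropagation.

The package is aimed at researchers studying neurovascular coupling and
effective connectivity in hybrid EEG–fNIRS brain–computer interfaces who
need a fully inspectable, dependency-light reference pipeline with
ground-truth-verifiable behaviour.

## Worked example

```python
import neurofuse as nf
from neurofuse.features import dataset_to_bundles
from neurofuse.train import TrainConfig, cross_validate

cfg = nf.SimConfig(n_subjects=2, n_clips_per_class=15, clip_duration=7.5,
                   n_eeg_channels=8, n_fnirs_channels=4, seed=0)
ds = nf.generate_dataset(cfg)                 # 120 paired clips
bundles = dataset_to_bundles(ds, seed=0)      # 360 windowed GC bundles
rep = cross_validate(bundles, "fivefold_subject_dependent",
                     TrainConfig(variant="mfa_cnn", epochs=5, seed=0))
print(f"{rep.accuracy_mean:.1f}% +/- {rep.accuracy_sd:.1f}")
```

This prints `99.7% +/- 0.6`: with class-distinct couplings the GC
features are almost perfectly decodable, and each fold's held-out clips
(3 of 15 per subject and class) are classified window by window. Running
the same protocol with `class_coupling=nf.default_class_coupling(8, 4,
separable=False)` — identical generative parameters for every class —
yields ≈ 23%, i.e. chance for four balanced classes, confirming that the
pipeline finds no signal where none exists.

The same steps are available from the shell:

```bash
neurofuse simulate --config sim.json --out data/ --seed 0
neurofuse features --in data/ --out features.npz
neurofuse crossval --data features.npz --variant mfa_cnn
neurofuse ablation --data features.npz
```

## Layout

| Module | Contents |
| --- | --- |
| `neurofuse.synthetic` | coupling specs, VAR simulation, neurovascular forward model, dataset generation/IO |
| `neurofuse.preprocess` | filtering, band extraction, resampling, STFT band power, Beer–Lambert, windowing, splits |
| `neurofuse.granger` | AR fitting, order selection, pairwise GC, within-EEG and cross-modal GC matrices |
| `neurofuse.features` | clip → windowed feature-bundle pipeline |
| `neurofuse.nn`, `neurofuse.model` | NumPy layers and the three-branch attention classifier |
| `neurofuse.loss` | weighted multi-loss and branch-accuracy tracking |
| `neurofuse.train` | training loop, 5-fold and LOSO protocols, ablations, metrics |
| `neurofuse.benchmark` | the desk-scale separable/null benchmark configurations |

See `docs/methods.md` for modelling assumptions, parameter choices and
known limitations.
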