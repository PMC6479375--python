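# delda

Feature extraction and benchmarking for multichannel emotion EEG:
per-band **differential entropy** (DE) fused with multi-class
**linear discriminant analysis** (LDA), plus the five-classifier
evaluation harness needed to compare the two stages against raw-signal
baselines — all exercisable end to end on synthetic data, with no access
to a gated EEG corpus required.

## The problem and the method

Affective brain–computer interfaces classify a subject's emotional state
(negative / neutral / positive) from EEG. Raw multichannel EEG is
high-dimensional and noisy; the pipeline implemented here reduces it in two
stages:

1. **Band decomposition.** Each trial (channels × samples, 200 Hz) is
   band-pass filtered into the five canonical rhythms — Delta 1–3, Theta
   4–7, Alpha 8–13, Beta 14–30, Gamma 31–50 Hz — with a zero-phase
   5th-order Butterworth filter. Band-filtered EEG is well approximated by
   a zero-mean Gaussian, so the differential entropy of channel *c* in band
   *i* has the closed form

   *h_i(X) = ½ ln(2πe σ_i²)*  (nats),

   i.e. one log-variance feature per (channel, band). With 62 channels and
   5 bands the "combined band" feature vector has 310 entries per trial.

2. **Fisher discriminant reduction.** With class means μ_j, global mean μ
   and class sizes N_j, the within- and between-class scatter matrices are
   S_w = Σ_j Σ_{x∈X_j} (x−μ_j)(x−μ_j)ᵀ and
   S_b = Σ_j N_j (μ_j−μ)(μ_j−μ)ᵀ. The projection W maximizing the Fisher
   quotients wᵀS_b w / wᵀS_w w is obtained from the generalized
   eigenproblem S_b w = λ S_w w; at most K−1 = 2 directions carry
   between-class information for 3 classes. The projection is always
   fitted on the training split only.

The evaluation harness benchmarks four feature conditions (`raw`, `lda`,
`de`, `de_lda`) across bands with five classifiers (k-NN k=20, L2 logistic
regression, RBF SVM C=1, random forest 120/10/8, MLP 64+32) over repeated
stratified 70/30 splits, reporting accuracy, macro precision/recall/F1,
Cohen's kappa, summed confusion matrices and per-split fit+predict time.

Because real emotion corpora are registration-gated, the package ships a
synthetic generator that emulates the standard corpus geometry (15 subjects
× 3 sessions × 15 clips = 675 trials, 62 channels, 200 Hz) with the class
signal encoded exactly where DE can see it: per-band, per-channel
log-variance offsets. Its analytic ground truth makes every pipeline stage
testable.

## Worked example

```bash
delda --log-level WARNING run --config demo.yaml
```

with `demo.yaml` describing a small synthetic run (4 subjects, 16 channels,
4-s clips, strong band-power effect, SVM + random forest, 10 stratified
70/30 splits):

```yaml
seed: 7
input: {kind: synthetic, preset: strong, n_subjects: 4, n_clips_per_class: 3,
        n_sessions: 1, n_channels: 16, clip_seconds: 4}
conditions: [de, de_lda]
classifiers: [svm, rf]
protocol: {mode: repeated_holdout, repeats: 10}
out_dir: demo_run
```

The run writes `metrics_<condition>.tsv`, `per_split_<condition>.tsv`,
`timing_<condition>.tsv`, one summed confusion matrix per cell, and a
reproducibility manifest. The DE + SVM rows of `metrics_de.tsv` from that
run:

```
    band classifier  accuracy_mean  accuracy_std  macro_f1_mean  kappa_mean
   alpha        svm       0.309091      0.129986       0.262919    0.002262
    beta        svm       1.000000      0.000000       1.000000    1.000000
   gamma        svm       1.000000      0.000000       1.000000    1.000000
combined        svm       0.936364      0.061359       0.933862    0.904429
```

Read: the generator placed its class effect in beta/gamma band power, so
beta/gamma DE separates the classes perfectly while alpha sits at the 1/3
chance level (kappa ≈ 0); `metrics_de_lda.tsv` shows the same structure
after reduction to 2 Fisher components (combined-band SVM 0.99), with
per-split SVM times an order of magnitude below the 310-feature condition
(`timing_*.tsv`).

`delda synth` writes a synthetic corpus to EDF files plus a label sidecar
and a ground-truth JSON; `delda run` also accepts such an EDF directory as
input (`input: {kind: edf, edf_dir: ..., sidecar: ...}`), so the pipeline
runs unchanged on any EDF dataset with one categorical label per file.

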