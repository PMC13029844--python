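# gaitrank

Person identification from ground-reaction-force (GRF) gait recordings,
with rank-based fusion of a classifier ensemble — built for studying how
well gait biometrics survive an everyday covariate: carrying a briefcase in
one hand.

A walker crosses two hidden force plates; each limb's stance yields three
force components (anterior–posterior, vertical, medial–lateral) at 960 Hz,
giving a six-channel cycle `(L_AP, L_V, L_ML, R_AP, R_V, R_ML)` in raw
newtons, zero during swing and zero-padded to a common length. Because the
plates are all a deployed system sees, signals are never normalised by body
weight — the mass dependence is part of the biometric, and also the reason
an asymmetric load is a serious confound.

## The method

K base classifiers (1-D deep networks and/or a deterministic
nearest-centroid reference) each produce class posteriors, truncated to an
ordered Top-T list per sample. Fusion is purely ordinal. With
`Acc[j,p]` the held-out probability that classifier *j*'s first *p*
positions contain the true identity, classifiers get per-position
competition ranks `R[j,p]` (ties reordered by Top-1 accuracy, residual ties
shared) and quality weights

    w[j,p] = (K + 1 − R[j,p]) / K .

Two voting rules are implemented:

* **weighted vote by rank order** — one Top-1 vote per classifier, weight
  `w[j,1]`;
* **rank-based additive weighted Top-T vote** — T votes per classifier,
  position *p* carrying `λ·f_p + (1−λ)·w[j,p]` with `f_p = (T+1−p)/T`;
  λ is swept over (0, 5] in steps of 0.1 (λ > 1 privileges position over
  classifier quality and is often optimal).

Tied maximal scores fall back to the Top-1 indication of the most accurate
base classifier; if that is ambiguous the ensemble answers `None`, which
counts as an error. Three protocols probe covariate robustness: **A**
(train and test unloaded, 10-fold CV), **B** (train unloaded, test loaded)
and **C** (B plus a ×9 augmentation of the training set: band-limited
noise injection, ±15-sample per-leg time shifts, ≤3 % left-stance cropping
with resampling, same-class mixup, and their listed combinations).

Because the kind of laboratory dataset this pipeline targets is not
publicly distributable, the package ships a synthetic gait-population
generator (`gaitrank.synthetic`) with subject-specific waveform templates,
mass-correlated vertical peaks, trial-to-trial noise and an
asymmetric-load model — every experiment below is reproducible from a
seed. See `docs/methods.md` for the model and its limits.

## Worked example

```python
from gaitrank.synthetic import GeneratorConfig, build_study
from gaitrank.classifiers import ClassifierConfig
from gaitrank.evaluation import run_scenario

cfg = GeneratorConfig(n_subjects=30, trials_min=15, trials_max=15, seed=1)
unloaded, loaded = build_study(cfg)          # 450 + 450 cycles

harness = [
    ClassifierConfig(architecture="nearest_centroid", seed=1, downsample=4),
    ClassifierConfig(architecture="cnn", seed=1, downsample=16,
                     conv_filters=(16, 32), conv_kernels=(7, 5),
                     fc_units=(64,), max_epochs=30, patience=6),
]

for scen in ("B", "C"):
    rep = run_scenario(scen, unloaded, loaded, harness, seed=1)
    ro, _ = rep.mean_sd(rep.rank_order_accuracy)
    tt, _ = rep.mean_sd(rep.topT_accuracy)
    print(f"scenario {scen}: bases "
          f"{[round(v[0], 3) for v in rep.base_top1.values()]}, "
          f"rank-order {ro:.3f}, top-T {tt:.3f} "
          f"(lambda* {rep.topT_best_lambda[0]:.1f})")
```

prints

```
scenario B: bases [0.196, 0.813], rank-order 0.813, top-T 0.551 (lambda* 1.0)
scenario C: bases [0.2, 1.0], rank-order 1.000, top-T 0.744 (lambda* 1.0)
```

Reading: under the briefcase covariate (B) the raw-distance centroid
collapses to 19.6 % while the CNN holds 81.3 %; the rank-order vote
correctly follows the validation-best member. Augmenting the training set
(C) lifts the CNN — and with it the ensemble — to 100 % on this synthetic
study, the same qualitative recovery that motivates augmentation for gait
biometrics. Misclassifications concentrate among subjects of similar body
mass (`run_scenario(..., with_mass_gap=True)` reports the histogram and
ECDF).

A `gaitrank` CLI wraps the same functionality (`simulate`, `augment`,
`train`, `fuse`, `evaluate` subcommands); see `gaitrank --help`.

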