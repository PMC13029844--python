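# Methods

## Problem setting

`gaitrank` addresses closed-set person identification from ground reaction
forces (GRFs): a walker crosses two force plates, each recording one stance
phase as three components — anterior–posterior (AP), vertical (V) and
medial–lateral (ML) — at 960 Hz. One *gait cycle* is the six-channel vector
`(L_AP, L_V, L_ML, R_AP, R_V, R_ML)`, zero outside each limb's stance,
zero-padded at the end to the longest cycle in the dataset. Forces stay in
raw newtons: in deployment nothing but the plates is measured, so
body-weight normalisation is impossible, and the mass dependence of the
signal is in fact part of the biometric (a "weak biometric" in its own
right). The covariate of interest is a 4.6 kg briefcase carried in one
self-chosen hand, which raises effective weight, loads the carrying side
asymmetrically and perturbs timing.

## Rank-based ensemble fusion

K base classifiers each emit posterior probabilities over the C enrolled
identities; posteriors are sorted (exact ties broken by ascending class
index) and truncated to a Top-T list. Fusion uses only these ordinal
rankings:

* **Position-wise accuracy.** On a labelled evaluation set, `Acc[j,p]` is
  the fraction of samples whose true class appears within the first `p`
  positions of classifier `j`'s list. We measure it on the 20 % validation
  split of the training data (see *Splits*), never on test labels.
* **Ranks and weights.** Per position, classifiers receive competition
  ranks (`1 + #{strictly better}`); equal accuracies are reordered by Top-1
  accuracy and residual ties share a rank. The quality weight is
  `w[j,p] = (K + 1 − R[j,p]) / K ∈ [1/K, 1]`.
* **Weighted vote by rank order.** Each classifier casts one vote for its
  Top-1 class with weight `w[j,1]`; the maximal summed weight wins.
* **Rank-based additive weighted Top-T vote.** Each classifier casts T
  votes; a vote at position `p` carries `λ·f_p + (1 − λ)·w[j,p]` with the
  position weight `f_p = (T + 1 − p)/T`. `λ` trades position information
  against classifier quality; values above 1 are legal and useful (the
  quality coefficient then goes negative — implemented literally, no
  clamping), and the λ grid is (0, 5] in steps of 0.1 (50 points), with the
  smallest maximiser reported.
* **Ties.** Scores within a 1e−12 relative tolerance count as tied. A tie
  is resolved by the Top-1 indication of the classifier(s) with maximal
  Top-1 validation accuracy: a unanimous indication inside the tied set
  wins, anything else yields `None` (no decision). `None` counts as an
  error in every accuracy we report; tie counts are reported alongside.

Correctness of both voting rules is checked against a brute-force scorer
that loops literally over the indicator "classifier j put class i at
position p", exhaustively for all ranking combinations in small worlds
(K ≤ 3, C ≤ 4, T ≤ 3).

## Base classifiers

Five 1-D deep architectures are provided as templates — plain CNN,
CNN-LSTM-FC, ResNet1D, ConvMixer1D and an InceptionTime-style network —
implemented on a small NumPy layer engine (im2col convolutions, depthwise
and pointwise convolutions, batch normalisation, LSTM with full BPTT, Adam,
categorical cross-entropy). Every layer's backward pass is verified against
central finite differences. Hyperparameters are bounded by per-architecture
search spaces (filter counts per block, kernel sizes, LSTM width/depth,
block counts, dropout ranges, batch sizes, learning rate in [1e−5, 1e−3]);
`random_search` draws configurations from one seeded stream so a larger
budget strictly extends a smaller one. Template defaults sit at the small
end of each space so CPU training is practical; sub-space "tiny" configs
are accepted outside strict validation for smoke testing.

`nearest_centroid` is the sixth backend: the mean training waveform per
identity, with posteriors proportional to inverse Euclidean distances. It
is fully deterministic and exists so the fusion layer can be exercised
without long training runs. It is deliberately naive: being a raw-distance
method it is sensitive to temporal misalignment, which is exactly the
weakness that motivates deep classifiers in this field (see *Limitations*).

### Splits

Training data are split 80/20 at trial level, stratified by subject, so
every identity stays in the fitting part. The fit early-stops on the 20 %
split (patience on validation loss, best weights restored), and the same
split feeds the ensemble's `Acc[j,p]` table. An ensemble harness imposes
one shared split on all members so the table is measured on common cycles.
Train/test separation is strict at trial level; augmentation touches
training inputs only.

## Augmentation

Four operators, all stance-aware and label-preserving:

* **Jitter** — white noise low-pass filtered (4th-order Butterworth, 30 Hz
  cutoff at 960 Hz), rescaled to unit RMS over the stance window, then
  added as `x′ = x + a·RMS(x)·s̃` with `a = 0.01` on vertical channels and
  `0.02` elsewhere. RMS(x) is computed over stance samples only (otherwise
  the perturbation would depend on padding length), and the unit-RMS
  rescaling keeps the effective perturbation at `a` relative RMS regardless
  of the filter's gain. Vertical channels are clipped at zero afterwards —
  a plate cannot pull the foot down; the clip touches only near-zero edge
  samples and moves the RMS ratio far less than the ±25 % contract band.
* **Time shift** — each leg's three channels move together by an integer
  draw from ±15 samples (±15.625 ms), independently per leg, zero-filled.
* **Window crop** — 1 to ⌊3 % of stance⌋ samples are removed from the left
  stance window (cut split uniformly between the two ends) and the segment
  is linearly resampled back to its original length; right leg untouched.
* **Same-class mixup** — `γ·x₁ + (1−γ)·x₂` with `γ ~ U(0.85, 0.95)`, both
  cycles from the same subject (and, in this package, the same condition).

The ×9 training expansion emits each original plus eight variants: the
three single operators, the three pairs, jitter+mixup, and
jitter+shift+crop, applied in listed order. A subject with a single cycle
degrades mixup to identity with a warning. Augmented copies get trial ids
`1000·combo + original` so dataset keys stay unique.

## Synthetic gait population

The generator stands in for a request-only laboratory dataset and copies
its population statistics: 215 subjects by default, body mass from
N(74.33, 16.63²) kg truncated to [45, 130] (truncation bounds rule out
non-physical draws), height N(174.41, 9.49²) cm, 14–20 trials per
condition, a 4.6 kg briefcase, carrying hand fixed per subject (50/50 by
default — the real split is unknown).

Each subject owns per-limb template parameters drawn once: vertical peak
amplitudes A1, A2 ~ U(1.05, 1.25) body weights at t1 ~ U(0.22, 0.28) and
t2 ~ U(0.72, 0.78) of stance, mid-stance valley U(0.70, 0.85) BW, AP
braking/propulsion lobes U(0.15, 0.25) BW, ML amplitude U(0.03, 0.10) BW,
stance duration U(0.60, 0.75) s, plus shape coefficients. The vertical
profile is a sum of Gaussian bumps (two peaks plus a mid-stance correction
fixing the valley) tapered smoothly to zero at the stance edges — the
canonical M-shape; AP is a braking lobe followed by a propulsion lobe (the
S-shape); ML is a small multi-bump profile. Since peak force is amplitude ×
body weight, vertical peaks correlate strongly with mass across subjects
(Spearman ρ > 0.9 at the default noise), which is what makes mass-gap
confusion analysis meaningful.

Trial-to-trial noise: multiplicative amplitude jitter (σ = 0.02), peak
timing jitter (σ = 0.01 of stance) and stance-duration jitter (σ = 0.03 s).
With all three at zero, trials are bit-identical.

Layout and impulse balance: the left stance opens the recording; the right
stance starts near the cycle midpoint. The cycle length is set from the
impulse balance — summed vertical impulse equals effective weight × cycle
duration (within 10 %; exact up to rounding by construction) — because a
walker must support their own weight on average. Subjects with a lower
mean stance force get a proportionally longer double-support overlap.
Loading adds the briefcase mass to the effective weight, inflates
carrying-side vertical amplitudes by δ_carry = 6 % versus δ_contra = 2 %
contralaterally, multiplies carrying-side ML by 1.3 and lengthens stance by
3 %. These magnitudes are configurable model choices; only their ordering
(carry > contralateral ≥ 0) is asserted, matching the asymmetry direction
reported for unilateral load carriage.

Seeding: one master seed; per-cycle seeds derive from
`SeedSequence((master, subject_index, condition, trial))`, so studies are
bit-reproducible and any single cycle can be regenerated alone.

### What the generator does *not* emulate

Footwear, walking-speed and fatigue covariates; inter-trial correlation
drift; sensor quantisation and crosstalk; genuine biomechanical coupling
between limbs (each limb's template is drawn independently); and the real
dataset's accuracy levels. Passing tests therefore demonstrate that the
pipeline's *mechanics and directional behaviour* are right — covariate
degradation, augmentation recovery, mass-ordered confusions — not that any
particular accuracy transfers to real force-plate data.

## Evaluation protocols

* **Scenario A** (reference): train and test on unloaded cycles, 10-fold
  cross-validation partitioning trials *within* each subject, so every
  subject appears in every training fold (closed-set requirement); mean ±
  sd over folds.
* **Scenario B** (realistic): train on all unloaded, test on all loaded.
* **Scenario C**: B with the ×9 expansion applied to the 80 % fitting split
  only; validation and test cycles stay original.

Reports carry per-classifier Top-1/Top-5, both fusion accuracies, the λ
curve and its optimum, tie counts, optional leave-one-out ablation rows
(ranks, weights and λ re-derived for each K−1 subset) and the body-mass
confusion analysis: |mass(true) − mass(predicted)| over misclassified
samples, a 1 kg histogram and the ECDF at 4.6 kg and 11 kg (configurable);
a run without errors reports an empty histogram and an undefined ECDF.

## Problem sizes and numerical choices

The end-to-end checks and `scripts/acceptance.py` use 30 subjects × 15
trials per condition with a two-member harness — the nearest-centroid
backend plus one small CNN (two conv blocks, 16/32 filters, time axis
decimated ×16) — sizes chosen so a full A/B/C pass with the λ sweep and
ablation completes in a few minutes on one CPU core while preserving every
structural property of the full-scale protocol. The ensemble accuracy of a
report is read as the better of the two voting strategies. Score ties use
a 1e−12 relative tolerance; posterior-rank ties break by ascending class
index; stance detection takes the envelope of supra-threshold samples
(default threshold 10 N — well above sensor noise, far below body weight)
so brief interior dips do not split a stance.

## Known limitations

* With K = 2 the Top-T additive vote is weak by construction: at λ → 0 the
  quality weight is constant across positions, so a classifier's T votes
  tie, and λ ≥ 1 mixes the weaker member in; the rank-order vote, which
  tracks the validation-best member, is the stronger strategy at that K.
  The additive vote comes into its own with larger, quality-homogeneous
  ensembles.
* The nearest-centroid backend degrades sharply under the load covariate
  (raw Euclidean distance is misalignment-sensitive), while the CNN holds
  up and recovers fully with augmentation. That gap is a faithful
  reproduction of why this field uses deep classifiers, but it means
  centroid-only harnesses understate attainable accuracy.
* The NumPy engine is single-threaded float64; paper-scale widths (1024
  filters, 215 classes, N = 1471) train, but slowly. The templates exist
  for structural fidelity and search-space validation, not for speed.
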