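# Methods

## Problem and model

`lesionfuse` implements a multi-task framework for classifying a binary
per-study outcome (an "AF-like" vs "non-AF-like" label attached to each
scan) from a 3-D intensity volume containing one or more lesions. The
design couples three sources of evidence:

1. **Segmentation branch.** A 3-level 3D U-Net (encoder channels
   16/32/64 by default, mirrored decoder with skip connections)
   predicts a voxel-wise lesion probability map, trained with Dice
   loss, `L_seg = 1 − (2Σpm + ε)/(Σp + Σm + ε)`, ε = 1e-6.
2. **Prior-attention-guided classification branch.** A 3D CNN whose
   convolutions mirror the U-Net's subsampling scales. At each scale
   the classification activation is multiplied by `(1 + a_s)` where
   `a_s = σ(channel-mean of the U-Net's post-pooling encoder
   activation)` lies in [0, 1]. The modulation is residual
   (multiplicative with a +1 floor) so attention can emphasise lesion
   regions without zeroing gradients; a zero activation yields a
   uniform 0.5 attention. The branch global-average-pools into a
   64-d semantic vector.
3. **Attention-weighted radiomics.** A fixed 32-feature vector is
   extracted from the lesion ROI (six families, below). A learnable
   linear scorer produces per-study softmax weights on the feature
   simplex; the weighted features (rescaled by the feature count to
   keep magnitudes trainable) feed the radiomics head, and the weights
   themselves are the feature-significance read-out.

Three softmax heads emit two-class probabilities: radiomics-only,
CNN-only, and a combined MLP on [semantic ‖ weighted radiomics]
(hidden width 64). Final head layers are zero-initialized, so an
untrained model outputs (0.5, 0.5) from every head — a useful
symmetric-initialization contract for tests.

**Two-stage training.** Stage 1 minimizes `DiceLoss + L_cnn` over the
segmentation branch, classification trunk and CNN head. Stage 2
freezes those extractors (semantic vectors are cached) and minimizes
`L_rad + L_com` over the radiomics attention, radiomics head and
fusion MLP. Each stage keeps the parameter snapshot with the minimum
validation loss seen during that stage; the fold's final model is the
best stage-1 extractor state combined with the best stage-2 head
state. Selecting a single global minimum across both stages is not
meaningful because the two stage losses are on different scales and an
early stage-1 optimum would carry untrained heads.

**Optimization.** Adam (β = 0.9/0.999), batch size 8, exponentially
decayed learning rate `lr(t) = lr0 · 0.98^t` per epoch with
lr0 = 1e-4 over 50 epochs (25 per stage) in the canonical profile.
Augmentation applies random axis flips and in-plane 90° rotations to
volume and mask jointly; the identity transform has positive
probability and augmentation never runs at inference.

**Cross-validation and ensembling.** Patients are partitioned
uniformly at random into five folds (sizes differing by at most one,
reproducible from a seed). Per-fold feature standardization statistics
are computed on the training split only. Pooled out-of-fold scores
(each study scored by the one model that never saw it) give the
headline metrics; for external cohorts the five fold models'
probabilities are arithmetically averaged.

## Radiomics features

All texture families use 26-connectivity, distance-1 neighbourhoods,
and equal-width discretization of ROI intensities into `n_levels`
(default 32) bins; the top bin is right-closed. Conventions that the
standard definitions leave open, fixed here and enforced by tests
against brute-force enumeration oracles:

- **GLCM**: the 13 unique 3-D directions, counted symmetrically,
  normalized per direction and averaged (directions with no in-ROI
  pair are skipped). Correlation of a constant ROI is defined as 1.
- **GLDM**: dependence = number of 26-neighbours within
  `|Δlevel| ≤ α` (α = 0 default); emphasis features use the
  dependence *size* = count + 1 so isolated voxels stay defined.
- **GLSZM**: zones are 26-connected equal-level components.
- **NGTDM**: `s_i = Σ |i − mean(in-ROI neighbours)|` over voxels with
  at least one in-ROI neighbour. Coarseness of a constant ROI returns
  the conventional large constant 1e6; contrast/busyness/strength fall
  back to 0 on degenerate denominators.
- **First order**: entropy over the same equal-width binning; kurtosis
  is the Fisher (excess) form; constant ROIs yield 0 for skewness,
  kurtosis and entropy.
- **Shape**: surface area by exposed-face counting; sphericity
  `π^{1/3}(6V)^{2/3}/A`; elongation and flatness are anisotropy ratios
  `sqrt(λ_major/λ_minor) ≥ 1` from the mask's second moments, with each
  voxel contributing its own cube inertia (spacing²/12) so thin
  structures remain finite and a single voxel scores exactly 1;
  maximum 3-D diameter by pairwise voxel-centre distances.

Feature standardization is fold-aware (z-scores fitted on training
folds) to prevent leakage into validation metrics.

## Evaluation

AUC is the Mann–Whitney statistic (ties counted ½). Confidence
intervals are stratified-bootstrap percentile intervals (2000
resamples by default, within-class resampling so every replicate keeps
both classes, fully seeded). The operating point maximizes
sensitivity + specificity over midpoints of adjacent distinct scores,
ties broken toward higher specificity; sensitivity, specificity,
accuracy, PPV and NPV are reported as percentages with explicit
"undefined" markers on zero denominators. Fold summaries are
mean ± sample SD; subgroup reports stratify by sex, age ≤70/>70,
NIHSS ≤4/>4 and CHA2DS2-VASc ≤3/>3, marking single-class strata
not-evaluable. The cutoff is chosen on the evaluated set itself (the
reporting convention the per-fold tables use); a fold-internal-cutoff
mode is available separately via per-fold reports.

## Interpretability

Grad-CAM: channel weights are global averages of `∂(class logit)/∂A`
at the last convolution of the classification branch; the map is
`ReLU(Σ w_c A_c)`, trilinearly upsampled and min–max normalized, with
all-zero maps flagged degenerate rather than renormalized. That last
convolution sits just before the final pooling, which doubles the
saliency grid resolution relative to placing it after. Feature
significance (FSR) is defined as the cohort mean of the per-study
attention weights, overall and per predicted class (true-label views
optional); held-out studies are ranked by each fold's own model.

## Synthetic phantom cohorts

The generator emulates the study conditions at desk scale: volumes
with a dark noise background (σ = 4 intensity units) containing 1–2
ellipsoidal lesions (radius 3–5 voxels) of base intensity 60, with a
per-study multiplicative intensity jitter in [0.8, 1.2]. Class 1
lesions carry a voxel-wise alternating high/low texture (checkerboard,
amplitude 40) and an elongation factor 1.8; class 0 lesions carry
low-pass-filtered noise (Gaussian σ = 1.5, amplitude ~8) and are
spherical. This makes NGTDM-family contrast (plus shape anisotropy)
the designed discriminating statistics, so recovery by the network's
feature ranking is a meaningful check. Metadata (sex, age ~71.6 ± 12,
NIHSS, CHA2DS2-VASc) are sampled independently of the label by
default, with an optional label shift to exercise enriched subgroup
regimes. All randomness is spawned from one master seed; cohorts are
pure functions of (params, n, seed).

What the phantoms do *not* emulate: anatomy (no atlas or DWI physics),
inter-site intensity distributions, segmentation noise (masks are
exact), or realistic class overlap — the default cohort is strongly
separable. Passing the end-to-end tests therefore demonstrates that
the machinery recovers a known signal, not that clinical-level
discrimination is attainable.

## Desk-scale profile and numerical choices

`RunConfig.desk_scale()` is the single-CPU profile used by the
end-to-end tests and the acceptance script: 16×32×32 phantoms fed
directly as network input, channels (4, 8, 16), 8 epochs split 6/2,
lr0 = 1e-2, 500 bootstrap resamples. The raised learning rate
compensates for having ~30 optimizer steps instead of the canonical
~2500; with lr0 = 1e-4 the parameters could move by at most ~3e-3
over the whole short schedule, which cannot train from random
initialization. Two related choices stabilize this short regime: the
classification trunk uses leaky ReLU (slope 0.05), because at lr 1e-2
plain ReLU units died after the first epoch and froze the CNN head at
chance; and the segmentation head's bias starts at −3 to match the low
(~2–5%) lesion-voxel prevalence, which markedly accelerates Dice
convergence. The canonical profile (32×64×64 input via the
pad-to-[32,256,256]-then-4×-downsample path, channels 16/32/64,
50 epochs at lr0 1e-4) remains the package default.

Other numerical conventions: cross-entropy probabilities are floored
at 1e-12; sigmoid inputs are clamped at ±60; constant-volume intensity
rescaling returns all zeros with a warning; the low-resolution mask
uses majority vote with ties counted as foreground; padding is centred
and recorded so it is exactly invertible.

## Known limitations

- The in-repo autodiff/conv backend is sized for these small networks;
  it is single-threaded NumPy and not suitable for clinical-resolution
  training.
- Channel count of multi-channel inputs is a free knob (default 1);
  no cross-channel radiomics are defined (features use channel 0).
- The bootstrap CI is percentile-based; no analytic (DeLong) CI, no
  calibration or decision-curve analysis.
- Checkpoint selection inside each stage assumes the stage losses are
  comparable across its epochs; no early stopping is implemented.
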