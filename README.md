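# lesionfuse

Segmentation-guided 3-D lesion classification with attention-weighted
radiomics fusion.

`lesionfuse` is for researchers who want to predict a per-study binary
outcome (the motivating case: underlying atrial fibrillation from the
ischemic lesion seen on diffusion-weighted brain MRI) from a 3-D
volume plus a lesion mask, and to understand *why* the model decides
what it does. Because clinical cohorts of this kind are private, the
package ships a synthetic phantom generator whose two classes differ
in lesion texture and shape, so the whole pipeline is testable and
reproducible end to end on a laptop CPU.

## The model

Two branches share one input volume `x` (channel-first, canonically
32×64×64):

- a 3-level **3D U-Net** predicts the lesion map, trained with Dice
  loss `L_seg = 1 − (2Σpm+ε)/(Σp+Σm+ε)`;
- a mirrored **3D CNN** classification branch whose activation at each
  scale *s* is modulated by prior attention from the U-Net's
  subsampling layers: `q_s ← q_s · (1 + σ(mean_c e_s))`;
- radiomics features `z` (32 features: first-order, shape, GLCM, GLDM,
  GLSZM, NGTDM, computed inside the mask) are re-weighted by a
  self-attention module, `w = softmax(Wz + b)`, `z̃ = d·(w ⊙ z)`.

Three softmax heads — radiomics-only, CNN-only, and a combined MLP on
`[h ‖ z̃]` where `h` is the CNN's pooled semantic vector — give
two-class probabilities. Training is two-staged (stage 1:
`L_seg-Dice + L_cnn`; stage 2: `L_rad + L_com` with extractors frozen)
with Adam, batch size 8, and learning rate `lr(t) = lr₀·0.98^t`
(lr₀ = 1e-4, 50 epochs canonically). Evaluation uses fivefold
patient-level cross-validation with min-validation-loss checkpoints,
pooled out-of-fold scores, Youden operating points, stratified
bootstrap 95% CIs, and cross-fold prediction averaging for external
cohorts. Interpretation comes from 3-D Grad-CAM on the classification
branch and the feature-significance ranking (FSR) given by the cohort
mean of the attention weights.

Everything — including the 3-D convolutions and backpropagation — runs
on a small in-repo NumPy autodiff core (`lesionfuse.nn`); there is no
GPU or deep-learning-framework dependency.

## Worked example

```python
from lesionfuse import LesionFusionModel, PhantomParams, RunConfig

config = RunConfig.desk_scale(seed=7)          # reduced single-CPU profile
params = PhantomParams(grid_shape=config.input_shape, seed=7)
model = LesionFusionModel.from_phantoms(params, n_per_class=16, seed=7,
                                        config=config)
results = model.fit()                          # fivefold, two stages (~1 min)
print(results.summary())
```

```
          Lesion fusion classifier — fivefold cross-validation
========================================================================
studies: 32   pos: 16   neg: 16   folds: 5   seed: 7
config hash: 064aa0e48a9a7c3c
------------------------------------------------------------------------
head          AUC           95% CI   sens%   spec%    acc%   PPV%   NPV%
radiomics   1.000     [1.00, 1.00]   100.0   100.0   100.0  100.0  100.0
cnn         0.891     [0.76, 0.98]    68.8   100.0    84.4  100.0   76.2
combined    1.000     [1.00, 1.00]   100.0   100.0   100.0  100.0  100.0
------------------------------------------------------------------------
fold mean ± SD (per-fold cutoffs):
radiomics AUC 1.000 ± 0.000   acc 100.0 ±  0.0
cnn       AUC 1.000 ± 0.000   acc 100.0 ±  0.0
combined  AUC 1.000 ± 0.000   acc 100.0 ±  0.0
========================================================================
```

Each row is one classifier head evaluated on pooled out-of-fold
scores: AUC with a stratified-bootstrap 95% CI, then sensitivity,
specificity, accuracy, PPV and NPV at the operating point that
maximizes sensitivity + specificity. On this deliberately separable
phantom cohort the radiomics and combined heads are perfect and the
CNN-only head is weaker — the expected ordering, since the phantom
classes are defined by ROI texture statistics that the radiomics
features capture directly. `results.grad_cam(i)` returns a saliency
map for study *i* from the fold model that held it out, and
`results.fsr()` ranks features by average attention weight:

```
top-5 features by average significance:
  firstorder_range                   0.0442
  firstorder_kurtosis                0.0372
  glcm_idm                           0.0355
  gldm_small_dependence_emphasis     0.0351
  glcm_correlation                   0.0350
```

The same workflow is scriptable from the shell:

```bash
lesionfuse simulate -n 32 -s 1 -o cohort/ --grid 16 32 32
lesionfuse radiomics -m cohort/manifest.csv -o features.csv
lesionfuse train -m cohort/manifest.csv --desk-scale -o run/
lesionfuse evaluate -s run/scores.csv -o report.json
lesionfuse interpret -r run/ -m cohort/manifest.csv -o fsr/
```

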