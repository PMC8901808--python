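# slnrad

Preoperative prediction of sentinel-lymph-node (SLN) metastasis in breast
cancer from dynamic contrast-enhanced (DCE) MRI, as a tested, reusable
pipeline.  The package implements two competing feature arms over the same
downstream protocol — conventional radiomics (CR) and deep-learning-based
(DLB) features from a frozen convolutional network — and exercises them on
synthetic two-resolution phantom cohorts with planted, recoverable class
signal, standing in for private patient data.

**Who it is for:** quantitative-imaging researchers who want a transparent,
oracle-tested reference implementation of a kinetic-map radiomics pipeline
(texture matrices, peritumoral rings, ADASYN, LASSO model selection,
Youden thresholding) and a phantom generator to validate it end to end.

## The method

Each subject carries five co-registered DCE phases S₀…S₄ (one pre-contrast,
four post-contrast).  Three scanner-independent kinetic ratio maps are
computed voxelwise:

    wash-in  = (S₁ − S₀)/S₀ × 100 %
    wash-out = (S₁ − S₄)/S₁ × 100 %
    SER      = (S₁ − S₀)/(S₄ − S₀) × 100 %    (signal enhancement ratio)

Two regions are analyzed: the intratumoral ROI and a 0–4 mm peritumoral
shell built by in-plane dilation.  Tumors under 64 voxels are excluded.

**CR arm.** Each map/region pair is absolutely resampled into a fixed
physical window (e.g. intratumoral wash-out −156…100 %) and quantized to
128 grey levels; shape, first-order, GLCM, NGLDM, GLRLM, GLZLM and Laws
filter-bank features are extracted (intratumoral 93, plus peritumoral for
146 total).

**DLB arm.** Masked, window-normalized maps are rendered as 224×224×3
slices (channels wash-in / wash-out / SER, scaled 0–255) and pushed through
a frozen CNN; the last fully connected layer's 1000 activations are
averaged over slices per subject.

**Shared downstream protocol.** Features are z-scored with training-set
statistics; the training split is rebalanced with ADASYN; features are
filtered by Mann-Whitney p, decorrelated at a Spearman |ρ| threshold, and
optionally PCA-projected (hyperparameters grid-searched by mean validation
accuracy).  The reduced features plus 11 clinical covariates enter
L1-penalized (LASSO) logistic selection with 3-fold CV under the
one-standard-deviation rule, capped at 10 features; the selected features
get an unpenalized logistic model whose decision threshold maximizes the
Youden index (YI = sensitivity + specificity − 1) on training scores.  The
whole cycle repeats over many seeds and the seed with the best training
accuracy wins; its frozen threshold is applied to the validation split
(same 0.7 mm resolution) and an independent 0.78 mm test split.

## Worked example

```python
from slnrad import (PhantomConfig, generate_cohort, SLNPredictionModel,
                    ModelConfig)

config = PhantomConfig(seed=42)          # 109 train / 54 validation / 35 test
studies, manifest = generate_cohort(config)
model = SLNPredictionModel.from_cohort(studies, config, arm="CR",
                                       config=ModelConfig(n_seeds=10))
results = model.fit(seed=0)
print(results.summary())
```

prints

```
SLN metastasis prediction — repeated-seed LASSO/logistic pipeline
====================================================================
arm: CR    winning seed: 1 of 10
reduction: p<0.05, |rho|<0.95, PCA=none
decision threshold (Youden, training): 0.5063

selected features and logistic coefficients:
  (intercept)                                         -1.9895
  CR:intratumoral:wash_out:glcm_contrast              +1.3951
  CR:intratumoral:wash_out:glcm_correlation           +0.3534
  CR:intratumoral:wash_out:ngldm_busyness             -1.6897
  CR:intratumoral:wash_out:laws_skewness_7            -1.9740
  CR:intratumoral:ser:first_order_energy              -0.7124
  CR:peritumoral:wash_out:first_order_kurtosis        -0.7508
  CR:peritumoral:wash_out:first_order_energy          -1.3261
  CR:peritumoral:wash_out:ngldm_busyness              +1.9192
  clinical:tumor_grade                                +1.6384
  clinical:lymphovascular_invasion                    +2.5428

performance (rows: splits):
              auc  sensitivity  specificity    ppv    npv  accuracy     yi
training    0.983        0.943        0.946  0.892  0.972     0.945  0.889
validation  0.931        0.842        0.829  0.727  0.906     0.833  0.671
testing     0.776        0.643        0.810  0.692  0.773     0.743  0.452
```

The phantom generator plants the class signal through a higher wash-out
fraction and more heterogeneous enhancement texture in positive tumors and
through two clinical covariates — and the fitted model recovers exactly
those mechanisms: wash-out texture features, tumor grade and
lymphovascular invasion.  The drop from validation (same resolution as
training) to the 0.78 mm test split illustrates the resolution-sensitivity
question the two feature arms are compared on.

The command line mirrors the library:

```sh
slnrad run-all --arm both --seed 7 --output-dir out/
slnrad simulate --seed 7 --output-dir out/      # cohort roster only
```

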