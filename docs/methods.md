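# Methods

This note records the scientific and numerical choices behind `slnrad`:
what is modelled, which conventions were pinned where the problem left them
open, and what the synthetic cohorts can and cannot demonstrate.

## Kinetic maps

The three ratio maps use only S₀ (pre-contrast), S₁ (first post-contrast)
and S₄ (last post-contrast): wash-in = 100·(S₁−S₀)/S₀, wash-out =
100·(S₁−S₄)/S₁, SER = 100·(S₁−S₀)/(S₄−S₀).  Voxels with a zero denominator
are marked invalid (NaN) and excluded from every downstream region
statistic rather than imputed — imputation would manufacture extreme
percent values precisely at pathological voxels.  On valid voxels the maps
satisfy the algebraic identity SER·(S₄−S₀) = wash-in·S₀ = 100·(S₁−S₀),
which the tests assert to 1e−9 relative tolerance.

Absolute resampling windows (percent) are fixed physical windows, not
per-image ranges: intratumoral wash-in 0…640, wash-out −156…100, SER
−1280…1280; peritumoral identical except wash-out −540…100.  Quantization
to 128 grey levels uses left-closed equal-width bins,
`level(v) = min(L−1, floor((v−lo)/(hi−lo)·L))`, with the last bin closed —
the common absolute-resampling convention; it is monotone and idempotent
after clipping.  Maps stay at native resolution: the 0.78 mm test cohort is
deliberately *not* resampled onto the training grid, because resolution
sensitivity is the scientific question.

## Regions

The peritumoral region is the 0–4 mm shell around the tumor.  Dilation is
2D in-plane per slice by default: with 2 mm slices a 4 mm 3D dilation would
add exactly two whole slices anisotropically, whereas the in-plane pitch
(0.7/0.78 mm) resolves the millimetre intent; a 3D mode exists as a switch.
Distance semantics are voxel-center Euclidean distance ≤ threshold
(`scipy.ndimage.distance_transform_edt`), verified against a brute-force
per-pixel scan.  The fixed 224×224 crop for the CNN is centered on the
intratumoral centroid rounded to the nearest pixel (ties toward the lower
index), constant across a subject's slices, zero-padded at volume borders.
Tumors below 64 voxels are excluded.

## Conventional radiomics

Texture is computed in 3D: GLCM and GLRLM aggregate the 13 unique
3D directions at distance 1 (GLCM distance is fixed at 1 voxel), NGLDM uses
26-connected neighborhoods, GLZLM zones are 26-connected equal-level
components.  Inside matrix statistics grey levels are weighted 1-based so
low-grey-level emphases stay finite.  NGLDM coarseness is guarded by
ε = 1e−6 so constant regions return 1/ε instead of diverging.  Every matrix
equals an exhaustive brute-force construction on random ≤6³ ROIs (50 per
family in the acceptance suite).

Laws features are 2D per slice: the 25 outer products of L5 = [1,4,6,4,1],
E5 = [−1,−2,0,2,1], S5 = [−1,0,2,0,−1], W5 = [−1,2,0,−2,1],
R5 = [1,−4,6,−4,1], numbered 1…25 row-major in that kernel order (the
numbering in published feature names like "Energy_8" reflects an unstated
ordering; row-major is this package's pinned convention).  Filters are
applied to the windowed, unquantized percent map, same-size with zero
padding; responses at in-ROI pixels are pooled across a subject's slices
before taking Energy (mean square) and Skewness, which weights slices by
their ROI area.

The default catalog is pinned to the published model-input counts — 93
intratumoral features and 146 with the peritumoral region — because the
published per-region arithmetic ("105 features") cannot be reconciled
without the study's unavailable supplement.  Composition: 5 shape (intratumoral only) + per
map 24 matrix/first-order statistics per region for the intratumoral side,
15 for the peritumoral side (no GLRLM/GLZLM there), plus pinned Laws
filter subsets (8 map/filter combos intratumorally, 4 peritumorally, each
contributing Energy and Skewness).  The catalog is configurable; every
feature named in the published selected-feature tables is representable.

## DLB features

Preprocessing follows the masking-before-normalization order: mask to the
ROI (outside set to 0), clip to the same absolute windows as CR, map
affinely to [0,1], multiply by 255.  Consequently the zeroed background is
*nonzero* after mapping for windows with a negative lower bound (wash-out,
SER) — kept deliberately, as the faithful reading of that order.  No
channel-mean subtraction is applied by default (the 0–255 values go in
directly); a canonical-preprocessing switch is available.

The backbone is frozen (never updated) behind a single forward-pass
contract with the tap at the last fully connected layer, pre-softmax,
width 1000.  Two architectures are provided, both as plain numpy forward
passes: a 16-layer VGG configuration that can load user-supplied weights
from an `.npz` archive, and a small strided CNN with He-scaled seeded
random weights.  The random-weight backbone is the default for synthetic
cohorts: frozen random projections preserve enough class signal to
exercise and validate the full pipeline, and make every test independent
of downloaded weights.  Per-subject vectors are the element-wise mean of
the per-slice activations (order-invariant).

## Reduction and modeling

Order is fixed: z-score → ADASYN → Mann-Whitney filter → Spearman prune →
optional PCA.  All statistics are fitted on the training split only and
reused verbatim on validation/test (asserted by provenance flags);
only the training split is ever rebalanced.  The z-score uses the n−1 SD
convention; zero-variance training columns are dropped everywhere with a
warning (constant synthetic features are plausible, so this is not an
error).  ADASYN uses k = 5 neighbors and β = 1 (full balance): the budget
(N_maj−N_min)·β is allocated across minority samples proportionally to
their majority-neighbor fraction, and each synthetic point interpolates
toward a minority-class neighbor.  Mann-Whitney p-values are exact when
both groups have <8 tie-free samples, otherwise normal-approximated with
tie correction.  The Mann-Whitney and Spearman steps run on the rebalanced
training table by default (the reduction is described after rebalancing),
with a switch to use the originals.  Correlated groups keep the member
with the smallest Mann-Whitney p (greedy, ascending p).  Reduction applies
to image features only; the 11-number clinical block (5 scalar fields +
one-hot molecular subtype (4) and pathological type (2)) is appended
unreduced.  Hyperparameters are restricted to the study grids — p ∈
{0.001, 0.005, 0.01, 0.05}, ρ ∈ {0.75…0.95}, PCA ∈ {none, 20…100} — and
grid-searched by mean validation accuracy over repeated modeling seeds.

LASSO selection is an L1-penalized binomial-deviance path (the outcome is
binary) over 100 log-spaced λ from λ_max (smallest λ zeroing all
coefficients) down to 10⁻⁴ λ_max, with 3-fold stratified CV whose fold
assignment reshuffles per seed.  The "minimum CV error plus one standard
deviation" rule is read as the one-standard-error rule with the SD taken
across the three folds' errors at the minimizing λ; if the chosen λ's
active set exceeds 10 features, larger λ are used until it does not.  The
selected features get an unpenalized maximum-likelihood logistic fit.  The
decision threshold maximizes the Youden index over the midpoints of
adjacent sorted unique training scores (ties → lowest threshold;
prediction is positive at score ≥ threshold).  The seed protocol repeats
selection/fit/threshold for seeds 1…n_seeds and keeps the seed with the
highest training accuracy — computed on the rebalanced training table by
default (the description is ambiguous between original and rebalanced; a
switch selects the original) — with ties to the lowest seed.  An empty
selection degrades to the intercept-only, all-negative classifier rather
than aborting, so null cohorts run end to end.  A split containing a
single class reports NaN metrics with a warning instead of aborting the
protocol; `evaluate` itself still refuses single-class labels.

Reported per-split metrics are AUC (trapezoidal ROC), sensitivity,
specificity, PPV, NPV, accuracy and YI at the frozen training threshold;
training metrics are reported on the original (unbalanced) training rows.

## Synthetic cohorts

The generator emulates the study conditions: 109 + 54 subjects at 0.7 mm
in-plane / 2 mm slices, 35 independent test subjects at 0.78 mm, positive
fraction 0.34, 5-phase series, ellipsoidal tumors (radii jittered in
4.5–6.5 mm in-plane, 2.4–3.6 mm axially on a 56×56×10 grid), and a
piecewise-linear enhancement curve: S₀ = b, rapid rise to S₁ = b(1+a),
linear wash-out to S₄ = S₁(1−w) — the simplest curve matching the three
ratio maps' semantics.  Uptake is modulated inside the tumor by a smoothed
Gaussian texture field so texture features are non-degenerate.  Noise is
additive Gaussian with SD 3 % of baseline; Rician noise is omitted as
negligible at typical DCE SNR.

Class signal is planted through: wash-out fraction (standardized mean
difference 1.2, i.e. w ~ N(0.18 + 1.2·0.08·y, 0.08)); texture
heterogeneity (SMD 1.0); lymphovascular invasion (log-odds shift +2.2 over
a 15 % base rate, giving ≈61 % prevalence in positives); tumor grade
(latent-normal shift +0.9).  These magnitudes were chosen once as effect
sizes a radiomics study of this size could plausibly detect — a single
mechanism at SMD 1.2 corresponds to a standalone AUC of ≈0.80 — and yield
pipeline-level validation AUC near the published 0.87.  Setting all
effects to zero produces exchangeable-label null cohorts.

What the phantoms do **not** emulate: irregular tumor boundaries, Rician
noise, motion/registration error, B₁ inhomogeneity, real clinical-covariate
correlation structure, or the biology linking peritumoral tissue to nodal
spread.  Passing tests therefore demonstrate that the pipeline recovers
signal it is told exists and manufactures none where there is none — not
that the published patient-level AUCs are correct.

## Problem sizes in the test and acceptance runs

Parameter recovery runs 20 protocol replicates at 25 LASSO seeds each
(scaled from the study's 100 seeds) on one default cohort; the acceptance
script uses 10 replicates.  The null control uses 10 (script: 5)
independent small null cohorts (40/20/8) × 2 protocol replicates, so the
standard error reflects cohort-to-cohort variation.  Oracle checks use 50
random ≤6³ ROIs per texture family.  These sizes keep a full run in the
minutes range on a single CPU while leaving the statistical assertions
comfortably powered.

## Known limitations

* The DLB arm's default random-weight backbone validates plumbing and
  signal flow, not transfer-learning quality; canonical pretrained weights
  must be supplied externally to reproduce a true VGG-16 feature space.
* The published training-set metric rows are not jointly consistent with
  any confusion matrix at n=109/37+ (they evidently reflect the rebalanced
  training set), so only their sensitivity/specificity/YI arithmetic is
  checkable.
* The grid search optimizes validation accuracy and the final seed is
  chosen by training accuracy, faithfully to the protocol; neither is a
  nested, unbiased model-selection scheme, and the reported validation
  metrics inherit that optimism.
* Real-mode ingestion covers NIfTI volumes with header spacing; DICOM
  series and registration are out of scope.
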