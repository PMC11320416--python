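# Methods

## The model

The package classifies multi-modal 3D brain MRI cases (binary tasks such as
glioma vs. brain metastasis, or predicting hemorrhagic transformation after
stroke thrombolysis) from deep features that are *gated* by a predicted
lesion-probability map and *fused* across encoder scales.

**Segmentation backbone.** For each modality an independent encoder–decoder
is trained on expert lesion masks only — the case-level diagnosis is never
visible to this stage (the training API accepts records with the class label
stripped, and the loop reads only the image and the mask). The encoder is a
3D ResNet-50-style stack: a 7×7×7 stride-2 stem with 3×3×3 stride-2 max
pooling, then four bottleneck stages of 3/4/6/3 blocks with 256/512/1024/2048
output channels. Stage 2 strides once more; stages 3 and 4 keep their grid
and instead dilate their 3×3×3 convolutions (rates 2 and 4). On a
155×280×280 volume the grids are therefore 39×70×70 (stage 1) and 20×35×35
(stages 2–4); a vanilla stride pattern would shrink the final grid to
5×9×9 and could not reproduce these sizes. The decoder is minimal — trilinear
upsampling of the final stage back to the stage-1 grid and a 1×1×1 projection
to two channels with a voxelwise softmax — so representational capacity
concentrates in the encoder, whose weights are reused for feature extraction.

**Mask-attention gating and multi-scale fusion.** At extraction time the
decoder's lesion-channel probability map is resampled (trilinear, clamped to
[0, 1]) onto the grid of each selected encoder stage and multiplied
elementwise into that stage's feature maps, broadcast over channels. Gated
maps from stages 2–4 are reduced per channel by global average *and* global
max pooling and concatenated in (stage, pooling) order:

    F = concat_i [ pool( D(E_N(x)) ∘ E_i(x) ) ],   i = 2, 3, 4

giving (512 + 1024 + 2048) × 2 = 7 168 dimensions per case per modality at
full width. Summation across stages in place of concatenation is
dimensionally impossible (unequal channel counts), so concatenation is the
implemented reading. Four extraction variants reproduce the ablation
structure: `plain` (last stage, ungated), `mask` (last stage, gated),
`multiscale` (stages 2–4, ungated), `m3` (stages 2–4, gated).

**Classification.** Feature columns are z-scored (average- and max-pool
blocks live on different scales), reduced by PCA to the smallest component
count reaching 95 % cumulative explained variance (capped at n−1), and
classified by an RBF-kernel SVM (C = 1, kernel width 1/(d·Var), balanced
class weights); random-forest (500 trees), gradient-boosting (200 rounds,
learning rate 0.1) and MLP (hidden widths 64/16) backends are available.
Multi-modality fusion concatenates per-modality feature vectors before
reduction (default) or averages per-modality classifier scores.

**Evaluation.** Stratified 5-fold cross-validation with AUC (tie-aware rank
statistic), F1 for the positive class and accuracy, reported fold-wise as
mean ± std. The reducer and classifier are always refit inside the training
fold, so no held-out information enters fitting. Variant differences are
assessed with a paired permutation test that randomly swaps, per case, which
variant a held-out score is attributed to (10 000 permutations by default);
this test is this package's choice of significance procedure.

## Numerical implementation

The network runs on a small numpy layer library written for this package
(`m3.nn`): convolution as one GEMM per kernel offset (with an im2col path,
chunked over output depth, for the single-channel stem — a stride-2 gather
has no contiguous runs, so the stem first splits the padded volume into its
eight stride-2 parity sub-volumes, after which every kernel-offset slice is
unit-stride), instance normalization, ceil-mode max pooling, separable
trilinear resizing, and softmax cross-entropy / soft-Dice losses, all with
analytic backward passes that the test suite checks against central finite
differences. Optimization is Adam (lr 1e-3 by default; the experiment
harness uses 3e-3 for the small nets it trains). Upsample-then-project and
project-then-upsample are mathematically identical for a linear resize
followed by a 1×1×1 projection; the implementation projects first to avoid
materializing a full-resolution copy of the 2048-channel map.

Normalization is per-channel batch normalization with running statistics,
as in the reference backbone. This choice is load-bearing for
classification, not a detail: at inference batch norm is a *fixed affine
map*, so the absolute intensity scale of a volume survives into the pooled
features. A per-sample alternative (instance norm) was evaluated and
discards exactly the mean-intensity component of the class signal — a
brighter lesion sets its own normalization scale and normalizes to the same
contrast as a dimmer one — which collapsed phantom separation from
AUC ≈ 0.9 to ≈ 0.65 under otherwise identical conditions. Running
statistics are part of the checkpoint; training-mode normalization uses the
current batch and is deterministic given the seeded batch order. Two
residual consequences worth knowing: features depend (deterministically) on
the training cohort through the running statistics, and receptive-field
overlap still lets structure just outside the lesion influence gated
features — gating suppresses, but does not exactly remove, background-driven
variation.

Training details: per-voxel cross-entropy over the two channels is the
default loss, with a lesion-class weight of 20 to counter the voxel-level
imbalance (lesions occupy ~1 % of a volume); soft Dice and CE+Dice are
selectable, and the experiment harness trains with CE+Dice, which was the
more reliable combination for small lesions on coarse prediction grids.
"200 iterations" of the original protocol is read as 200 epochs
(`TrainConfig.epochs` default); the harness's desk-scale experiments use 50.
The reference label is brought onto the stage-1 prediction grid by
nearest-neighbour *downsampling* — literal cropping cannot map a full-size
label onto a 4×-coarser grid while covering the field of view.

## Synthetic phantoms

The generator emulates co-registered multi-modal volumes with one compact
lesion (axis-aligned ellipsoid, Gaussian-smoothed rim that stays exactly 1
inside the mask so noiseless construction checks are exact), spherical
background "distractor" blobs placed away from the lesion and independent of
the class label, and additive Gaussian noise. The class signal is confined
to the lesion: a per-modality mean shift (`class_effect`) and a within-lesion
noise rescaling (`texture_effect`) for class 1. A class-independent base
contrast (`lesion_contrast`, default 2.0) keeps lesions visible in both
classes — without it class-0 lesions would be invisible and class-blind
segmentation training unlearnable, which does not match the clinical
situation the phantom stands in for.

Presets:

* `tumor3` — 3 modalities (T1ce/T2/FLAIR-like), balanced 40 + 40, clear
  class effect (1.0/0.8/0.6 intensity units against noise σ = 0.1), mild
  texture effect, 3 distractors;
* `stroke5` — 5 modalities (ADC/CBF/CBV/MTT/TTP-like), imbalanced 60 + 11,
  weaker effects, noise σ = 0.15;
* `distractor1` — 1 modality, 24 + 24, weak class effect (mean shift 0.35,
  texture ratio 1.8) under heavy class-uncorrelated background structure:
  10 small bright blobs whose amplitude is drawn per blob from
  U(1.74, 2.9) — overlapping the lesion intensity range so background
  brightness confounds ungated pooled intensities — with per-blob internal
  texture U(1, 4)×σ. Lesions are large (radius 8–11 voxels) so they span
  several feature-grid cells, as real lesions do; at smaller radii a lesion
  covers a single stage-grid cell and gated features degenerate to one
  mask-confidence value. This is the regime in which probability-map gating
  should pay off, used by the ablation-ordering checks.

Effect sizes are free parameters chosen once to be plausible for
well-separated vs. hard tasks; they are not calibrated to any clinical data.
What the phantoms do *not* model: MR physics (bias fields, motion,
registration error — volumes are generated co-registered, matching the
post-preprocessing state the pipeline assumes), anatomy, multi-class lesion
substructure. Passing phantom tests therefore demonstrates the mechanics and
the ordering of the ablation variants under controlled conditions, not
clinical performance.

## Desk-scale experiment sizes

The experiment harness defaults are sized for a single CPU: 32×48×48
voxel phantoms, width-scaled encoders (1/16 of full width — the smallest
scale at which the stem retains enough channels to segment; at 1/32 the
2-channel stem cannot), 50 training epochs, batch size 8, and one shared
class-blind segmentation net per modality trained on all cases (the
`shared_segnet` mode; class labels still never reach it, but the strict
per-fold mode `shared_segnet=False` is the default for leak-free protocols
and is used wherever runtime permits). The full-width architecture checks
run one forward pass on a 155×280×280 volume (~2 GB peak memory).

## Seeds and reproducibility

A master seed fans out to every stochastic component (phantom cohort, fold
shuffle, weight init, batch order, classifier seeds, permutation tests)
via CRC32 of a (seed, tag-path) tuple, each derived seed < 2³¹. Identical
(config, seed) reproduces cohorts byte-identically and experiment reports
bit-identically; per-case phantom seeds derive from (cohort seed, case
index) so any single case can be regenerated in isolation.

## Known limitations

* The phantom's lesion geometry (ellipsoid) and intensity model are far
  simpler than clinical lesions; absolute metric values on phantoms say
  nothing about clinical AUC/F1/ACC.
* Exact oracle-mask background invariance does not hold: encoder receptive
  fields (deep stack, dilations) let background near the lesion leak into
  within-lesion features. The operational property — gating strongly reduces
  background-driven variation relative to ungated pooling — is what the
  tests assert.
* The MLP backend has no class-weighting (scikit-learn's MLPClassifier
  accepts none); stratified folds are its only imbalance handling.
* `Direct CNN`-style joint segmentation+classification is out of scope; the
  ablation variants cover feature-extraction mechanisms only.
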