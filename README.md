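# m3 — mask-attention multi-scale classification of multi-modal 3D brain MRI

Clinically important binary distinctions — glioma vs. solitary brain
metastasis on structural MRI, or predicting hemorrhagic transformation (HT)
after stroke thrombolysis from diffusion/perfusion maps — hinge on subtle
properties of a small lesion inside a large volume. Features pooled over a
whole volume dilute that signal with irrelevant anatomy; radiomics captures
only shallow statistics of it.

This package implements a pipeline that makes deep features *lesion-aware*:

1. a 3D bottleneck-residual encoder–decoder is trained per modality on
   expert lesion masks only (never on the diagnosis) to predict a voxelwise
   lesion-probability map `D(E_N(x))`;
2. that map gates the encoder's multi-scale feature maps,
   `D(E_N(x)) ∘ E_i(x)`, suppressing background structure
   ("mask attention");
3. gated maps from stages i = 2…4 are reduced by global average + max
   pooling and concatenated across scales (7 168 dimensions per case and
   modality at full width);
4. features are z-scored, PCA-reduced (95 % variance) and classified with
   an RBF SVM (RF/GBM/MLP backends available), per modality and fused
   across modalities;
5. everything is evaluated under stratified 5-fold cross-validation with
   AUC / F1 / ACC reported fold-wise as mean ± std, including the ablation
   variants `plain`, `mask`, `multiscale`, `m3`.

Because clinical datasets of this kind are private, the package ships a
synthetic phantom generator (`m3.phantom`) producing co-registered
multi-modal volumes with a compact lesion carrying the class signal,
class-uncorrelated distractor blobs, and noise — enough structure to
exercise and test every stage offline, including the ablation ordering.
See `docs/methods.md` for the model, the phantom's scope, and all numerical
choices.

## Worked example

Run a complete ablation experiment on the distractor-heavy phantom preset
(one modality, 24+24 cases, weak class effect under heavy class-uncorrelated
background structure). Seed 3 draws a cohort on which background structure
is particularly confounding:

```python
from m3.evaluate import ExperimentConfig, run_experiment

cfg = ExperimentConfig(
    preset="distractor1",
    variants=("plain", "mask", "multiscale", "m3"),
    epochs=50, width_scale=1/16, learning_rate=3e-3,
    shared_segnet=True, folds=4,
)
report = run_experiment(cfg, seed=3)
for variant in cfg.variants:
    mean, std = report.mean_std(variant, "T1ce", "auc")
    print(f"{variant:10s} AUC {mean:.3f} +- {std:.3f}")
```

prints (a few minutes on one CPU)

```
plain      AUC 0.368 +- 0.131
mask       AUC 0.611 +- 0.171
multiscale AUC 0.500 +- 0.197
m3         AUC 0.618 +- 0.185
```

On this draw, whole-volume pooling (`plain`) is fully confounded by the
background blobs (below chance), and both gated variants (`mask`, `m3`)
recover usable signal by suppressing them with the predicted
lesion-probability map. Across easier cohort draws the variants converge
toward AUC 1 and the gap closes; fold-to-fold standard deviations at n=48
are large, which is why the test suite compares variants on means over
several master seeds. `compare_variants(report, "m3", "plain")` attaches a
paired permutation p-value to a difference.

The command line mirrors the library:

```bash
m3 simulate --preset tumor3 --out data/            # NIfTI volumes + manifest.csv
m3 train-seg --manifest data/manifest.csv --modality T1ce --out seg.npz
m3 extract --manifest data/manifest.csv --model seg.npz \
           --modality T1ce --variant m3 --out feat.csv
m3 classify --features feat.csv --backend svm --folds 5 --seed 1 --out report.json
m3 run --config experiment.yaml --seed 1 --out report.json   # all of the above
```

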