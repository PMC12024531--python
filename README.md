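# euslite

A lightweight-CNN toolkit for classifying gastric subepithelial lesions on
endoscopic ultrasound (EUS): **GIST** (gastrointestinal stromal tumor, the
positive class) versus **leiomyoma**.  It is aimed at researchers who want
to study compact, speckle-robust classifiers for EUS without access to
clinical image archives: every stage of the pipeline runs end-to-end on a
built-in synthetic EUS phantom generator.

What the package provides:

* **`euslite.archnet`** — the lightweight architecture family, declaratively.
  The canonical model is seven units of valid convolution → batch norm →
  ReLU → 2×2 average pooling (kernels 9,5,5,5,3,3,2; channels
  1→32→32→64→128→256→256→256 at 360×360 input) plus a single 256→2
  classifier behind dropout 0.8 — exactly **1,434,658** trainable parameters.
  A 12-member grid (depths 5/6/7 × final widths 64/128/256/512, codes
  A1…C4) and exact shape/parameter accounting come with it.
* **`euslite.resnet`** — the ResNet-18 baseline (1-channel stem, 2-class
  head; **11,171,266** parameters), both as a parameter table and as a
  trainable network.
* **`euslite.augment`** — probe-centered rotational augmentation: rotate by
  22.5° increments about the ultrasound probe center (15 extra variants per
  frame), then trim to 360×360 with per-angle blank-corner validation;
  dataset normalization statistics.
* **`euslite.phantom`** — synthetic EUS phantoms: central probe, echogenic
  wall rings, hypoechoic lesions whose internal homogeneity and margin
  regularity differ by class, multiplicative gamma speckle, and cohort
  sampling with study-style lesion-size statistics (9.3 ± 5.7 mm development,
  18.7 ± 10.7 mm held-out preset).
* **`euslite.train_harness`** — the training recipe (Adam, lr 5e-5 halved
  every 250 epochs at full scale; desk presets for CPU runs), patient-grouped
  splits and 5-fold cross-validation with median-model selection, and the
  dropout/batch-norm/weight-decay ablation runner.
* **`euslite.evaluate`** — sensitivity/specificity/accuracy/PPV/NPV/F1 with
  Wilson intervals, ROC/AUC, 20-mm size stratification, and brute-force
  reconstruction of confusion matrices from printed summary percentages.
* **`euslite.interpret`** — Grad-CAM per conv unit with lesion-mask
  enrichment scoring.
* **`euslite.nn`** — the compact NumPy CNN engine (im2col + BLAS, full
  backprop, Adam) that powers training on a single CPU core.

All randomness is seed-driven and the engine is single-threaded, so runs are
reproducible.

## Worked example

```python
import numpy as np
from euslite import archnet, phantom, train_harness as th, evaluate as ev, interpret

# exact architecture arithmetic
spec = archnet.build_canonical()
print(archnet.count_parameters(spec))            # 1434658
print([s.side_pre_pool for s in archnet.shape_chain(spec)])
# [352, 172, 82, 37, 16, 6, 2]

# a synthetic cohort: 50 patients x 4 frames, lesions 9.3 +/- 5.7 mm
cohort = phantom.generate_cohort(phantom.CohortConfig(n_patients=50, seed=7))
data = th.arrays_from_phantoms(cohort, input_side=96)

# train the 96-px desk-scale sibling of the canonical model
fold = th.train(archnet.build_desk(96, dropout_rate=0.5), data,
                th.TrainConfig.desk(seed=0))
print(round(fold.final_val_accuracy, 3))          # 0.933

# diagnostic metrics on the held-out patients
_, val_ids = th.split_train_val(data.patient_ids, 0.7, seed=0)
val = data.by_patients(val_ids)
scores = fold.model.predict_scores(val.x)
roc = ev.roc_auc(scores, val.y)
print(round(roc.auc, 3))                          # 0.997
```

The first two numbers are exact: the canonical model's trainable-parameter
total and its layer-by-layer feature-map sides.  The last two are the
held-out, patient-grouped validation accuracy and ROC AUC of a roughly
four-minute CPU training run on the synthetic cohort — they say the phantom classes are
cleanly learnable, not that clinical accuracy would match.

Inspect what the model looks at:

```python
layer = interpret.deepest_spatial_layer(fold.model)   # "Conv4" for desk96
smap = interpret.gradcam(fold.model, val.x[0, 0], layer, "GIST")
inside, outside = interpret.mask_enrichment(smap, val.masks[0])
print(round(inside, 2), round(outside, 2))            # 0.97 0.38
```

A thin CLI mirrors the library (`euslite generate|augment|stats|train|
crossval|grid|ablate|evaluate|gradcam|summarize`), and `examples/` contains
one short narrative script per capability.

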