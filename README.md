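# dieanet

Grading lung adenocarcinoma from HE-stained histopathology patches requires
a network to see both the local growth morphology of single cells and the
overall pattern of cell clusters. This package implements a
**dimension-information-embedding attention** operator (DIEA) built for that
problem, together with the full pipeline around it — so that every stage is
runnable and testable end-to-end on synthetic HE-like images, with no
external data, on one CPU.

The operator compresses a C×H×W feature map into four directional strip
descriptors (average and max pooling along each spatial axis),

&nbsp;&nbsp;aʰ_c(h) = (1/W)·Σᵢ x_c(h,i),&nbsp;&nbsp;mʰ_c(h) = maxᵢ x_c(h,i)&nbsp;&nbsp;(and likewise per column),

fuses them through a shared squeeze 1×1 convolution, re-expands a column
embedding h_a ∈ R^(C×(H+W)×1) and a row embedding h_m ∈ R^(C×1×(H+W)), and
multiplies them per channel into an embedding map h_am ∈ R^(C×(H+W)×(H+W))
whose four quadrants carry every avg/max axis interaction. A stride-2 3×3
convolution and a sigmoid turn h_am into a gate g ∈ (0,1)^(C×H×W) applied as
y = x ⊙ g. Coordinate Attention (average strips only, separable gate) is
included as the baseline, and the AP+AP / MP+MP pooling ablations are a
config switch.

Around the operator the package provides:

* **model zoo** — ResNet-34, MobileNetV2 and EfficientNet-B0 classifiers
  with configurable attention injection, plus parameter/MAC budget
  accounting at 256×256 (`dieanet.zoo`);
* **preprocessing** — sparse-NMF stain separation and normalization in
  optical-density space, seeded random cropping, the 75%-blank patch filter,
  and case-level stratified 5-fold assignment (`dieanet.preprocessing`);
* **synthetic fixtures** — an HE-like generator with grade-ordered nucleus
  density and controllable blank regions (`dieanet.synthetic`);
* **training & metrics** — AdamW with warm-up + cosine annealing,
  leakage-checked cross-validation, and the nine-metric report
  (ACC, AUC, MCC, kappa, macro/weighted F1/precision/recall)
  (`dieanet.train`);
* **Grad-CAM** (`dieanet.explain`) and a CLI (`dieanet …`).

Everything runs on a small NumPy reverse-mode autodiff engine included in
the package (`dieanet.autodiff`, `dieanet.nn`), so there is no deep-learning
framework dependency.

## Worked example

Budgets of the three backbones, bare and attention-augmented
(`python examples/02_compute_budget.py`):

```
model                              params (M)  MACs @256 (G)
resnet34                              21.2862         4.8050
resnet34 + CA                         21.3118         4.8053
resnet34 + DIEA                       21.3180         4.8059
mobilenet_v2                           2.2277         0.4254
mobilenet_v2 + CA                      2.2380         0.4255
mobilenet_v2 + DIEA                    2.2418         0.4258
efficientnet_b0                        4.0114         0.5366
efficientnet_b0 + CA                   4.0217         0.5367
efficientnet_b0 + DIEA                 4.0255         0.5370
```

The bare-backbone rows match the published 3-class figures (2.23M / 4.01M
parameters; 4.8042 / 0.4261 / 0.5404 GMACs within 1%), and the attention
rows show the operator's budget neutrality: at its default placement it adds
at most 0.7% parameters and 0.11% MACs, while always costing slightly more
than the CA baseline it extends.

The full pipeline on synthetic data
(`python examples/04_cross_validation.py`, a couple of minutes on one CPU):

```
patches: 90 cropped, 75 passed the 75%-blank QC rule
fold sizes (cases): {0: 3, 1: 3, 2: 3, 3: 3, 4: 3}

per-fold validation accuracy: [0.857, 0.857, 0.929, 0.824, 0.812]
acc    = 0.856 ± 0.045
auc    = 0.951 ± 0.048
mcc    = 0.797 ± 0.069
kappa  = 0.783 ± 0.068
f1_m   = 0.850 ± 0.044
```

Fifteen synthetic cases (five per grade, two scans each) are stain-
normalized, cropped and QC-filtered; the tiny attention CNN then separates
the three nucleus-density grades at ~0.86 accuracy against a 1/3 chance
level, under a case-level split in which no patient contributes to both
training and validation. `examples/01_attention_gate.py`,
`03_stain_normalization.py` and `05_grad_cam.py` walk the operator algebra,
the stain machinery and the class-activation maps individually.

## Layout

```
src/dieanet/        attention.py  zoo.py  preprocessing.py  synthetic.py
                    train.py  explain.py  cli.py  autodiff.py  nn.py
examples/           one narrative script per capability
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     models, conventions, parameter choices, limitations
```
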