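# lighteyes

Lightweight, full-resolution convolutional segmentation of retinal fundus
structures — vessels, microaneurysms (MA) and hard exudates (EX) — in color
fundus photographs, aimed at settings where models must be small enough for
mobile/edge deployment and where annotated images are scarce.

## The model

Fundus structures are tiny: thin vessels can be a single pixel wide and
microaneurysms cover roughly 0.1% of an image. Encoder–decoder networks that
downsample aggressively (VGG/ResNet backbones) lose exactly the spatial
detail those structures need. `lighteyes` instead builds a **full-resolution
encoder**: 24 stacked 3×3 same-padded convolutions with *no* downsampling,
giving a 49×49 receptive field while every feature map keeps the input
resolution. Memory stays bounded because layers are narrow — at most 16
filters (layers 1–12), reduced to 8 from layer 13 on.

A three-branch decoder reads the encoder at two depths plus a pooled path:

* branch 1 — 1-channel 3×3 head on the mid-depth tap (receptive field 33×33);
* branch 2 — 1-channel 3×3 head on the final tap (51×51);
* branch 3 — 2×2 max-pool of the final tap, three 3×3 convs, a 1-channel
  head at half resolution (66×66), then ×2 bilinear upsampling;

the three 1-channel maps are concatenated and fused by a final 3×3
convolution and sigmoid. Each branch is also a supervised head (deep
supervision); variants `A1`/`A2`/`A3` truncate the network to a single head.
The default network has **35,551 parameters** (316 filters); the variants
have 28,369 / 33,625 / 35,377.

Training uses the **random-drop loss**, a class-balanced cross-entropy in
which each background pixel j is stochastically dropped with probability
p_drop(p_j) = 1 − p_j:

    L(p, y) = −β Σ_{y_j=1} log p_j − (1−β) Σ_{y_j=0} 1(p_j) log(1 − p_j),
    β = N_n / (N_n + N_p)

so easy negatives stop contributing gradient while hard negatives (high
activation p_j) are almost always retained. Evaluation binarizes probability
maps at the **equilibrium point** — the PR-curve threshold where precision
and recall are closest — and reports Se/Sp/Pr/Re/F1/JI/Acc/AUC, optionally
restricted to the field-of-view mask.

All tensor computation (convolution, pooling, bilinear resampling,
backpropagation, ADAM, xavier initialisation) is implemented in numpy and
verified against finite differences; the model is small enough that CPU
training is practical.

## Worked example

Train on a tiny synthetic lesion task (4 images, 64×64, ~0.1% bright-blob
foreground) and evaluate on 2 held-out images:

```python
import numpy as np
from lighteyes import SyntheticSpec, make_dataset, TrainConfig
from lighteyes.pipeline import train, predict, evaluate
from lighteyes.fundus_io import read_manifest

spec = SyntheticSpec(size=(64, 64), task="lesion", seed=0)
train_m, test_m = make_dataset(spec, n_train=4, n_test=2, out_dir="wk")
result = train(train_m, TrainConfig(iterations=200, seed=0), "wk/run")
print("parameters:", result.run_record["n_parameters"])
predict(result.weights_path, [r["image"] for r in read_manifest(test_m)], "wk/pred")
print(evaluate("wk/pred", test_m).to_text())
```

Output (about a minute on one CPU core):

```
parameters: 35551
Se        0.8333
Sp        0.9996
Pr        0.8333
Re        0.8333
F1        0.8333
JI        0.7143
Acc       0.9993
AUC       0.9997
threshold 0.0039
```

The mean training loss falls from 49.5 (first 20 iterations) to 4.6 (last
20). Precision equals recall exactly because the operating threshold is the
equilibrium point; AUC ≈ 1 shows the ranking is near-perfect, while F1
reflects the handful of boundary pixels a 6-pixel lesion can get wrong.
Accuracy is inflated by class imbalance — with 99.9% background, predicting
"background" everywhere already scores 0.999, which is why F1/JI/AUC are the
informative numbers here.

The same workflow is available from the shell:

```bash
lighteyes synth --task lesion --size 64 64 --n-train 4 --n-test 2 --out wk
lighteyes train --manifest wk/train.csv --iterations 200 --seed 0 --out wk/run
lighteyes predict --weights wk/run/weights.npz --out wk/pred wk/test/*_image.png
lighteyes eval --pred-dir wk/pred --manifest wk/test.csv
lighteyes summary          # per-layer architecture accounting
```

Real datasets (DRIVE, STARE, CHASE_DB1, IDRiD, e-ophtha EX) are used by
pointing a CSV manifest (`image,gt,fov` columns) at their files; nothing is
downloaded by the package.

## Layout

| module | contents |
| --- | --- |
| `lighteyes.model` | network builder, parameter/receptive-field accounting, forward/backward |
| `lighteyes.loss` | random-drop loss, class-balanced cross-entropy |
| `lighteyes.metrics` | confusion counts, Se/Sp/Pr/Re/F1/JI/Acc, ROC-AUC, equilibrium threshold |
| `lighteyes.fundus_io` | image/mask IO, manifests, 712×1072 lesion resize, ×6 augmentation |
| `lighteyes.synthetic` | fundus-like fixture generator (vessel trees, lesion blobs) |
| `lighteyes.pipeline` | training loop, prediction, dataset-level evaluation |
| `lighteyes.cli` | `lighteyes synth|train|predict|eval|summary` |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
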