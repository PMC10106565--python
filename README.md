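# glsegnet

Global–local representation learning for binary medical-image segmentation.

Segmenting lesions, glands or organs in 2-D medical images (histology,
dermoscopy, MRI slices, radiographs) requires both long-range context — to
suppress cluttered, irrelevant background — and fine local geometry, which
plain encoder–decoder networks tend to lose in their shallow skip
connections. `glsegnet` is a U-shaped network that addresses both ends:

* a **context-rich encoder** whose skip connections are enriched by
  multi-scale atrous convolution (MSC, rates 1/2/4/8), multi-scale max
  pooling (MSP, sizes 2/4/8/16) and cross-level fusion of shallow features
  into deeper skips;
* a **ViT bottleneck** — patch embedding plus pre-norm transformer layers
  computing `softmax(QKᵀ/√d_k)V` multi-head self-attention — that filters
  the deepest features for global semantics;
* an **attention-gated decoder**: each stage computes
  `AG(X, C) = σ(ψ(relu(WₓX + W_cC))) · C` over the summarized skip `C` and
  the upsampled decoder feature `X`, then fuses
  `Y = Conv₃ₓ₃([AG(X, C); UP(X)])`; a 7×7 convolution and sigmoid produce
  the mask.

Training minimizes a four-term hybrid loss

```
L = α(1 − DSC) + β·BCE + γ(1 − SSIM) + θ·‖ΔI_s − ΔI_g‖/(H·W),   α+β+γ+θ = 1
```

combining region overlap, per-pixel classification, windowed structural
similarity and a Laplacian edge-preservation penalty. Evaluation reports
five indices: MeanDice, MeanIoU, weighted F-measure (wFm), Structure-measure
(Sm) and Enhanced-alignment measure (Em).

The network runs on a small, fully tested reverse-mode autodiff engine over
numpy (`glsegnet.autograd`) — no deep-learning framework is required — which
keeps the package light and every gradient checkable against finite
differences. A deterministic synthetic "lesion-on-background" generator
makes the whole pipeline testable without downloading datasets.

## Worked example

```python
import numpy as np
from glsegnet import (ModelConfig, SyntheticSpec, TrainConfig,
                      generate_pair)
from glsegnet.train import evaluate_model, train

spec = SyntheticSpec(image_size=64, seed=1)
def split(start, n):
    pairs = [generate_pair(spec, i) for i in range(start, start + n)]
    imgs = np.stack([np.repeat(p[0][None], 3, 0) for p in pairs]).astype("float32")
    masks = np.stack([p[1][None] for p in pairs]).astype("float32")
    return imgs, masks, [str(i) for i in range(start, start + n)]

cfg = TrainConfig(epochs=50, image_size=64, seed=1, model=ModelConfig.tiny())
model, record = train(cfg, split(0, 16))
print("first/last epoch loss:",
      round(record.epochs[0]["total"], 4), round(record.epochs[-1]["total"], 4))
print("held-out:", {k: round(v, 3)
                    for k, v in evaluate_model(model, split(16, 8)).means.items()})
```

prints (about two minutes on one CPU):

```
first/last epoch loss: 0.688 0.0292
held-out: {'dice': 0.897, 'iou': 0.817, 'wfm': 0.893, 'sm': 0.852, 'em': 0.977}
```

The loss falls by a factor of ~20 over 50 epochs and the tiny model segments
held-out synthetic lesions at Dice ≈ 0.90 — the blobs are recovered nearly
pixel-perfectly, with the remaining error concentrated on blurred boundaries.

The same pipeline is available from the shell:

```bash
glsegnet synth --out data/ --n-train 80 --n-test 20
glsegnet train --data data/ --out runs/exp1 --tiny
glsegnet predict --weights runs/exp1/best.npz --input data/test/images --output preds/
glsegnet evaluate --pred preds/ --gt data/test/masks --report report.json
```

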