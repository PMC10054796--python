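# fundcam

Attention-guided crop augmentation and ensemble classification for
**multi-label retinal fundus images**.

Fundus photographs used for disease screening (RFMiD-style datasets:
thousands of images, dozens of co-occurring disease labels, severe class
imbalance) pose two linked problems: lesions are small relative to the
frame, and many categories have only a handful of examples. `fundcam`
implements a pipeline that attacks both with the network's own attention:

1. **Class-activation attention.** For feature maps $A^k$ of the last
   convolutional layer and class logit $y^c$, Grad-CAM weights are
   $w_k^c = \frac{1}{Z}\sum_{i,j} \partial y^c / \partial A_{ij}^k$ with
   $Z = WH$, and the map is
   $I^c_{\text{Grad-CAM}} = \mathrm{ReLU}(\sum_k w_k^c A^k)$.
   Guided backpropagation (ReLU backward passes only positive gradients
   through positively activated units) gives image-resolution saliency,
   and Guided-Grad-CAM is their elementwise product. Per-class maps are
   averaged over the image's positive labels.
2. **Attention-crop augmentation.** The aggregated map is scaled to
   $[0,255]$, thresholded at $\theta$ (default 128) into a binary mask
   $M = \mathbb{1}[I > \theta]$, the smallest circumscribed rectangle of
   the mask is cut from the original image, bilinearly resized back to
   the model input size, and added to the training set with the source
   image's full label vector.
3. **Weighted focal loss.** Per class,
   $\mathrm{FL}(p_c) = -\alpha_c (1-p_c)^\gamma \log p_c$ with
   $\gamma = 2$ and inverse-frequency weights $\alpha_c$, focusing
   training on hard, rare labels.
4. **Fold-bagged two-model fusion.** Each of two backbone architectures
   is trained on each of $k=5$ cross-validation folds (10 models); fold
   predictions are averaged within an architecture and the two score
   matrices fused convexly, $G_f = \lambda G_1 + \sigma G_2$ with
   $\lambda + \sigma = 1$ (default $0.6/0.4$).

The CNN machinery (convolution, ReLU, pooling, GAP, linear and residual
blocks, Adam, manual backprop including the guided-ReLU rule) is
implemented in NumPy inside the package (`fundcam.nn`), which keeps
every gradient the attention maps depend on directly checkable against
finite differences. Registered backbones: `tiny_cnn` (the desk-scale
default), `vgg16`, `vgg19`, `resnet50`.

A synthetic-data module generates fundus-like images — a bright circular
field on an exactly black background with planted, class-coloured lesion
blobs whose pixel masks are known — so the whole pipeline trains and
validates in minutes on a CPU without any external dataset.

## Worked example

```python
import numpy as np
from fundcam import SyntheticSpec, generate_dataset
from fundcam.estimators import AttentionEnsembleClassifier
from fundcam.ensemble import multilabel_metrics

spec = SyntheticSpec(image_size=32, n_classes=2, label_prevalence=0.5,
                     blob_radius=(5.0, 8.0), blob_intensity=(0.6, 0.9), seed=3)
train, _ = generate_dataset(spec, 60)
test, _ = generate_dataset(SyntheticSpec(**{**spec.__dict__, "seed": 4}), 30)

est = AttentionEnsembleClassifier(backbones=("tiny_cnn", "tiny_cnn"),
                                  folds=2, epochs=30, batch_size=8,
                                  lr_init=1e-2, seed=2)
est.fit(train.images_array(), train.label_matrix())
rep = multilabel_metrics(est.predict_proba(test.images_array()),
                         test.label_matrix())
print(len(est.checkpoints_), round(rep.accuracy, 3), round(rep.mean_auc, 3))
```

prints

```
4 1.0 1.0
```

i.e. the two-stage run produced 2 backbones x 2 folds = 4 fold models,
and the fused ensemble classifies all held-out (image, class) cells
correctly with a mean per-class ROC AUC of 1.0 on this easy synthetic
task.

The same pipeline is scriptable from the shell:

```bash
fundcam simulate --out data/ --n 60 --classes 2 --size 32 --seed 3
fundcam train    --image-dir data/ --labels data/labels.csv --out runs/
fundcam augment  --checkpoint runs/ckpt_00_tiny_cnn_fold0.npz \
                 --image-dir data/ --labels data/labels.csv --out aug/
fundcam gradcam  --checkpoint runs/ckpt_00_tiny_cnn_fold0.npz \
                 --image data/syn_0000.png --class-index 0 --out cams/
fundcam evaluate --checkpoint-dir runs/ --image-dir data/ \
                 --labels data/labels.csv --out eval/
```

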