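# Methods

## The model

`fundcam` implements a multi-label image classifier for retinal fundus
photographs whose distinguishing feature is that the network's own
class-attention is recycled as a data-augmentation signal.

**Attention maps.** Let $A^k$ ($k = 1..K$, each $W \times H$) be the
output maps of a chosen convolutional layer — by default the activation
of the last convolutional block, which is also where global average
pooling (GAP) reads them, so spatial class evidence survives up to the
classification head. For the pre-sigmoid logit $y^c$ of class $c$:

* Grad-CAM: $w_k^c = \frac{1}{WH} \sum_{ij} \partial y^c / \partial
  A^k_{ij}$, $I^c = \mathrm{ReLU}(\sum_k w_k^c A^k)$. The normaliser is
  the map area, making each weight the global average of its channel's
  gradient; with a GAP + linear head this reduces exactly to the head
  weight divided by $WH$, a closed form the tests exploit.
* Guided backpropagation: a backward pass in which every ReLU, besides
  the usual gating on positive forward activations, drops negative
  incoming gradients. Models without ReLUs reduce to the standard
  gradient. The per-channel image gradient is collapsed to one channel
  by a max over colour channels when a scalar intensity is needed.
* Guided-Grad-CAM: the elementwise product of the guided saliency and
  the Grad-CAM map bilinearly upsampled to image resolution.
* Multi-label aggregation: the mean of the per-class maps over the
  image's ground-truth-positive classes during training-time
  augmentation (predicted-positive classes at inference). The mean (not
  sum) keeps the scale independent of how many labels an image carries.

**Cropping.** The aggregated map is min-max scaled to $[0, 255]$
(constant maps scale to all-zero, yielding no crop), thresholded
strictly at $\theta$, and the smallest circumscribed rectangle of the
resulting mask — equivalently the min/max occupied row and column — is
cut from the original image and bilinearly resized to the model input
size. $\theta$ defaults to 128, the midpoint of the byte range; the
mask and the box area are monotonically non-increasing in $\theta$.
Crops inherit the full label vector of their source image: the crop is
assumed to contain the lesion evidence for every positive label, which
holds when attention concentrates on lesions but is an approximation
for images with widely separated multi-class findings (per-class
cropping is available as a variant). Images with an empty mask or no
positive label contribute no crop.

**Loss.** Weighted focal loss per class,
$\mathrm{FL}(p_c) = -\alpha_c (1 - p_c)^\gamma \log p_c$, where $p_c$
is the predicted probability of the true state of class $c$ (sigmoid
output for a positive label, its complement for a negative one),
averaged over classes and batch so that settings transfer across label
counts. $\gamma = 2$ by default; $\gamma = 0$, $\alpha = 1$ recovers
binary cross-entropy, an identity the tests assert to 1e-12.
$\alpha_c \propto n/(C \max(n_c, 1))$, normalised to mean 1, counters
label imbalance; probabilities are clamped to $[10^{-7}, 1-10^{-7}]$
before the log.

**Training protocol.** Two stages. Stage 1 trains one base network on
the full images and uses its attention maps to produce one crop per
image. Stage 2 trains each of two backbone architectures on each of $k$
cross-validation folds of the enlarged dataset — originals, attention
crops, and one classically augmented copy per record (random
brightness x[0.8, 1.2], gamma [0.8, 1.25], saturation x[0.8, 1.2],
rotation +-15 deg, random crop keeping >= 85% area, horizontal flip
p = 0.5; ranges are the package's own choices). Optimisation is Adam
from 1e-4 with reduce-on-plateau (factor 0.1, patience 8 epochs on
validation loss, floor 1e-7 — three plateau cycles exhaust the range)
and early stopping after 20 stale epochs, restoring the best
checkpoint. The reference protocol uses $k = 5$ and two ImageNet-class
backbones, giving 10 fold models.

**Prediction.** Fold predictions are averaged within an architecture
(the bagging reduction; the convex fusion below is defined for exactly
two score sets, so a pre-fusion reduction is required), then fused:
$G_f = \lambda G_1 + \sigma G_2$, $\lambda + \sigma = 1$, default
$(0.6, 0.4)$. $G_f$ is elementwise bounded by $\min(G_1, G_2)$ and
$\max(G_1, G_2)$.

**Metrics.** Micro-averaged over all (image, class) cells at decision
threshold 0.5 by default (macro is a config option; reports label the
mode): accuracy $= (TP+TN)/\text{cells}$, precision, recall, F1.
Per-class ROC AUC is the rank (Mann-Whitney) statistic with ties
counted 0.5; classes with only one label value in the evaluation set
have undefined AUC and are excluded from the macro mean with a count
in the report.

## The CNN engine

All differentiable machinery lives in `fundcam.nn`: conv / ReLU /
max-pool / GAP / linear / residual layers on float64 NumPy arrays with
hand-written backward passes, and Adam. This makes the guided-ReLU
backward rule a first-class layer property rather than a framework
hook, and keeps every gradient the attention maps use directly
verifiable: the suite checks feature-map gradients against central
finite differences (tolerance 1e-3 at epsilon 1e-4) and the focal-loss
gradient likewise. The `tiny_cnn` backbone is two 3x3 conv/ReLU blocks
(8 and 16 channels) with GAP and a linear head — deliberately without
max pooling, so the path from the attention target layer to the logits
is smooth and the finite-difference oracle is well posed (max pooling
is nondifferentiable at within-window ties). `vgg16`/`vgg19` (3x3
stacks, 2x2 pools, GAP head in place of the fully connected stack) and
`resnet50` (bottleneck residual blocks with projection shortcuts; no
batch normalisation — biases take its place in this engine) satisfy the
same contract and are constructible and differentiable at any class
count, but are impractical to *train* in this engine and carry no
pretrained weights; desk-scale runs use `tiny_cnn`.

## Synthetic data

The generator emulates exactly the image structure the pipeline depends
on: a bright, vignetted circular field (radius 0.45 of the frame) on an
exactly black background; independent per-class Bernoulli labels; for
each positive label 1-2 Gaussian-profile blob lesions in a
class-distinctive hue (hues kept away from the warm background colour),
radius drawn from a configurable range, fully inside the field, with
the rasterised disc mask of every blob retained; additive Gaussian
noise (sd 0.02). Defaults: 224 px frame, prevalence 0.4. It does **not**
model vessel trees, optic discs, texture variation within a lesion
class, or inter-class visual similarity — so passing tests show the
pipeline's mechanics (learning, localization, cropping, fusion) are
correct, not that the method reaches any particular accuracy on real
fundus photographs.

Desk-scale test and acceptance runs use 32 px images, 2 classes,
prevalence 0.5, blob radii 5-8 px, 60-100 training images, 2 folds and
2 `tiny_cnn` "architectures", about 30 epochs at learning rate 1e-2 —
sizes at which the full two-stage run takes on the order of a minute
while every protocol count (folds x architectures checkpoints, crop
bookkeeping) is exercised unchanged.

## Numerical and design choices

* Grad-CAM normaliser $Z = WH$; aggregation normaliser $Z$ = number of
  aggregated classes.
* Byte scaling maps constant attention maps to all-zero (no crop)
  rather than dividing by zero; the scaled maximum is clipped to 255 so
  the strict threshold at $\theta = 255$ is exactly empty.
* Bounding boxes are 0-based, half-open, x indexing columns and y rows;
  an all-zero mask returns an explicit empty signal, and the empty-mask
  fallback keeps only the original image.
* Crop-to-identity: cropping the full frame at its own size returns the
  pixels untouched (no resampling round-trip).
* The stage-1 crop generator is one model trained on all training data
  (per-fold crop generation would multiply cost without changing the
  protocol's shape); it is the first backbone in the configured pair.
* Dataset-level determinism: one seed fans out to stage seeds drawn
  from a single generator, so fold assignments, augmented-record lists
  and fitted weights are reproducible bit for bit on one platform.
* The ensemble's first three ablation rows share a single training run
  without attention crops, which makes "ensemble = fusion of the single
  rows" exact rather than a retraining coincidence.

## Known limitations

* The NumPy engine is CPU-bound and unsuitable for training
  ImageNet-scale backbones; the architecture registry exists to keep
  the contract honest, not to reach benchmark accuracy.
* Guided backprop on architectures whose ReLUs sit inside residual
  bodies is supported, but the saliency literature's caveats about
  guided methods acting partly as edge detectors apply unchanged.
* One crop per image with inherited full labels is an approximation for
  multi-label images with spatially disjoint findings.
* Synthetic results quantify pipeline correctness only; real-data
  performance depends on backbone capacity and pretraining outside this
  package's scope.
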