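# ductstone

Weakly-supervised detection of common-bile-duct (CBD) stones in grayscale
CT-like slices: train a convolutional network from **image-level labels
only** (stone present / absent), then localize the stone at inference time
from the network's own spatial-channel attention maps.

The package is for researchers studying weakly-supervised lesion
localization — situations where drawing ground-truth boxes is too expensive,
but presence/absence labels are cheap. Since the clinical CT data this task
comes from is private, the package ships a synthetic phantom generator that
reproduces the task's statistical structure (a small, moderately bright
stone confined to a duct region, against brighter bone-like distractors
present in every image), so the whole pipeline runs end-to-end with no
downloads.

## Model

For a slice `I` (H x W in [0,1]) the network computes

* a VGG-style backbone feature `f_b` at 1/4 resolution;
* a multiple field-of-view encoder feature
  `f_E = f_d^1 ++ f_d^2 ++ f_d^3 ++ f_d^4 ++ f_p`, where
  `f_d^k = dconv^{2^{k-1}}(f_b ++ f_d^{k-1})` are cascaded 3x3 dilated
  convolutions (rates 1,2,4,8) and `f_p` is a 2x2 max-pooled copy of `f_b`;
* a full-resolution decoder feature `f_U` (upsampling + instance-norm
  stages, with global-average-pooled backbone blocks as channel-wise
  forward connections);
* CBAM-style attention: channel attention
  `m_c = sigma(maxpool_s(f_U) + avgpool_s(f_U))`, spatial attention
  `m_s = sigma(conv7x7(maxpool_c(f_U) ++ avgpool_c(f_U)))`, probability map
  `m_p = sigma(conv1x1(m_s * (m_c * f_U)))`;
* a classification head on the flattened `m_p` giving the stone
  probability `y_hat`.

Training minimizes
`l = w_fg*l_fg + w_bg*l_bg + w_con*l_con + w_cls*l_cls` with weights
(1, 0.5, 1, 1), where `l_fg = mean((1-m_s)*m_p)`,
`l_bg = mean((1-y)*m_p)`, `l_con = BCE(y, GAP(m_p))` and
`l_cls = BCE(y, y_hat)` — all functions of the image-level label only.
Optimization: RMSProp (rho 0.9, eps 1e-8), batch size 3, initial learning
rate 1e-4, /10 on a 5-epoch validation plateau, early stop after 10.

At inference the stone attention map
`m_a = avgpool_c(m_s * (m_c * f_U)) * (1 - m_p)` is max-normalized and
thresholded at 0.6; if the classifier votes positive, the bounding box of
the largest 8-connected component is the detection.

The network runs on a small NumPy reverse-mode autodiff core bundled with
the package (`ductstone.autodiff`) — no deep-learning framework required.

## Worked example

```sh
ductstone experiment --out runs/demo --seed 1
```

generates 60 training and 30 test phantoms (96 x 96, stone:normal = 1:2),
trains the detector from the image-level labels, detects on the test split
and prints, e.g.:

```json
{
  "n_images": 30,
  "confusion": {"tp": 10, "fp": 0, "tn": 20, "fn": 0},
  "accuracy": 1.0,
  "sensitivity": 1.0,
  "specificity": 1.0,
  "f1": 1.0,
  "miou": 0.3038129124101975,
  "ap": 0.0,
  "random_box_miou": 0.009898876370933821,
  "miou_over_random": 30.691656408831072
}
```

Here `accuracy/sensitivity/specificity/f1` score the stone-present
classification of the 30 held-out phantoms at a 0.5 threshold on `y_hat`;
`miou` is the mean IoU between predicted and true stone boxes over the 10
stone images (a missed detection counts 0); `ap` is average precision at
IoU 0.5 (zero here: the boxes overlap every stone but none tightly enough
to clear the 0.5 match threshold); `random_box_miou` is the same mIoU after
re-placing each predicted box uniformly at random — the ~30x gap over
chance is the evidence that the attention maps, trained with no box
supervision, genuinely found the stones. Localization quality at this
desk scale is initialization-sensitive; see the limitations section of
`docs/methods.md`. Artifacts (dataset, checkpoint, per-epoch history, detections,
metrics, run summary) land under `runs/demo/`.

The individual stages are also available as
`ductstone simulate | train | predict | evaluate`, and as library functions
(`ductstone.generate_dataset`, `ductstone.train`, `ductstone.detect`,
`ductstone.classification_metrics`, ...).

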