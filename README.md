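# dermatex

Dual-branch convolutional classification of textured skin-disease
images, combining a 2-D CNN on (optionally enhanced) RGB images with a
1-D CNN on a handcrafted texture/shape descriptor vector, plus the
wavelet-fusion enhancement stage, evaluation metrics and Grad-CAM
saliency maps. Everything is testable end-to-end on a seeded synthetic
image generator, so no external dermatology collection is required.

## The method

**Enhancement (ICTEF).** Each channel is filtered by three arms —
double-stage Gaussian (3×3, σ=1, applied twice), a 3×3 locally
adaptive Wiener filter, and CLAHE followed by a 3×3 median — then each
arm is decomposed by a 3-level db2 discrete wavelet transform. The
three decompositions are fused by the per-subband arithmetic mean,

    A_m = (A_G + A_W + A_M)/3,   and likewise H_m, V_m, D_m,

and the enhanced image is `IDWT(A_m, V_m, H_m, D_m)`, clipped to [0, 1].

**Handcrafted descriptors**, computed on the grayscale image:

- *GLCM* (6 values): contrast Σ(i−j)²P_ij, correlation, energy ΣP²_ij,
  homogeneity ΣP_ij/(1+|i−j|), autocorrelation ΣP_ij·ij and entropy
  Σ−P_ij ln P_ij of the normalized 8-level co-occurrence matrix at
  horizontal offset 1.
- *Directional LBP* (32 values): the 3×3 neighbourhood is split into
  top/bottom/left/right 3-neighbour patterns, each thresholded
  strictly against the center into a 3-bit code; four 8-bin histograms
  are concatenated. (The conventional 256-bin LBP is also provided.)
- *HOG* (34,596 values at 256×256): 9-bin unsigned orientation
  histograms over 8-px cells, L2-normalized in 2×2-cell blocks with
  50% overlap.

**SDNet.** The 2-D branch runs three blocks of
`Conv(3×3, same) → ReLU → BatchNorm → MaxPool(2×2)` with 64/128/256
filters on the H×W×3 image; the 1-D branch runs the analogous
`Conv(3) → ReLU → BatchNorm → MaxPool(2)` blocks on the descriptor
vector. Flattened branch outputs are concatenated (at nominal scale
262,144 + 1,106,944 = 1,369,088 values) and a fully connected softmax
head produces class posteriors. Training uses Adam (lr 0.001, ×0.5
step decay) on a stratified 70:30 split. The network and its
backpropagation are implemented in NumPy (`dermatex.nn`).

**Explainability.** Grad-CAM on the last 2-D convolution: channel
weights are spatial means of the class-logit gradient, the map is the
rectified weighted channel sum, bilinearly upsampled and
max-normalized.

## Worked example

```python
import numpy as np
from dermatex.synthetic import default_class_specs, generate_image
from dermatex.glcm import compute_glcm, glcm_features
from dermatex.lbp import ilbp_features
from dermatex.image import to_grayscale

for spec in default_class_specs():
    g = to_grayscale(generate_image(spec, (64, 64), seed=0))
    f = glcm_features(compute_glcm(g))
    print(f"{spec.class_name:16s} contrast={f.contrast:.3f} "
          f"correlation={f.correlation:.3f} entropy={f.entropy:.3f}")
```

prints

```
acne             contrast=0.349 correlation=0.898 entropy=2.545
lupus            contrast=0.665 correlation=0.891 entropy=3.110
melanoma         contrast=1.035 correlation=0.874 entropy=3.371
urticaria_hives  contrast=0.071 correlation=0.927 entropy=1.320
herpes_hpv       contrast=1.553 correlation=0.825 entropy=3.551
```

i.e. the five synthetic classes keep the intended texture orderings:
the herpes-like class is the most contrasted and least correlated, the
hives-like class the smoothest and most correlated. A full experiment
(`dermatex.pipeline.run_experiment`) trains the fused model and its
single-branch ablations with and without enhancement and emits one
JSON report with a confusion matrix and accuracy/precision/recall/F1
per block.

A CLI is included: `dermatex synth | enhance | features | run | explain`.

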