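# Methods

This note records the models implemented by the package, the choices
made where the design was genuinely open, what the synthetic data do
and do not emulate, and the conditions under which the end-to-end
experiments run.

## Enhancement (ICTEF)

Three filter arms run on the same grayscale raster and are fused in
the wavelet domain:

1. **Double-stage Gaussian** — the normalized 3×3 discretization of
   the isotropic Gaussian (σ = 1 px) applied twice, on symmetric
   boundaries. The kernel is the analytic
   `exp(-(x²+y²)/2σ²) / 2πσ²` evaluated on the window grid and
   renormalized to sum 1, so constants are preserved exactly.
2. **Adaptive Wiener (3×3)** — local mean μ and variance σ² from a box
   filter on reflective boundaries; noise power ν estimated as the
   mean local variance; output `μ + max(σ²−ν, 0)/σ² · (x−μ)`. The
   filter is implemented directly rather than via `scipy.signal.wiener`
   because the latter zero-pads borders, which distorts edges and
   breaks constant preservation.
3. **CLAHE + median (3×3)** — `skimage` CLAHE with 8×8 tiles and clip
   limit 0.01, then a 3×3 median. A zero-dynamic-range input is passed
   through CLAHE unchanged: equalization is ill-defined on a flat
   histogram, and the library's behaviour there (mapping any constant
   to 1.0) is a normalization artifact, not a meaningful enhancement.

Each arm is decomposed by a 3-level db2 DWT with **periodized
boundaries** (chosen for exact perfect reconstruction and
deterministic subband shapes), coefficients are averaged per subband
*at every level* — averaging only the coarsest level would leave the
reconstruction undefined — and the inverse transform is clipped to
[0, 1] since fusion can overshoot the valid range. RGB images are
enhanced per channel so the image branch keeps its 3-channel input.

Degenerate inputs: images smaller than 8×8 are rejected (3 DWT
levels); the periodized transform may round sizes up internally and
the reconstruction is cropped back.

## Descriptors

All descriptors run on the Rec.-601 luma of the working-resolution
image.

**GLCM.** Intensities are uniformly quantized to 8 levels; pairs at
horizontal offset 1 are counted symmetrically and normalized
(`skimage.feature.graycomatrix` does the counting). Levels, distance
and angle are configurable; the defaults are the smallest
configuration whose statistics sit in the conventional ranges.
Correlation uses row/column standard deviations in the denominator —
identical to the single-variance form on symmetric matrices but
keeping the value in [−1, 1] generally. A constant image has zero
marginal variance; its correlation is reported as 1.0 with a warning
(a flat field is perfectly self-similar), because raising inside batch
feature extraction would poison whole runs. Entropy uses the natural
logarithm with 0·ln 0 = 0.

**Directional LBP.** Strict `>` against the center (ties → 0), codes
over interior pixels only (padding would invent histogram mass), and
MSB-first packing of each direction's neighbour list — top (p1,p2,p3),
bottom (p6,p7,p8), left (p1,p4,p6), right (p3,p5,p8). The packing
order is a free choice; it is fixed, documented and tested. Histograms
are raw counts (each sums to the interior-pixel count), concatenated
U‖B‖L‖R; optional frequency normalization is off by default. Strict
thresholding makes all codes exactly invariant to adding a constant or
positively rescaling the image; no rotation invariance is claimed.

**HOG.** Centered differences [−1 0 1] on replicate-padded borders;
unsigned orientations folded to [0°, 180°) with nine 20° bins
(the sign-ambiguity of arctan makes the unsigned convention the
natural one); magnitude-weighted votes split linearly between the two
nearest bin centers; 2×2-cell blocks advancing one cell (50% overlap)
L2-normalized with ε = 10⁻⁶ and no clipping. Zero-magnitude pixels
carry orientation 0 with zero weight, so the choice is inert; a
constant image yields the all-zero vector. The stride-1 block grid is
what makes an 8-px cell on a 256×256 image produce 31×31 blocks × 36
values = 34,596 features, the count that pins the geometry.

## The dual-branch classifier

Built and trained entirely in NumPy (`dermatex.nn`): layers cache
forward state, backpropagation is hand-derived per layer (verified
against finite differences in the tests), and Adam with a mutable
learning rate drives the updates. Design points forced by the printed
architecture:

- convolutions are stride-1 with *same* padding (output size equals
  input size in every conv row);
- max-pooling halves lengths with floor (34,596 → 17,298 → 8,649 →
  4,324 on the nominal descriptor vector);
- BatchNorm (2 trainable parameters per channel) sits after ReLU,
  matching the printed layer order;
- the fully connected head maps the concatenation
  [2-D flatten ‖ 1-D flatten] to class logits.

Two configurations are distinguished. The *default* uses 5 classes,
a biased head and the full 34,634-long descriptor vector
(6 + 32 + 34,596): the method text combines all three descriptor
families. The *nominal accounting* configuration
(`SDNetConfig.table_compat()`) reproduces the printed architecture
table exactly — HOG-only 34,596 input, 4 output units, biasless head
(1,369,088 × 4 = 5,476,352) — and exists purely for structural
verification. The printed parameter counts of the 2nd/3rd 1-D
convolutions are internally inconsistent (they ignore input channels);
standard dense-across-channels convolution is implemented and those
two cells are not treated as reference values.

"Decay rate 0.5" in the stated hyperparameters is read as a step
learning-rate schedule (×0.5 every `decay_every` epochs, default 50
under the nominal 200-epoch budget); the alternative readings (Adam
moment coefficient, exponential decay) are less common for a lone
"decay rate" entry. Batch size (unstated) defaults to 32. Ties in the
predicted posterior resolve to the lowest class index.

## Pipeline

Images are bilinearly resized to the working resolution before
anything else. Handcrafted descriptors are always computed on the
**original** grayscale; enhancement, when enabled, conditions only the
image branch's input. The enhancement stage's CLAHE arm renormalizes
local contrast, and on data whose classes differ chiefly in texture
contrast this measurably erodes the descriptors' class separation —
while the image branch benefits from the denoising. Computing
descriptors on the untouched image keeps their calibrated magnitudes
and lets enhancement do the one thing it is for.

Because the descriptor segments live on wildly different scales
(GLCM ≈ 1, LBP counts ≈ 10⁴, HOG ≈ 1), the feature matrix is z-scored
per dimension with statistics fit on the training split only
(config-off able). Feature manifests carry a configuration hash;
a fitted pipeline refuses matrices produced under a different
configuration.

## Synthetic data

Each class is a filtered Gaussian random field: white noise smoothed
by a Gaussian of the class's correlation length, rescaled to unit
sample variance, multiplied by the texture amplitude and added to the
base gray level. Amplitude directly controls co-occurrence contrast;
correlation length controls neighbour correlation (and, at fixed
amplitude, depresses contrast), so the five default classes reproduce
the qualitative orderings expected of the five disease classes: the
herpes-like class is the most contrasted, the hives-like class the
smoothest and most correlated. The melanoma- and lupus-like classes
additionally carry an elliptical lesion whose boundary radius is
perturbed sinusoidally with a seeded phase (a shape cue for HOG and a
ground-truth mask for saliency checks). All three channels share one
luminance field up to small seeded chromatic offsets; degradations
(additive Gaussian noise, optional blur) are applied last and never
affect labels. All randomness flows from explicit integer seeds;
regeneration is bit-identical.

What this generator does **not** emulate: hair and ruler artifacts,
specular highlights, vignetting, color variation between lesion types,
and any structural morphology beyond a perturbed ellipse. Passing
tests therefore demonstrate that the pipeline recovers controlled
texture/shape structure — not clinical performance on dermatology
photographs.

## End-to-end experiment conditions

Training the nominal 256×256 / 64-128-256-filter network for 200
epochs is a GPU-scale job; the package's experiments run at
scaled-down conditions chosen once for the synthetic study:

- working resolution 128×128; HOG cell 16 px (block grid 7×7,
  keeping the descriptor length moderate at the reduced resolution);
- filters (8, 16, 32) in both branches; 40 epochs, batch 32,
  Adam lr 10⁻³ with the ×0.5 decay rescaled to every 15 epochs
  (preserving the nominal 200:50 proportion);
- 40 images per class, stratified 70:30 split.

Under these conditions the fused model recovers the five synthetic
classes at ≥95% held-out accuracy. The enhancement comparison on
noise-degraded data (σ = 0.1) is measured on the **image-branch (2-D)
classifier**: enhancement acts on images, and on this synthetic family
the descriptor branch alone nearly saturates the fused model's
accuracy, so the fused comparison would measure seed noise rather than
the enhancement effect. (The reference study reports the
with/without-preprocessing comparison per model — 1-D, 2-D and fused —
so the 2-D row is the faithful analogue.)

## Evaluation

Metrics follow the one-vs-rest count formulas; macro averages are
unweighted class means, micro averages pool counts first. For
single-label multiclass data micro precision = micro recall =
accuracy, which the tests assert. Zero-denominator classes yield 0
with a warning. Cross-validation uses stratified k-fold with a
normal-approximation 95% interval `mean ± 1.96·s/√k` (sample standard
deviation), clipped to [0, 1]; no exact small-k interval is attempted.

Grad-CAM weights each channel of the last 2-D convolution by the
spatial mean of the class-logit gradient and rectifies the weighted
sum; the map is bilinearly upsampled and max-normalized when nonzero.
If the head carries no weight from the image branch the map is
identically zero (asserted).

## Known limitations

- The NumPy network is single-threaded per matmul chain and CPU-bound;
  it is meant for desk-scale experiments, not production training.
- The enhancement stage's CLAHE parameters (8×8 tiles, clip 0.01) are
  conventional defaults, not tuned to any dataset.
- Synthetic classes are stationary textures; conclusions about
  spatially structured lesions rest only on the ellipse cue.
- The 95% CI formula is the normal approximation; at k = 5 it is
  optimistic.
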