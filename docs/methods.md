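# Methods

## Registration model

The registration operator takes a fixed image `f` (right breast) and a
moving image `m` (horizontally flipped left breast), both square,
normalised to [0, 1], and predicts a dense displacement field
φ : pixel → ℝ² in pixels of the fixed frame. The transformed image is
`m∘φ`, sampled bilinearly at `grid + φ` with border clamping, so warped
intensities never leave the input's range and the operator is
differentiable in both the image and the field (verified against finite
differences to < 10⁻⁴ relative error).

The field predictor is a 2-D U-Net over the two stacked images:
stride-2 3×3 convolutional encoder, decoder with nearest-neighbour
upsampling and skip connections, LeakyReLU(0.2) everywhere except the
final flow convolution, which is zero-initialised so the untrained model
is exactly the identity transform. Default channels are encoder
(16, 32, 32, 32) and decoder (32, 32, 32, 32, 32, 16, 16) — the
configuration this model family conventionally uses; a half-width
profile, encoder (8, 16, 16, 16) / decoder (16, 16, 16, 16, 16, 8, 8),
is provided for desk-scale runs at 128×128 and is what the test suite
and acceptance script train.

Because no autodiff framework is assumed, the package carries its own
minimal reverse-mode engine (`mammosub.autodiff`): convolutions as
im2col + batched BLAS matmul (the input gradient of a strided
convolution is computed as a zero-stuffed transposed convolution), the
bilinear sampler with analytic gradients for both arguments, and the
loss terms. Activations are float32; all heavy steps are matrix
multiplications.

## Loss

    L(f, m, φ) = L_mse(f, m∘φ) + λ · L_ppm(φ),     λ = 1

* `L_mse` — mean squared intensity difference over the breast +
  pectoral mask of the fixed frame. Masking applies to the similarity
  term only; each training pair carries its own mask.
* `L_ppm` (per-pixel misalignment) — forward differences of both
  displacement components in each spatial direction; within a direction
  the squared differences are averaged over components and valid
  positions, and the two directional means are summed. Under this
  normalisation a field linear in the column index with slope `c`
  scores exactly `c²/2`, and on [0, 1] images total losses land in the
  10⁻³ range. A zero or constant field scores 0, so the penalty is
  translation-invariant.

Training: Adam (β = 0.9/0.999), initial learning rate 2·10⁻⁴, cosine
annealing per epoch to zero without restarts —
`lr(e) = lr₀ (1 + cos(π e/E))/2`. The validation pass uses the same
masked loss and performs no updates; the best-validation weights are
kept and restored at the end of training. All randomness (weight
initialisation, batch shuffling) flows from one integer seed, so runs
are bit-reproducible on one device.

## Preprocessing

Intensity normalisation divides by the full bit-depth range (65535 for
uint16), never by per-image min/max, so the two sides of a pair stay on
one scale. The breast + pectoralis mask comes from skin-line detection:
Otsu's threshold located on the intensity histogram, then relaxed by a
factor 0.4 toward the background so the faint outer skin falloff stays
inside the mask, followed by largest-connected-component selection,
hole filling and a light closing (pad-replicated at the frame so tissue
touching the image border is not eroded).

Geometry: the image is padded with background (0) on the nipple side to
a square, resized with bicubic interpolation (4×4 neighbourhood) and
centre-cropped, preserving aspect ratio throughout (a circle stays a
circle). The clinical protocol is 2016×2816 → 520×520 → 512×512; other
working sizes keep the same 520:512 ratio (130 → 128 for phantoms).
Masks follow the same chain with nearest-neighbour resampling and
re-binarisation. The pair mask is the fixed-image mask only: the loss
region is defined once, in the fixed frame, which avoids warping a
second mask. Coordinates are row-major and 0-based with the chest wall
at column 0 after flipping.

## Synthetic phantoms

The generator emulates what an MLO view looks like, not how X-rays
propagate:

* **Contour** — semi-ellipse anchored to the chest-wall edge; the scale
  is solved by bisection so the realised mask area matches the requested
  breast-area fraction (within quantisation). The vertical extent may
  clip at the frame (large breasts) but the horizontal extent is capped
  at 0.95·width so the skin line stays visible; fractions that would
  need more are rejected.
* **Pectoral wedge** — triangle in the upper posterior corner, brighter
  than fat, included in the mask (the loss region includes pectoralis).
* **Glandular texture** — Gaussian blobs biased toward the breast
  interior; the glandular mask is cut at the intensity quantile that
  realises the requested gland-content ratio, so the density covariate
  is honoured by construction.
* **Skin line** — intensity falls smoothly to background over ~1.2 % of
  the image width.
* **Thickness** — maps linearly to base tissue brightness
  (0.30 + 0.004·mm, capped), a monotone attenuation proxy sufficient to
  exercise the covariate machinery.
* **Asymmetry** — a zero-mean Gaussian-smoothed white-noise field scaled
  to a target RMS displacement (default 3 px, correlation length
  min(H, W)/2). The correlation length is deliberately breast-scale:
  bilateral MLO asymmetry is dominated by positioning differences —
  residual rotation, stretch, compression — that vary smoothly over the
  whole breast, not by short-wavelength tissue displacement. The scale
  also matters for the loss economics: at λ = 1 the smoothness penalty
  of a field with RMS u and correlation ℓ grows like (u/ℓ)², so a
  rough synthetic field would make substantial deformation cost far
  more than the image term can repay and no similarity-driven method
  could recover it. The left image is the right image warped by the
  (fixed-point-inverted) field and mirrored, so the stored ground-truth
  field maps the flipped-left grid onto the right image, the same
  convention the model predicts. With zero deformation and zero noise
  the flipped left equals the right bit-for-bit.
* **Noise** — independent white Gaussian noise on both sides plus a
  low-frequency texture perturbation on the left (both scale with
  `noise_sd`, default 0.01).

Cohort sampling draws breast area uniformly in [11.1, 79.8] %, gland
ratio in [11.5, 85.0] %, and thickness in [12, 84] mm — the spans of the
clinical test cohort — each case with a child seed derived from the
cohort seed.

What the phantoms do **not** model: X-ray physics and scatter, 3-D
compression mechanics, vendor post-processing, calcifications, skin
folds, and — importantly — the clinical covariate *correlations* (in
real cohorts dense breasts tend to be thinner and smaller; here the
covariates are independent). Passing tests therefore demonstrate that
the pipeline's machinery is correct and that the registration method
recovers smooth synthetic asymmetries; they do not certify clinical
difference-image quality.

## Evaluation

SAD between two images is the mean absolute intensity difference over
the mask on [0, 1] intensities (the normalisation that makes values like
0.05–0.07 comparable across breast sizes). Per case the pipeline
records SAD without registration (fixed vs flipped), SAD with
registration (fixed vs transformed), and their difference, the
improvement.

Quartile subgroups: records are sorted by the covariate — decreasing
for breast area, gland ratio and thickness, increasing for baseline
SAD — with ties broken stably by case id, and split into four contiguous
groups whose sizes differ by at most one (larger groups first; 500 cases
give exactly 4×125). Statistics are nonparametric by default: paired
two-sided Wilcoxon signed-rank within groups (all-zero differences
report p = 1), Mann–Whitney on the improvement between groups with Holm
correction; paired/unpaired t-tests are available behind a flag. Groups
with fewer than two cases omit the statistic with a warning.

## Scaled-down analog experiment

The clinical protocol (1600 cases at 512×512, 800 epochs) is far beyond
a single CPU, so the package defines one fixed desk-scale analog used by
the acceptance tests and `scripts/acceptance.py`: 96 phantom pairs at
128×128 (RMS asymmetry 3 px, correlation 64 px, noise SD 0.01), split
64 train / 8 validation / 24 test following the clinical 1000/100/500
proportions, half-width U-Net, 150 epochs at batch 8, λ = 1, cosine
annealing from 2·10⁻⁴. It reports mean SAD without/with registration,
mean improvement, fraction of improved cases, the paired Wilcoxon p,
and the median endpoint error between predicted and ground-truth fields
(the ground-truth field is pushed through the same resize/crop chain as
the images before comparison; the error is taken over the mask interior,
eroded by 4 px, since the field is unconstrained where there is no
tissue contrast).

## Numerical choices and edge cases

* Warp border policy: clamp (nearest border pixel); no gradient flows to
  sampling coordinates pushed outside the frame.
* Difference images are written as 16-bit PNG with a fixed linear
  [0, 1] → [0, 65535] scale, so files from different cases are
  comparable; round-trip error is at most 1/65535 per pixel.
* Displacement fields persist as 32-bit float two-channel TIFF,
  losslessly.
* A lesion of radius 0 is a no-op; a lesion centre outside the mask is
  an error. The inserted profile is `a·cos²(πr/2R)`, so the centre
  increase is exactly `a` and the support is strictly `r < R`.
* Training aborts with a diagnostic on a non-finite loss rather than
  continuing with poisoned weights.

## Known limitations

* Single resolution, single channel; no diffeomorphic guarantee — large
  fields can fold (the smoothness penalty discourages but does not
  forbid it).
* Amortized deformation recovery at desk scale: under the reduced
  150-epoch schedule the shared model aligns texture locally (hence the
  SAD improvement) but recovers only part of the smooth global
  asymmetry component — per-pair instance optimization of the same loss
  converges to a markedly lower endpoint error than the amortized
  prediction. Closing that gap takes training budgets closer to the
  clinical protocol (hundreds of epochs over hundreds of cases), not a
  wider network: doubling the channel plan or the epochs moves the
  desk-scale endpoint error only marginally.
* CPU-only: the full clinical protocol is supported in code but takes
  hours; the provided profiles are sized for minutes.
* The phantom's thickness→brightness proxy is monotone but arbitrary;
  absolute SAD values from phantoms should not be compared with
  clinical SAD values, only the with/without contrast should.
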