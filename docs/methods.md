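# Methods

## The regression problem

Gestational age (GA) estimation from T2-weighted fetal brain MRI is a
scalar regression problem on image stacks: each subject contributes up to
three anatomical planes (axial, coronal, sagittal), each a stack of 2-D
slices, with a ground-truth age label in days. The difficulty is that the
fetal brain occupies a small, variably positioned part of a noisy maternal
field of view, so a regressor benefits from a mechanism that localizes the
brain without manual segmentation.

## Model

The network has two parallel branches, each a residual CNN ending in a
spatial pooling layer and a fully connected scalar head:

* the **global branch** consumes the full multi-slice input `X`
  (1, 3, or 5 slices centered on the middle slice, as channels);
* the **local branch** consumes the same input multiplied by a soft
  attention mask derived from the global branch.

The mask is computed from the activations `f_k(x, y)` of the global
branch's last convolutional layer (`K` channels; 512 for ResNet-18, 2048
for ResNet-50, 32 for the `tiny` desk-scale family):

    H(x, y) = max_k | f_k(x, y) |

`H` is bilinearly up-sampled to the input resolution, normalized to
[0, 1] with a truncated ReLU (clamp to `[0, c]` then divide by `c`; the
ceiling `c` defaults to the per-sample maximum and may be set to a lower
percentile to blunt single-pixel spikes), and multiplied by a 2-D Gaussian
centered on the image, encoding the prior that the fetal brain lies near
the center of the field of view. The product of the mask with `X` feeds
the local branch. Both branch outputs are trained with MSE against the
true age and their arithmetic mean is the fused prediction; for
multi-plane models, one network per plane is trained under the summed
per-plane loss and the fused per-plane predictions are averaged.

The full mask path is differentiable (the channel max and the
max-normalization route gradients through their argmax; the Gaussian is a
constant), so the local-branch loss back-propagates into the global
branch and the model trains end to end. A `gradient_through_mask=False`
switch detaches the mask for ablation. With the percentile variant of the
ceiling (below 100), the ceiling value itself is treated as a
data-dependent constant outside the gradient path; the default
max-normalization has no such cut.

### Order of attention operations

Normalization is applied *after* up-sampling and the Gaussian product
comes last, with no re-normalization afterwards. With max-normalization
the order of up-sampling and normalization matters only marginally
(bilinear weights are convex, so the up-sampled maximum can sit slightly
below the source maximum); the implementation fixes one order and the
public `attention` functions remain freely composable.

### Choices left open by the architecture

* The two branches do not share weights; a shared-backbone variant was
  not implemented because the two-stack layout is the minimal consistent
  reading of the architecture.
* The fused (branch-averaged) prediction carries no loss term of its own;
  only the two per-branch MSE terms are summed. A `fused_loss_weight`
  exists for ablation.
* Multi-plane training uses three disjoint per-plane networks under one
  summed loss. Because the parameter sets are disjoint and Adam updates
  are per-parameter, optimizing the sum is exactly equivalent to
  optimizing each plane separately with the same schedule; the
  implementation exploits this decomposition. `total_loss` computes the
  literal plane-summed objective for verification.
* **Head pooling is global average pooling by default.** A max-pooled
  head was evaluated first and overfits badly at desk scale (train MAE
  ~3 days against held-out ~20 days in a paired pilot): a single maximal
  activation carries no information about object area, which is the
  dominant age signal at 64 px. Average pooling integrates activation
  area and generalized (held-out R² 0.97 versus 0.64 in the same pilot).
  `pool="max"` remains available.

## Training protocol

* Reference schedule: Adam, learning rate 1e-4, batch 50, 2000 optimizer
  steps ("iterations" are read as optimizer steps, the idiom that pairs
  with a batch size). This is `TrainConfig()`.
* Desk-scale preset (`TrainConfig.desk()`, also the estimator defaults):
  learning rate 1e-2, batch 25, 300 steps, tiny backbone, 64-px inputs.
  The rate was chosen in a pilot (1e-3 underfits in 300 steps) before the
  acceptance experiments were run and applies uniformly to all of them.
* Targets are calibrated, not standardized: each branch head outputs a
  z-scaled value mapped through a fixed affine `y = z*sd + mean` set from
  the training labels, so a freshly initialized network starts predicting
  the cohort mean age. MSE is computed in days².
* Validation R²/MAE are computed every `eval_every` steps; the
  best-on-validation-MAE checkpoint is restored at the end. Whether the
  validation split drove checkpoint selection in the reference protocol
  is unstated; selection on validation MAE is this package's choice.
* Non-finite loss aborts with diagnostics rather than continuing.
* All randomness (phantom rendering, splits, batch sampling, crop
  offsets, initialization) flows from named integer seeds; two CPU runs
  with the same seeds are bit-identical.

### Fine-tuning (site adaptation)

`finetune_split` reserves `floor(0.2 n)` subjects of an external cohort
for adaptation and holds out the rest. Adaptation uses Adam at 1e-5
(batch 5); when the adaptation set has at most 5 samples the rate drops
to 1e-6 (`FinetuneConfig()`; the desk preset scales both rates up by two
decades to match the desk training rate). The monitored early-stopping
quantity is not fixed by the protocol's description; this implementation
monitors the adaptation-set epoch loss with a patience of 5 epochs.
Zero-shot and fine-tuned R²/MAE on the held-out 80% are reported side by
side.

## Evaluation statistics

* **R²** = 1 − SS_res/SS_tot, and **MAE** in days.
* **Lin's concordance correlation coefficient**
  ρc = 2·cov(y, ŷ) / (var(y) + var(ŷ) + (ȳ − ŷ̄)²) with population (1/n)
  moments, Lin's original definition; sample moments are an option.
  The 95% CI applies the Fisher z transform with Lin's asymptotic
  variance of the transformed estimate and back-transforms; the interval
  is clamped to bracket the point estimate (it degenerates at |ρc| = 1).
* **McBride strength-of-agreement**: poor < 0.90, moderate [0.90, 0.95),
  substantial [0.95, 0.99], almost perfect > 0.99. The printed bin edges
  are ambiguous at exact boundaries; the convention here keeps "< 0.90"
  strict and the bins exhaustive.
* **Modified Bland–Altman quantile curves**: pairs sorted by true age; a
  15-point window with 95% overlap (fractional stride rounded up to 1
  point) slides along the age axis; the 5/10/25/50/75/90/95% empirical
  quantiles of (ŷ − y) are taken per window at the window's median true
  age; each quantile series is smoothed with a Gaussian kernel
  (σ = 2 window positions, configurable). Because the smoother is one
  positive linear operator shared across levels, the curves remain
  monotone in quantile level at every evaluation point.

## Preprocessing conventions

* Middle slice of a stack of length L is index ⌊(L−1)/2⌋ (for even L,
  the lower of the middle pair); `select_slices` takes that slice plus
  ⌊n/2⌋ neighbors on each side.
* Images smaller than the crop size are symmetrically zero-padded before
  cropping, so no subject is discarded for size.
* Per-sample normalization uses the joint mean/SD over all slices of a
  slab (not per-slice), preserving inter-slice intensity relations. It is
  idempotent and invariant to positive affine intensity changes — which
  also means a pure contrast rescaling of a site's images is removed by
  preprocessing; domain shift in the phantom experiments therefore comes
  from added noise and ghosting, not from the contrast factor.
* Coordinates are 0-based (row, col) with the origin at top-left.
* Ages are days everywhere inside the package; weeks only at reporting
  boundaries (weeks = days/7).

## The phantom test-bed

`gestage.phantom` generates subjects with a known latent age: a bright
filled ellipse (the "brain") whose semi-axes grow linearly from 8% to 30%
of the image side over the 126–280 day (18–40 week) range, carrying a
sinusoidal internal texture whose spatial frequency grows from 2 to 8
cycles/image (a proxy for progressing gyrification), over a darker
background with 6 clutter ellipses (maternal tissue), additive Gaussian
noise (SD 0.05 in [0, 1] intensity units), and a N(0, 2 px) jitter of the
object center. Three plane stacks (5 slices each; off-center slices
shrink the ellipse as a section through a spheroid would) are rendered
independently per subject, with the analytic middle-slice ellipse stored
as a ground-truth mask. A `skewed` age sampler (5% of mass on the top 15%
of the range) mimics the clinical scarcity of late-third-trimester scans.
`degrade` emulates a different acquisition site: affine contrast scaling,
a shifted low-amplitude ghost blended as (1−a)·img + a·shift(img), and
extra noise.

What the phantom does **not** emulate: anatomy, MR signal physics, motion
between slices, 3-D consistency across planes, or the intensity
distributions of any scanner. Passing the phantom experiments shows that
the architecture, attention mechanism, optimization, and statistics are
implemented correctly and can recover a size/texture-coded latent age
under clutter and domain shift — it says nothing quantitative about
performance on real fetal MRI.

## Scaled-down study conditions

The learning experiments run at desk scale on one CPU: tiny backbone,
64-px inputs, 3-slice slabs, 400-subject cohorts with a 70/10/20
subject-level split, 300 optimizer steps (multi-plane recovery), 200
subjects/250 steps for the paired clutter comparison, and a 100-subject
degraded external cohort for fine-tuning. These sizes are the package's
chosen reference conditions for its own validation suite; the published
protocol (ResNet-50, 224-px, 741 subjects, 2000 steps) is expressible
through the same configuration objects but is not exercised by the tests.

## Numerical notes

* Training runs in float32; a module-wide dtype switch
  (`gestage.nn.tensor.set_default_dtype`) enables float64 for
  finite-difference gradient verification.
* Bilinear up-sampling uses half-pixel sample centers (corner alignment
  disabled); interpolation weights are convex, so up-sampled values never
  leave the source range.
* An all-zero raw heatmap normalizes to all zeros instead of erroring, so
  degenerate early-training feature maps cannot halt training.
* Channel-max and max-pool gradients follow the first argmax on ties.
* Quantized exports: 16-bit NIfTI, 8-bit PNG; floats in [0, 1] in memory.

## Known limitations

* The NumPy network core is CPU-only and single-threaded; paper-scale
  ResNet-50 training is architecturally supported but computationally
  impractical here.
* Externally supplied backbone weights are loaded from `.npz` state
  dictionaries (with first-convolution channel adaptation: mean kernel
  replicated and rescaled by 3/C); no pretrained weights ship with the
  package, and nothing in the validation suite depends on them.
* The attention mechanism's benefit is demonstrated directionally on
  cluttered phantoms; effect sizes on real data cannot be inferred from
  the phantom.
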