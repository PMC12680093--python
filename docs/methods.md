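# Methods

## The classification problem

`neurofuse` classifies paired brain-MRI volumes into three diagnostic
classes — normal, benign tumor, malignant tumor — from two modalities
acquired on different grids: diffusion-weighted MRI (DWI) as three b-value
volumes (b0, b500, b1000) at D×H×W = 18×256×256, and T2-weighted MRI at
18×512×512 (same slices, twice the in-plane resolution). The architecture
fuses the two modalities late, after modality-specific volumetric feature
extraction, with an attention step that gates region tokens jointly across
modalities.

## Pipeline

1. **HFIR (High-Frequency Information Retention).** The T2 volume is
   brought onto the DWI grid without a lossy resize: a per-slice 3×3
   convolution lifts the single channel to C=16 shallow feature channels, a
   second 3×3 convolution reduces to C/r² = 4, and a pixel-unshuffle
   (space-to-depth) with r=2 moves each 2×2 spatial block into 4 channels.
   The unshuffle is a pure index bijection
   `out[b, c·r²+Δh·r+Δw, d, i, j] = in[b, c, d, i·r+Δh, j·r+Δw]`
   (row-major polyphase order), so the downsampling itself discards
   nothing; what the two linear convolutions route through it is learned.
   No nonlinearity sits between the convolutions by default (a config
   switch inserts one); 18×512×512 maps to a 16-channel 18×256×256 volume.

2. **Dual 3D ResNet-18 branches.** Two independent (no weight sharing)
   basic-block residual networks — widths 64/128/256/512, two blocks per
   stage, batch or instance normalization — extract layer-4 feature maps of
   512 channels. The in-plane stride plan is the 2D ResNet standard (stem
   /2, pool /2, stage strides 1,2,2,2); through-plane, the stem and pool
   keep depth and the stages stride (1,1,2,2) with depth padding
   (1,1,1,0), taking 18 slices to 4 (18 → 18 → 9 → 4). Projection
   shortcuts use a (3,1,1) kernel with the block's depth padding so both
   paths of a downsampling block agree on output size for every input the
   stride arithmetic admits; a (1,1,1) shortcut kernel would give depth 5
   where the residual path gives 4. With these choices a (18,256,256)
   input yields the (512,4,8,8) layer-4 map on both branches. The stride
   plan is exposed as data (`BackbonePlan`) and validated by pure integer
   arithmetic (`shape_plan`) before any forward pass.

3. **Adaptive Region Attention (ARA).** Both layer-4 maps are flattened to
   region-token sequences (token = one voxel of the feature grid, C
   channels). Tokens are depth-major over the full 3D grid (P = D·H·W =
   256), the only lossless flattening of a volumetric map; a
   `tokens="hw-slicewise"` option gates each depth slice independently
   instead — since the gate acts per token the two layouts are the same
   arithmetic on different batching, and a test asserts their equality.
   The concatenated token f = [fT2, fDWI] (2C channels) passes through a
   shared bottleneck Γ = σ(ReLU(f·Φ1 + b1)·Φ2 + b2) with Φ1 ∈ R^{2C×C/2},
   Φ2 ∈ R^{C/2×2C}; Γ splits into per-modality gates and each branch gets
   a residual rescale αm = Γm⊗fm ⊕ fm = (1+Γm)·fm. Gates in (0,1) can
   only amplify (at most 2×), never flip or suppress a feature — a
   property test asserts sign preservation and |f| ≤ |α| ≤ 2|f|.
   The bottleneck width is C/2 (a 4× reduction of the 2C input), matching
   the weight shapes above.

4. **Classification head.** The attended sequences are concatenated
   channelwise, restored to a (2C, D4, H4, W4) volume, and classified by
   dropout (p=0.5) → 1×1×1 convolution to 3 channels → global average
   pool. No rectification follows the classifier convolution: ReLU'd
   logits cannot go negative, which breaks cross-entropy; an optional ReLU
   on the fused features *before* the convolution is available
   (`head_relu`). Conv-then-pool and pool-then-conv commute for a 1×1×1
   kernel; conv-then-pool is implemented.

Five variants cover the ablation lattice (`dwi_only`, `t2_only`,
`t2_hfir_only`, `concat_no_ara`, `full`); `transfer_shared_weights` copies
parameters between variants wherever the architectures overlap so
ablations can share branch weights.

## Numerical engine

No deep-learning framework is used: `neurofuse.nn` is a compact
reverse-mode autodiff over numpy arrays, sufficient for the layers above
(3D convolution, max pooling, batch/instance normalization, linear layers,
dropout, pixel shuffling, softmax cross-entropy) plus AdamW with decoupled
weight decay and cosine annealing. Two implementation notes:

* 3D convolution is column-built im2col: one strided copy per (channel,
  kernel-offset) pair into a transposed patch matrix, then a single BLAS
  GEMM; the backward pass reuses the same patch construction for the
  weight gradient and a col2im scatter for the input gradient. Patch
  matrices are chunked along output depth (≤ 256 MB scratch) and held in a
  reusable arena — with fresh allocations, page faults on
  activation-sized buffers cost more than the arithmetic. For the same
  reason the package raises glibc's malloc trim/mmap thresholds at import.
* Every op's gradient is verified against central finite differences in
  the test suite (float64, relative error ≲ 1e-9); the HFIR block is
  additionally checked end-to-end at the 1e-4 tolerance its contract
  states.

Gradients accumulate on every graph node, not only leaves, which is what
lets Grad-CAM read ∂logit/∂activation off an intermediate layer without a
separate hook mechanism.

## Grad-CAM

For a chosen branch (default DWI, where the clinical overlays live) and
target class, channel weights are the global average of the logit's
gradient over the layer-4 activation; the CAM is the rectified
channel-weighted sum, max-normalized to [0,1] when nonzero, and
trilinearly upsampled to the input grid. Two details matter in practice:

* **Alignment.** The conv plan is corner-aligned (feature voxel *j* sits
  at input voxel *j*·stride), so the upsample interpolates at feature
  coordinate *p*/stride rather than on a half-cell-shifted zoom grid — a
  half-cell misalignment is several voxels on the input grid, enough to
  move a peak out of a small lesion.
* **Tap selection.** Besides the per-branch layer-4 maps (and earlier
  stages via ``stage``), the attention-gated maps (``dwi_attended``,
  ``t2_attended``) can be read. Because the head is a 1×1×1 convolution
  followed by global average pooling, the gradient of a logit with
  respect to an attended map is spatially uniform, so its Grad-CAM equals
  the model's rectified pre-pool class-evidence map exactly — the
  sharpest faithful localization signal the architecture offers, and the
  one the localization checks use.

Eval-mode determinism makes CAMs reproducible bit-for-bit. A caveat the
localization tests surfaced: on desk-scale cohorts, which features a
trained model uses (lesion-local vs. volume-global after per-volume
normalization) varies with the training seed, and CAM peak placement
varies with it; localization checks on small phantoms probe a property
that holds for well-fit models but is not guaranteed by classification
accuracy alone.

## Training protocol

Patient-level leave-one-out cross-validation: one fold per patient, the
held-out patient's scans never seen in training (asserted at fold
construction *and* again before training). Per fold, a freshly seeded
model is trained from scratch — AdamW, learning rate 1e-3, cosine
annealing to zero over the epoch budget, batch size 8, cross-entropy,
dropout 0.5 before the classifier. Weight decay (1e-4) and the epoch
budget (50 for the full preset) are not stated by the protocol this
follows; they are this package's defaults and are surfaced in
`TrainConfig`. Inputs are z-scored per channel per volume (standard for
arbitrary scanner units) with a zero-variance guard. All randomness —
initialization, batch order, dropout masks, per-fold seeds — derives from
one root seed; two runs with the same seed produce identical predictions.
Optional geometric augmentation (`TrainConfig.augment`) applies random
in-plane flips — and, in `"flip-shift"` mode, coherent circular in-plane
shifts — identically to both modalities; `"flip"` is the default.

## Synthetic phantom cohort

The clinical dataset the architecture was designed around (70 patients:
20 normal, 22 benign, 28 malignant) is private, so a generator produces
cohorts with its geometry and class structure: an ellipsoidal "brain" with
a smooth radial intensity profile and Gaussian noise (σ = 0.02 in
arbitrary [0,1] intensity units by default), into which lesions are
rendered:

* **benign** — smooth ellipsoid, boundary irregularity ≤ 0.2, bright on
  T2 (+0.30), mild b1000 contrast (+0.10);
* **malignant** — boundary perturbed by low-order spherical harmonics
  (irregularity 0.5–0.8), strongly b1000-hyperintense (+0.35, the
  diffusion-restriction analogue), milder on T2 (+0.15);

each jittered ±20% per patient, with in-plane radius 8–14% of the image
size, placed rejection-sampled inside the brain. With σ=0 the cohort is
separable by construction — lesion presence separates normal from tumor
and mean b1000 lesion contrast separates benign from malignant — which is
the learnability guarantee behind the training sanity checks.

What the phantom does **not** emulate: MRI physics (no Rician noise, no
bias fields, no partial-volume effects), skull/air interfaces,
co-registration error between modalities, or anatomical texture. Passing
tests therefore demonstrate that the pipeline is implemented correctly and
can learn class structure from multimodal volumetric contrast — not that
it reaches any particular accuracy on clinical data.

## Desk-scale (tiny) preset

Full-resolution LOOCV training is not CPU-scale, so tests and the
acceptance run use a reduced preset chosen once:

* phantom grids 8×64×64 (DWI) / 8×128×128 (T2), 12 patients (4 per
  class), noise-free;
* backbone widths (4,8,16,32), HFIR C=8, and a relaxed stride plan
  (spatial stage strides (1,2,1,1), depth (1,1,2,1)) so that the reduced
  input grid reaches the same printed (4,8,8) layer-4 geometry as the
  full-size plan — region-token count, attention shapes and Grad-CAM
  granularity all match the full model; block structure and fusion path
  are unchanged;
* instance normalization instead of batch statistics: with ~100 optimizer
  steps per fold, batch-norm running averages never burn in, while
  instance statistics behave identically in train and eval;
* dropout disabled: at this step budget the full preset's 0.5-dropout
  noise prevents convergence altogether (training loss plateaus near
  chance); regularization comes from augmentation instead;
* random flip augmentation (`augment="flip"`): in-plane flips applied
  coherently to both modalities — the phantom classes are flip-invariant,
  and with three training examples per class the invariance has to be
  supplied, not learned. A `"flip-shift"` mode adds coherent in-plane
  circular shifts (T2 at twice the DWI offset) but needs a longer
  schedule than the preset budget;
* 20 epochs, batch size 4 (more optimizer steps per epoch at this cohort
  size).

Even so, held-out LOOCV accuracy on 12 phantoms sits near the
learnability boundary: with three training examples of a class whose
lesion position, size and contrast are randomized, fold-level
generalization is genuinely hard, and different training seeds can move
which fold (if any) fails.

## Statistics

Point metrics are computed from the 3×3 confusion matrix (rows = true):
accuracy, one-vs-rest sensitivity/specificity/F1 per class, and their
unweighted macro averages — macro because the protocol prints single
overall values for a 3-class task whose overall sensitivity sits far below
accuracy, which weighted micro-averaging could not produce. Classes absent
from the truth of a (re)sample are excluded from macro means and flagged.
Cohen's κ = (po − pe)/(1 − pe) is defined as 0 when pe = 1.

Uncertainty uses the percentile bootstrap: 10,000 resamples of the patient
records with replacement, CI = (2.5th, 97.5th) percentiles of the
statistic; both the resample mean and the full-sample statistic are
reported. Model comparisons use paired resampling — one index multiset
applied to both prediction sets per resample — and report whether the
difference CI excludes zero. Prediction files are plain CSV
(`patient_id,true,pred`), so external models' predictions can be compared
without reimplementing them.

Degenerate inputs are defined, not crashed on: zero-variance volumes
normalize to zero, single-class resamples flag undefined sensitivities,
empty predicted classes still have specificity.

## Known limitations

* The phantom's simplicity means learned models key on intensity contrast;
  no claim transfers to clinical data.
* The depth stride plan is one consistent realization of the printed
  layer-4 endpoint; the original network's exact plan is not public.
* Batch-norm mode with LOOCV batch-size-1 evaluation relies on running
  statistics; the instance-norm switch exists precisely because those are
  unreliable at desk scale.
* The autodiff engine is single-threaded CPU; full-resolution *training*
  (as opposed to forward shape checks) is out of scope.
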