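# Methods

## Scope and model

The package corrects per-phase undersampled 4D-CBCT by image-to-image
translation into synthetic CT.  The model is a cycle-consistent GAN with a
patch-contrastive (NCE) regulariser on encoder features:

- **Generators** G_SN (streaked domain S → clean domain N) and G_NS, each:
  7×7 stem conv → two stride-2 3×3 convs (3 encoder stages, channels
  c, 2c, 4c) → nine residual blocks at 1/4 resolution → two
  nearest-upsample + 3×3 conv stages and a 7×7 output conv with tanh
  (3 decoder stages).  Instance normalisation (no affine) throughout —
  appropriate for batch size 1.  Nearest-neighbour upsampling + conv is
  used instead of transposed convolution to avoid checkerboard artifacts;
  the layer count is unchanged.
- **Discriminators** D_N, D_S: four stride-(2,2,2,1) 4×4 conv layers plus
  a 1-channel output conv, emitting a patch logit map (receptive field
  ≈ 70 px).  *No normalisation inside the discriminators*: per-image
  normalisation would cancel exactly the global CT-number depression the
  adversarial signal must detect for HU correction; without it the
  mean-error convergence of the generator is several times faster at desk
  scale.
- **Projection heads**: one 2-layer MLP per encoder stage (shared between
  the two directions), L2-normalised output embeddings (default dim 256;
  desk preset 64).

## Losses

`L_total = λ1·L_cont + λ2·L_cyc + λ3·L_adv + λ4·L_freq` with
λ = (2, 1, 1, 0.01) and τ = 0.07.  All reductions are means over
pixels/patches/batch; all logs are natural.

- **Contrastive**: for each of `n_patches` sampled locations per encoder
  layer, the query is the embedding of the *generated* image at that
  location and the positive is the embedding of the real image at the same
  location through the same encoder; the other `n_patches − 1` locations
  provide the negatives (`sim(u,v) = exp(cos(u,v)/τ)`, cross-entropy over
  the softmax of similarities).  Two schemes are available:
  - `contrastive_keys="paired"` (default): positives come from the paired
    real *target* image (the registered CT for direction S→N).  This uses
    the paired training data directly and converges markedly better at
    desk scale (held-out MAE 88 vs 106 HU after 300 iterations in our
    calibration experiment).
  - `contrastive_keys="self"`: positives from the generator's own input —
    the scheme usable with unpaired data.
  The loss is applied symmetrically for both directions and averaged.
- **Adversarial**: sigmoid patch scores with the non-saturating generator
  objective `−E[log D(G(x))]` by default (`adversarial_mode="lsgan"` gives
  the least-squares variant).  The reporting function `adversarial_loss`
  evaluates the classic two-term value `E[log D(real)] + E[log(1−D(fake))]`.
- **Cycle**: mean per-pixel L1 of both round trips S→N→S and N→S→N.
- **Frequency**: mean over frequency bins of `|DFT2(cycle residual)|²`
  with the unnormalised forward DFT.  By Parseval's theorem this equals
  `H·W ×` the pixel-domain MSE of the residual; the forward pass evaluates
  the DFT and the tests verify the constant exactly.

## Training

Adam with lr 2·10⁻⁴, β1 = 0.5, β2 = 0.999, batch size 1, 100 epochs (or a
fixed iteration budget), no learning-rate decay.  Each iteration updates
the discriminators first (current fakes, detached), then generators and
heads jointly on the total loss.  Paired random crops and paired random
horizontal flips (p = 0.5) augment the data; one root seed drives model
initialisation (Gaussian, sd 0.02), data order, crops, flips and patch
sampling, so a fixed-seed trajectory is bit-reproducible and resumable
from checkpoints.  The networks run on a small NumPy reverse-mode autodiff
engine (`cyclesct.nn`) whose gradients are verified against finite
differences in the test-suite; batch-1 stride-1 convolutions use a
kernel-offset accumulation fast path (~3× faster than im2col at 64×64 on
one CPU).

Desk preset (`TrainConfig.desk_preset`): 64×64 crops, base_channels 16,
n_patches 64 (k = 63), embedding dim 64, 300 iterations — about two
minutes on one CPU.

## The synthetic world

`cyclesct.phantom` renders a 2-D axial thorax phantom (body, two lungs,
spine, ribs, a lung tumor) in HU, with a raised-cosine respiratory cycle
over 10 phases (phase 0 = end-inspiration): the tumor and a diaphragm line
displace by `A·(1 − cos(2πp/n))/2`, default amplitude 8–12 mm per subject.
The "CT" is the analytic raster (a 720-angle reconstruction is available);
the "CBCT" surrogate is: linear HU→attenuation mapping (water
μ = 0.02 mm⁻¹, negative μ clipped), parallel-beam Radon transform at few
angles, ramp-filtered back projection (scikit-image, linear
interpolation), a global HU offset plus radially quadratic cupping, then
Gaussian noise — all seeded.

Degradation defaults (60 angles over 360°, offset −300 HU, cupping
+80 HU at the field corner, noise sd 40 HU) are **calibrated to the
observed-degradation regime of real 4D-CBCT**, i.e. a mean error near
−117 HU against ground truth.  Because air is already at the −1000 HU
floor and clips, the *applied* in-body offset must be about −300 HU for
the *observed* global mean error to land near −113 HU; the resulting
desk-phantom CBCT has MAE ≈ 132 HU and SSIM ≈ 0.93.  Note that in
parallel-beam geometry angles θ and θ+180° are redundant, so 60 angles
over 360° are 30 unique views.

What a green desk test does and does not establish: the synthetic world
has piecewise-constant anatomy, no scatter, detector lag, beam hardening,
breathing irregularity or registration error, and 2-D parallel-beam rather
than cone-beam geometry.  Passing shows the pipeline learns to remove the
modelled degradations end-to-end with the published hyperparameters; it
does not certify clinical-scale image quality.

## Evaluation conventions

- **SSIM** is computed from *global* image statistics (one value per
  image, no sliding window) with constants C1 = (0.01·2000)² = 400 and
  C2 = (0.03·2000)² = 3600 HU², matching the printed formula this suite
  reproduces; a windowed variant and constants based on the 4095 dynamic
  range are available via arguments.  Note the global form has no
  cross-covariance term, so it compares means and variances only.
- **PSNR** uses the evaluated image's own max |X| as peak by default (the
  printed formula), with a fixed-4095 peak option; zero MSE reports +inf
  with a flag rather than raising.
- **MI**: 256 equal-width bins over [−1000, 3095] HU, natural logs,
  0·log 0 := 0.  `MI(x,x) = H(x)` exactly under shared binning.
- **ROI analysis**: square ROIs with per-tissue default sizes (lung 35,
  bone 15, soft tissue 25, tumor 15 px); ROIs are caller-supplied, as
  manual delineation is in practice.
- **DVH**: Dx% is the minimum dose to the hottest x% of the structure,
  linearly interpolated on the sorted cumulative volume; VyGy is the
  percent of structure volume receiving ≥ y Gy (dose grids are cGy).
- **Paired t-tests**: two-sided, significant iff p < 0.003 (a
  Bonferroni-corrected cutoff; the threshold is configurable since the
  number of hypotheses behind it is context-dependent).  All-zero
  differences report p = 1 (not significant, flagged degenerate); a
  constant non-zero difference reports p = 0 (flagged).
- **RPD** = |A − F| / ((A+F)/2) × 100 with A the reference value;
  A + F = 0 reports NaN with no exception.

## Numerical choices and degenerate inputs

- HU values are clipped to [−1000, 3095] (dynamic range 4095) at every
  volume construction; the normalisation window [−1000, 3095] → [−1, 1]
  is the network input scale.
- FBP validation requires detector bin count = output grid size; empty
  angle lists, non-increasing angles, out-of-range phases, oversized
  crops/ROIs, empty masks and zero-length manifests raise `ValueError`;
  missing/corrupt files raise `IOError`.
- Checkpoints are single `.npz` archives with a JSON metadata header
  (weights, spec records, optimizer state, RNG state, loss history);
  loading a corrupt or version-mismatched file raises rather than
  silently resetting.

## Known limitations

- 2-D slice phantoms and parallel-beam projection stand in for cone-beam
  geometry; no scatter or motion-within-phase modelling.
- DICOM series I/O is not included (no DICOM library in the supported
  environment); volumes are NIfTI.
- Deformable registration is out of scope: real CT/CBCT pairs must be
  registered upstream; synthetic pairs are constructed aligned.
- The exact full generator is not translation-equivariant near borders
  (the residual trunk's receptive field reaches the border from
  everywhere); the encoder is, and the output field translates to small
  median deviation.
- Dose *computation* is out of scope; DVH metrics operate on a supplied
  dose grid with structure masks.
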