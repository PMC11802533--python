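# Methods

## Problem and approach

Dynamic contrast-enhanced (DCE) myocardial perfusion MRI must resolve the
first pass of a contrast bolus — one image per heartbeat per slice — which
forces a trade-off between spatial resolution, temporal resolution and slice
coverage. Acquiring only a central band of phase-encoding lines shortens the
per-slice acquisition (a 35% phase resolution is a 1/0.35 ≈ 2.86-fold gain,
and ≈ 5.7–8.6-fold when compounded with GRAPPA 2–3) at the cost of blur and
ringing along the phase-encoding axis. `perfdiff` restores the lost spatial
detail with a conditional denoising diffusion probabilistic model (DDPM):
a U-Net is trained to predict the noise in a corrupted high-resolution (HR)
frame while being conditioned on the co-registered low-resolution (LR)
frame, and sampling runs the learned reverse process from pure noise to a
super-resolved frame. Each frame is processed independently — no temporal
regularization — so temporal fidelity is preserved by construction.

## Diffusion model

With per-step retention factors `alpha_t = 1 - beta_t` and
`gamma_t = prod_{i<=t} alpha_i`, the forward process is

    q(y_t | y_{t-1}) = N(sqrt(alpha_t) y_{t-1}, (1 - alpha_t) I),
    q(y_t | y_0)     = N(sqrt(gamma_t) y_0, (1 - gamma_t) I),

and the reverse update, parameterized by the noise prediction
`f(x, y_t, gamma_t)`, is

    y_{t-1} = ( y_t - (1 - alpha_t)/sqrt(1 - gamma_t) * f ) / sqrt(alpha_t)
              + sqrt(1 - alpha_t) * z,

with `z ~ N(0, I)` during sampling (omitted at t = 1) and reverse variance
fixed at `1 - alpha_t`. Training minimizes the L1 distance between the
predicted and the injected noise at a random noise level.

Choices where the formulation leaves room:

* **Schedule** — linear `beta` from 1e-6 to 1e-2 over T = 2000 steps; this
  drives `gamma_T ≈ 4.5e-5`, i.e. the terminal state is indistinguishable
  from pure noise. The desk-scale schedule (T = 100, 1e-4 → 0.2) matches
  that terminal condition at 20× fewer steps.
* **Noise-level draw during training** — `t` uniform in {1..T}, using the
  discrete `gamma_t` (a piecewise-uniform continuous mode is available via
  `continuous_gamma`).
* **Stabilization** — at each reverse step the implied one-step estimate of
  the clean image is clipped to [-1, 1] before the mean is recomputed
  (`clip_y0`, on by default in sampling); early-step predictions can
  otherwise overshoot the data range. No noise is injected at the final
  step: it would only add variance to the returned image.

## Degradation operator

LR/HR pairs are synthesized from HR magnitude frames: FFT to a DC-centered
k-space grid, retention of `round(fraction * N_pe)` contiguous central
phase-encoding lines (zero elsewhere; readout untouched), inverse FFT,
magnitude. The retained band is symmetric about the DC index for odd counts
and puts the extra line on the lower-index side for even counts, so DC is
always kept. Per training pair the fraction is drawn uniformly from
[0.30, 0.50] — the dynamic degradation doubles as augmentation — and both
images are cropped to a common window around the heart.

Normalization is per series, not per frame: both images are divided by the
HR series' global maximum and mapped affinely to [-1, 1]. Per-frame min-max
scaling would distort the signal-time curves that the temporal evaluation
relies on. Joint random horizontal/vertical flips (each p = 0.5) are applied
on the fly during training.

## Denoiser architecture

The noise predictor is a U-Net consuming the LR image concatenated
channel-wise with the noisy image (2 channels in, 1 out). Five levels with
channels [64, 128, 256, 512, 512]; each encoder level holds two residual
blocks (group norm → SiLU → 3x3 conv, a per-channel noise-level bias, group
norm → SiLU → dropout 0.2 → 3x3 conv, residual sum); downsampling is 2x2
average pooling, upsampling nearest-neighbour plus convolution. Every
encoder feature (including the stem and the pooled tensors) is pushed onto
a skip stack; each of the three decoder blocks per level pops and
concatenates one. The bottleneck interleaves a single-head spatial
self-attention block (1x1-convolution query/key/value and output projection,
softmax over positions) between two residual blocks. The noise level enters
as a sinusoidal embedding of `sqrt(gamma)` refined by two linear layers and
projected per block. This instantiates 91.1M trainable parameters at 96x96.
Group counts are `min(32, channels)` reduced to the largest divisor; the
second convolution of each block and the attention output projection start
near zero so fresh blocks act close to the identity — initialization otherwise follows
Kaiming scaling.

The network runs on `perfdiff.nn`, a self-contained reverse-mode autodiff
engine on NumPy arrays (im2col convolutions, fused-padding gather, AdamW,
global-norm clipping), written for portability and bit-reproducibility:
every stochastic operation is a pure function of an explicit
`numpy.random.Generator`, so training, checkpoint resumption and sampling
are exactly repeatable across runs.

## Training

AdamW (decoupled weight decay 1e-4; biases and normalization parameters
excluded from decay), learning rate 3e-5, gradient clipping at global norm
1.0, constant learning rate. Full-scale defaults: 50,000 iterations at batch
128. Splits are at subject level (default 80:20), so no subject contributes
frames to both splits. Checkpoints carry parameters, optimizer moments and
the RNG state for bit-exact resumption. An exponential moving average of
weights is available but off by default.

## Synthetic phantom

No public perfusion series accompanies this problem, so all experiments run
on a synthetic short-axis first-pass phantom: an RV blood-pool ellipse, an
LV blood-pool disk and a concentric myocardial annulus on a quiet
background. Each compartment follows a gamma-variate bolus
`baseline + A ((t-t0)/(k*s))^k exp(k - (t-t0)/s)` — the standard first-pass
tracer shape, chosen because its peak time `t0 + k*s` is analytic — with
onsets ordered RV → LV → myocardium and peak enhancements 1.0 / 0.9 / 0.35
a.u. over a 0.1 a.u. baseline (myocardial enhancement is a fraction of the
blood-pool signal). Noise is additive Gaussian on the magnitude image
(sigma 0.02 a.u. by default, ≈ 2% of the LV peak). Optional features:
angular perfusion-defect sectors with reduced amplitude, and rigid ±2 px
per-frame translation emulating free breathing (off by default).

What the phantom does **not** emulate: MR physics (saturation-recovery
signal curves, T1 dynamics, coil sensitivities, Rician noise floors),
realistic anatomy, through-plane motion, or dark-rim artifacts beyond the
Gibbs ringing the truncation itself produces. Passing tests therefore
demonstrate that the pipeline is implemented correctly and that the model
can learn the truncation-inversion task — not clinical performance on
patient data.

## Evaluation

nRMSE divides the RMSE by the reference dynamic range and is reported in
percent. PSNR follows the 255-peak convention: both images are first
affinely rescaled so the *reference* spans 0–255 (the same pair feeds SSIM
for consistency), and identical images return a documented 200 dB cap.
SSIM uses the luminance/contrast/structure product with
`c1 = (0.01*255)^2`, `c2 = (0.03*255)^2`; the default evaluates one global
window (matching the definition as a single statistic), a sliding 11x11
Gaussian (sigma 1.5) mode is available and flagged in reports. Temporal
fidelity is read from ROI signal-time curves (mean intensity per frame per
compartment) and x-t profiles (one spatial line stacked over time). Paired
two-sided t-tests (and Wilcoxon signed-rank) compare per-frame metrics
between methods at alpha = 0.05; zero-variance inputs return a flagged
non-result. The protocol calculator reports
`grappa_factor / phase_fraction`.

## Desk-scale experiment

The CPU-scale end-to-end experiment (`run_desk_experiment`) uses 10 phantom
subjects at 32x32 with 25 frames each (≈ 200 training pairs after the 80:20
split), the desk U-Net (channels [16, 32, 64], one residual block per level
— ample capacity for piecewise-constant phantom anatomy at a fraction of
the cost), a T = 100 schedule, and 2,000 AdamW iterations at batch 16 with
learning rate 1e-3: the full-scale 3e-5 is calibrated for 50,000 iterations
at batch 128, and within a 25× shorter run the optimizer needs much larger
steps — at 3e-5 the model learns only the trivial high-noise behaviour
(predicting the noisy input back) and never exploits the LR conditioning,
so sampling cannot beat zero-padding. Gradient clipping keeps the larger
steps stable; the preset was calibrated on scaled-down phantom runs.

Desk-scale sampling follows the noise-free mean trajectory
(`inject_noise=False`). Compressing the noising process into 100 steps
forces per-step `beta` up to 0.2, i.e. reverse noise injections of
`sigma = sqrt(beta) ≈ 0.45` — large enough that ancestral sampling with a
2,000-iteration model fails stochastically on a subset of frames, while the
mean trajectory is robust. At the full-scale setting (T = 2000,
`beta ≤ 0.01`) this pathology does not arise and `sample()` keeps noisy
ancestral updates as its default.
Held-out subjects are degraded at the prospective 35% fraction,
super-resolved, and compared with zero-padded LR against the HR reference
(≥ 20 frames): the pipeline must beat zero-padding on mean PSNR and produce
signal-time curves closer to the reference. The run takes roughly 20
minutes on one CPU core.

## Numerical notes and limitations

* All network arithmetic is float32; metric and k-space computations are
  float64. FFTs use the unnormalized-forward/normalized-inverse convention.
* `retained_line_count` rounds half away from zero and keeps at least one
  line (DC).
* The evaluation rescales with the reference's range; a constant reference
  raises rather than silently returning infinities.
* Sampling at the full T = 2000 on 96x96 images is supported but slow on
  CPU; the desk schedule is the practical configuration here.
* The engine implements only what the U-Net needs (stride-1 square
  convolutions, factor-2 resampling); it is not a general-purpose framework.
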