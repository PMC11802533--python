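# perfdiff

Conditional diffusion super-resolution for dynamic contrast-enhanced (DCE)
myocardial perfusion MRI.

First-pass perfusion imaging must capture a contrast bolus transiting the
heart — one image per heartbeat per slice — so spatial resolution, temporal
resolution and slice coverage compete for the same acquisition window.
Acquiring only the central 30–50% of phase-encoding lines accelerates the
scan (1/0.35 ≈ 2.86-fold at 35% phase resolution; ≈ 5.7–8.6-fold when
compounded with GRAPPA 2–3) but blurs the image along the phase-encoding
axis. `perfdiff` restores the lost resolution with a conditional denoising
diffusion probabilistic model (DDPM): a U-Net noise predictor
`f(x, y_t, γ_t)` is trained on synthetic low-resolution / high-resolution
(LR/HR) pairs and sampling iteratively refines pure Gaussian noise into a
high-resolution frame, conditioned on the zero-padded LR frame. Each frame
is processed independently, so signal-time curves are not smoothed by any
temporal regularization.

The model: with a variance schedule `β_t`, `α_t = 1 − β_t`,
`γ_t = ∏ α_i`, the forward process corrupts the HR target as
`y_t = √γ_t · y_0 + √(1−γ_t) · ε`, and the learned reverse update is

    y_{t−1} = ( y_t − (1−α_t)/√(1−γ_t) · f(x, y_t, γ_t) ) / √α_t + √(1−α_t) · z.

Training minimizes `‖f(x, √γ y_0 + √(1−γ) ε, γ) − ε‖₁`.

The package is aimed at researchers prototyping generative super-resolution
for dynamic cardiac MRI: it bundles a synthetic first-pass perfusion
phantom (three compartments with gamma-variate kinetics peaking RV → LV →
myocardium), the k-space phase-line truncation pipeline that synthesizes
training pairs, the diffusion core, a conditional U-Net (91M parameters at
the full scale; a desk preset for CPU experiments) running on a
self-contained NumPy autodiff engine, training/inference orchestration, and
the evaluation stack (nRMSE / PSNR / SSIM, signal-time curves, x-t
profiles, paired tests, protocol arithmetic). See `docs/methods.md` for the
modelling details and design decisions.

## Worked example

The pieces compose as follows (phantom subjects → LR/HR pairs → training →
sampling → metrics):

```python
from perfdiff import (PhantomConfig, generate_series, degrade_series,
                      assemble_dataset, make_schedule, UNetConfig,
                      TrainingConfig, train, infer_series, evaluate_series)

subjects = {f"s{i:02d}": [generate_series(PhantomConfig(
    matrix_size=32, n_frames=25, seed=1000 + i))] for i in range(10)}
dataset = assemble_dataset(subjects, fraction_range=(0.30, 0.50), seed=1)
schedule = make_schedule(T=100, beta_start=1e-4, beta_end=0.2)
model, losses = train(dataset, UNetConfig.desk(seed=1), schedule,
                      TrainingConfig.desk(seed=1))
lr, hr = degrade_series(subjects[dataset.test_subjects[0]][0], 0.35)
sr = infer_series(model, lr, schedule, seed=7919, inject_noise=False)
print(evaluate_series(sr, hr).summary())
```

`run_desk_experiment` bundles exactly this pipeline, evaluates every
held-out frame and adds the comparison statistics:

```python
import numpy as np
from perfdiff.training import run_desk_experiment
from perfdiff.evaluation import ProtocolParams, nominal_acceleration

res = run_desk_experiment(seed=1)
print("held-out frames:", res["n_eval_frames"])
print(f"PSNR  SR vs HR: {res['psnr_sr'].mean():.2f} dB")
print(f"PSNR  LR vs HR: {res['psnr_lr'].mean():.2f} dB")
print(f"curve deviation SR {np.mean(list(res['curve_dev_sr'].values())):.3f}"
      f" vs LR {np.mean(list(res['curve_dev_lr'].values())):.3f}")
print(f"accel GRAPPA-3 @35%: {nominal_acceleration(ProtocolParams(3, 0.35)):.2f}")
```

prints (one CPU core, ≈ 19 minutes, almost all of it the 2,000 training
iterations):

```
held-out frames: 50
PSNR  SR vs HR: 26.03 dB
PSNR  LR vs HR: 22.28 dB
curve deviation SR 0.019 vs LR 0.043
accel GRAPPA-3 @35%: 8.57
```

The super-resolved frames beat the zero-padded LR input on PSNR (paired
t-test p ≈ 1e-29; nRMSE 6.2% vs 8.1%, SSIM 0.918 vs 0.887), and their ROI
signal-time curves deviate less than half as much from the HR reference —
the model sharpens frames without distorting the bolus dynamics. The
acceleration value is the nominal protocol arithmetic: GRAPPA factor
divided by the retained phase-line fraction.

A command-line interface mirrors the library:

```sh
perfdiff simulate --seed 0 --out sim/            # phantom series (NIfTI/NPZ)
perfdiff degrade  --input sim/series.nii.gz --fraction 0.35 --out pairs.npz
perfdiff train    --config conf.yaml --seed 0 --out run/
perfdiff sample   --model run/model.npz --input pairs.npz --seed 0 --out sr.npz
perfdiff evaluate --pred sr.npz --ref hr.npz --baseline lr.npz --out report.json
```

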