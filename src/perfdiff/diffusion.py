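"""Conditional denoising-diffusion core for image super-resolution.

The forward process corrupts a high-resolution target ``y0`` (scaled to
[-1, 1]) with Gaussian noise over ``T`` steps through per-step retention
factors ``alpha_t = 1 - beta_t``; the cumulative product
``gamma_t = prod_{i<=t} alpha_i`` gives the closed-form marginal

    y_t = sqrt(gamma_t) * y0 + sqrt(1 - gamma_t) * eps,   eps ~ N(0, I).

The reverse process starts from pure noise and iteratively applies

    y_{t-1} = (y_t - (1 - alpha_t)/sqrt(1 - gamma_t) * eps_hat) / sqrt(alpha_t)
              + sqrt(1 - alpha_t) * z,

where ``eps_hat`` is the noise predicted by a network conditioned on the
low-resolution image, and ``z`` is fresh noise (omitted at the final step).
Training minimizes the L1 distance between predicted and injected noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .phantom import NormalizationRecord

__all__ = [
    "NoiseSchedule",
    "make_schedule",
    "forward_step",
    "forward_marginal",
    "reverse_step",
    "sample",
    "training_loss",
    "draw_training_gamma",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Variance schedule: per-step beta/alpha, cumulative gamma, reverse sigma^2.

    Index convention: position ``t-1`` of each array belongs to step ``t``
    (steps run 1..T).
    """

    beta: np.ndarray          # (T,), per-step variance increment, in (0,1)
    kind: str = "linear"

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=np.float64)
        object.__setattr__(self, "beta", beta)
        if beta.ndim != 1 or beta.size < 1:
            raise ValueError("beta must be a non-empty 1-D array")
        if np.any(beta <= 0) or np.any(beta >= 1):
            raise ValueError("beta values must lie in (0, 1)")

    @property
    def T(self) -> int:
        return self.beta.size

    @property
    def alpha(self) -> np.ndarray:
        return 1.0 - self.beta

    @property
    def gamma(self) -> np.ndarray:
        return np.cumprod(self.alpha)

    @property
    def sigma2(self) -> np.ndarray:
        """Fixed reverse-step variance, 1 - alpha_t."""
        return self.beta.copy()

    def to_dict(self) -> dict:
        return {"T": int(self.T), "beta_start": float(self.beta[0]),
                "beta_end": float(self.beta[-1]), "kind": self.kind}


def make_schedule(T: int = 2000, beta_start: float = 1e-6, beta_end: float = 1e-2,
                  kind: str = "linear") -> NoiseSchedule:
    """Build a variance schedule.

    The default (linear, 1e-6 -> 1e-2 over T = 2000) drives ``gamma_T`` to
    ~4.5e-5, i.e. the terminal state is indistinguishable from pure noise.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError("need 0 < beta_start <= beta_end < 1")
    if kind == "linear":
        beta = np.linspace(beta_start, beta_end, T)
    elif kind == "quadratic":
        beta = np.linspace(np.sqrt(beta_start), np.sqrt(beta_end), T) ** 2
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    return NoiseSchedule(beta=beta, kind=kind)


def _check_t(t: int, T: int) -> None:
    if not (1 <= t <= T):
        raise IndexError(f"step t={t} outside 1..{T}")


def forward_step(y_prev: np.ndarray, t: int, schedule: NoiseSchedule,
                 rng: np.random.Generator) -> np.ndarray:
    """One forward noising step: sqrt(alpha_t) y_{t-1} + sqrt(1-alpha_t) z."""
    _check_t(t, schedule.T)
    a = schedule.alpha[t - 1]
    z = rng.standard_normal(np.shape(y_prev))
    return np.sqrt(a) * np.asarray(y_prev) + np.sqrt(1.0 - a) * z


def forward_marginal(y0: np.ndarray, t: int, epsilon: np.ndarray,
                     schedule: NoiseSchedule) -> np.ndarray:
    """Closed-form marginal: sqrt(gamma_t) y0 + sqrt(1-gamma_t) eps."""
    _check_t(t, schedule.T)
    y0 = np.asarray(y0)
    epsilon = np.asarray(epsilon)
    if epsilon.shape != y0.shape:
        raise ValueError("epsilon must match y0 in shape")
    g = schedule.gamma[t - 1]
    return np.sqrt(g) * y0 + np.sqrt(1.0 - g) * epsilon


def reverse_step(y_t: np.ndarray, t: int, epsilon_hat: np.ndarray,
                 schedule: NoiseSchedule, rng: np.random.Generator | None = None,
                 inject_noise: bool = True, clip_y0: bool = False) -> np.ndarray:
    """One reverse refinement step.

    With ``clip_y0`` the implied one-step estimate of the clean image,
    ``(y_t - sqrt(1-gamma_t) eps_hat) / sqrt(gamma_t)``, is clipped to
    [-1, 1] before the mean is recomputed — a standard stabilization for
    early steps where the prediction can overshoot the data range.  Noise is
    never injected at t = 1.
    """
    _check_t(t, schedule.T)
    y_t = np.asarray(y_t)
    epsilon_hat = np.asarray(epsilon_hat)
    if epsilon_hat.shape != y_t.shape:
        raise ValueError("epsilon_hat must match y_t in shape")
    a = schedule.alpha[t - 1]
    g = schedule.gamma[t - 1]
    if clip_y0:
        y0_hat = (y_t - np.sqrt(1.0 - g) * epsilon_hat) / np.sqrt(g)
        np.clip(y0_hat, -1.0, 1.0, out=y0_hat)
        epsilon_hat = (y_t - np.sqrt(g) * y0_hat) / np.sqrt(1.0 - g)
    mean = (y_t - (1.0 - a) / np.sqrt(1.0 - g) * epsilon_hat) / np.sqrt(a)
    if inject_noise and t > 1:
        if rng is None:
            raise ValueError("rng required when injecting noise")
        mean = mean + np.sqrt(1.0 - a) * rng.standard_normal(y_t.shape)
    return mean


def sample(x_lr: np.ndarray, model: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
           schedule: NoiseSchedule, rng: np.random.Generator,
           inject_noise: bool = True, clip_y0: bool = True,
           normalization: NormalizationRecord | None = None,
           progress: bool = False) -> np.ndarray:
    """Ancestral sampling: iterate reverse steps from y_T ~ N(0, I) to y_0.

    ``model(x, y_t, gamma)`` predicts the noise; ``x_lr`` must be normalized
    exactly as during training ([-1, 1]).  The returned image is clipped to
    [-1, 1] and, when a normalization record is supplied, mapped back to the
    data scale.
    """
    x_lr = np.asarray(x_lr)
    y = rng.standard_normal(x_lr.shape)
    steps = range(schedule.T, 0, -1)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm
        steps = tqdm(steps, desc="sampling", leave=False)
    for t in steps:
        gamma_t = np.float64(schedule.gamma[t - 1])
        eps_hat = model(x_lr, y, gamma_t)
        if np.shape(eps_hat) != y.shape:
            raise ValueError("model output shape mismatch")
        y = reverse_step(y, t, eps_hat, schedule, rng,
                         inject_noise=inject_noise, clip_y0=clip_y0)
    y = np.clip(y, -1.0, 1.0)
    if normalization is not None:
        y = normalization.invert(y)
    return y


def draw_training_gamma(schedule: NoiseSchedule, rng: np.random.Generator,
                        size: int = 1, continuous: bool = False) -> np.ndarray:
    """Noise levels for training draws.

    Default: pick t uniformly in {1..T} and return gamma_t.  The continuous
    mode instead draws gamma uniformly from [gamma_{t-1}, gamma_t] within a
    uniformly chosen step (piecewise-uniform over the schedule's range).
    """
    ts = rng.integers(1, schedule.T + 1, size=size)
    gam = schedule.gamma
    g_hi = np.concatenate([[1.0], gam[:-1]])     # gamma_{t-1}, with gamma_0 = 1
    if continuous:
        u = rng.random(size)
        return gam[ts - 1] + u * (g_hi[ts - 1] - gam[ts - 1])
    return gam[ts - 1]


def training_loss(model, x_lr: np.ndarray, y0: np.ndarray, epsilon: np.ndarray,
                  gamma_draw) -> float:
    """L1 between predicted and injected noise at noise level gamma.

    ``gamma_draw`` is a scalar in (0, 1) or a per-item vector for batched
    inputs (leading batch dimension).  This evaluation path carries no
    gradients; the optimizer in :mod:`perfdiff.training` re-implements the
    same objective through the autodiff graph.
    """
    x_lr = np.asarray(x_lr)
    y0 = np.asarray(y0)
    epsilon = np.asarray(epsilon)
    if epsilon.shape != y0.shape:
        raise ValueError("epsilon must match y0 in shape")
    g = np.asarray(gamma_draw, dtype=np.float64)
    if np.any(g <= 0.0) or np.any(g >= 1.0):
        raise ValueError("gamma must lie in (0, 1)")
    if g.ndim > 0:
        g = g.reshape(g.shape + (1,) * (y0.ndim - g.ndim))
    y_noisy = np.sqrt(g) * y0 + np.sqrt(1.0 - g) * epsilon
    eps_hat = model(x_lr, y_noisy, np.asarray(gamma_draw, dtype=np.float64))
    return float(np.abs(np.asarray(eps_hat) - epsilon).mean())
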