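"""Low-resolution / high-resolution pair synthesis by k-space truncation.

A high-resolution magnitude image is Fourier transformed, only a central
band of phase-encoding lines is retained (the rest zero-filled), and the
inverse transform's magnitude gives the low-resolution image at the same
matrix size.  Both images are then cropped to a common window around the
heart and normalized identically, yielding co-registered conditioning /
target pairs for training.

Conventions
-----------
* k-space grids are DC-centered (zero frequency at index ``N // 2``).
* the phase-encoding axis defaults to image rows (axis 0).
* the retained-line count is ``round(fraction * N_pe)`` with half away from
  zero; the band is centered on DC with the extra line on the lower-index
  side when the count is even, so DC is always retained.
* normalization divides by one global maximum of the HR series (not per
  frame, which would distort signal-time curves) and then maps to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import NormalizationRecord, PerfusionSeries

__all__ = [
    "KSpaceFrame",
    "LRHRPair",
    "to_kspace",
    "from_kspace",
    "truncate_phase_lines",
    "retained_line_count",
    "lowpass_image",
    "make_lr_hr_pair",
    "augment_pair",
    "degrade_series",
]


@dataclass
class KSpaceFrame:
    """A DC-centered complex k-space grid."""

    grid: np.ndarray                 # complex, rows x cols
    phase_encode_axis: int = 0       # which axis holds phase-encoding lines

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.complex128)
        if self.grid.ndim != 2:
            raise ValueError("k-space grid must be 2-D")
        if self.phase_encode_axis not in (0, 1):
            raise ValueError("phase_encode_axis must be 0 or 1")


@dataclass
class LRHRPair:
    """Co-registered conditioning (x) and target (y0) images at equal size."""

    x: np.ndarray                    # low-resolution conditioning image
    y0: np.ndarray                   # high-resolution target image
    fraction: float                  # retained phase-line fraction
    normalization: NormalizationRecord = field(default_factory=NormalizationRecord)

    def __post_init__(self):
        self.x = np.asarray(self.x)
        self.y0 = np.asarray(self.y0)
        if self.x.shape != self.y0.shape:
            raise ValueError("x and y0 must share a shape")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y0))):
            raise ValueError("pair contains non-finite values")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")


def to_kspace(image: np.ndarray, phase_encode_axis: int = 0) -> KSpaceFrame:
    """Forward FFT of a real magnitude image to a DC-centered grid."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    grid = np.fft.fftshift(np.fft.fft2(image))
    return KSpaceFrame(grid=grid, phase_encode_axis=phase_encode_axis)


def from_kspace(k: KSpaceFrame) -> np.ndarray:
    """Inverse FFT followed by magnitude."""
    return np.abs(np.fft.ifft2(np.fft.ifftshift(k.grid)))


def retained_line_count(fraction: float, n_pe: int) -> int:
    """round(fraction * N_pe), half away from zero, at least 1 line (DC)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    return max(1, int(np.floor(fraction * n_pe + 0.5)))


def truncate_phase_lines(k: KSpaceFrame, fraction: float) -> KSpaceFrame:
    """Zero all phase-encoding lines outside the central band.

    The band holds ``retained_line_count(fraction, N_pe)`` contiguous lines
    centered on DC (index ``N_pe // 2``); when the count is even the extra
    line sits on the lower-index side.  The readout axis is untouched.
    """
    axis = k.phase_encode_axis
    n_pe = k.grid.shape[axis]
    n_keep = retained_line_count(fraction, n_pe)
    dc = n_pe // 2
    lo = dc - (n_keep - 1 + 1) // 2
    hi = lo + n_keep                         # [lo, hi)
    out = np.zeros_like(k.grid)
    sl = [slice(None), slice(None)]
    sl[axis] = slice(max(lo, 0), min(hi, n_pe))
    sl = tuple(sl)
    out[sl] = k.grid[sl]
    return KSpaceFrame(grid=out, phase_encode_axis=axis)


def lowpass_image(image: np.ndarray, fraction: float,
                  phase_encode_axis: int = 0) -> np.ndarray:
    """Complex low-passed image before the magnitude step (linear in the input)."""
    k = to_kspace(image, phase_encode_axis)
    kt = truncate_phase_lines(k, fraction)
    return np.fft.ifft2(np.fft.ifftshift(kt.grid))


def degrade_image(image: np.ndarray, fraction: float,
                  phase_encode_axis: int = 0) -> np.ndarray:
    """Full degradation of one magnitude frame: FFT, truncate, zero-fill, |IFFT|."""
    return np.abs(lowpass_image(image, fraction, phase_encode_axis))


def _crop(image: np.ndarray, center: tuple[int, int], size: int) -> np.ndarray:
    r0 = int(center[0]) - size // 2
    c0 = int(center[1]) - size // 2
    if r0 < 0 or c0 < 0 or r0 + size > image.shape[0] or c0 + size > image.shape[1]:
        raise ValueError("crop window out of bounds")
    return image[r0:r0 + size, c0:c0 + size]


def make_lr_hr_pair(hr_image: np.ndarray, fraction: float,
                    crop_center: tuple[int, int] | None = None,
                    crop_size: int = 96,
                    series_max: float | None = None,
                    phase_encode_axis: int = 0) -> LRHRPair:
    """Degrade, crop and normalize one HR frame into a training pair.

    ``series_max`` is the global maximum of the HR series the frame belongs
    to; both images are divided by it and mapped to [-1, 1].  When omitted it
    is taken from the frame itself.
    """
    hr_image = np.asarray(hr_image, dtype=np.float64)
    if hr_image.shape[0] < crop_size or hr_image.shape[1] < crop_size:
        raise ValueError("hr_image smaller than the crop size")
    if crop_center is None:
        crop_center = (hr_image.shape[0] // 2, hr_image.shape[1] // 2)
    lr_full = degrade_image(hr_image, fraction, phase_encode_axis)
    lr = _crop(lr_full, crop_center, crop_size)
    hr = _crop(hr_image, crop_center, crop_size)
    if series_max is None:
        series_max = float(hr_image.max())
    if series_max <= 0:
        raise ValueError("series_max must be positive")
    norm = NormalizationRecord(kind="affine-to-[-1,1]", series_max=series_max)
    return LRHRPair(x=norm.apply(lr), y0=norm.apply(hr), fraction=float(fraction),
                    normalization=norm)


def augment_pair(pair: LRHRPair, rng: np.random.Generator) -> LRHRPair:
    """Random vertical / horizontal flip, each with probability 1/2, applied
    jointly to x and y0 so pixel correspondence is preserved."""
    x, y0 = pair.x, pair.y0
    if rng.random() < 0.5:
        x, y0 = x[::-1, :], y0[::-1, :]
    if rng.random() < 0.5:
        x, y0 = x[:, ::-1], y0[:, ::-1]
    return LRHRPair(x=x.copy(), y0=y0.copy(), fraction=pair.fraction,
                    normalization=pair.normalization)


def degrade_series(series: PerfusionSeries, fraction: float,
                   crop_center: tuple[int, int] | None = None,
                   crop_size: int | None = None,
                   phase_encode_axis: int = 0) -> tuple[PerfusionSeries, PerfusionSeries]:
    """Degrade every frame of a series at one fraction.

    Returns ``(lr_series, hr_series)`` cropped to the same window, both
    normalized to [-1, 1] by the HR series' global maximum and carrying the
    shared normalization record.  ROI masks are cropped alongside.
    """
    if crop_size is None:
        crop_size = min(series.shape)
    if crop_center is None:
        crop_center = (series.shape[0] // 2, series.shape[1] // 2)
    series_max = float(series.frames.max())
    lr_frames, hr_frames = [], []
    for frame in series.frames:
        pair = make_lr_hr_pair(frame, fraction, crop_center, crop_size,
                               series_max=series_max,
                               phase_encode_axis=phase_encode_axis)
        lr_frames.append(pair.x)
        hr_frames.append(pair.y0)
    norm = NormalizationRecord(kind="affine-to-[-1,1]", series_max=series_max)
    masks = None
    if series.roi_masks is not None:
        masks = {k: _crop(v, crop_center, crop_size) for k, v in series.roi_masks.items()}
    lr = PerfusionSeries(frames=np.stack(lr_frames), frame_times=series.frame_times.copy(),
                         roi_masks=masks, normalization=norm)
    hr = PerfusionSeries(frames=np.stack(hr_frames), frame_times=series.frame_times.copy(),
                         roi_masks={k: v.copy() for k, v in masks.items()} if masks else None,
                         normalization=norm)
    return lr, hr
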