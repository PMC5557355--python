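"""Image restoration and conditioning applied before object detection.

The preprocessing chain mirrors a typical confocal puncta workflow:
Richardson-Lucy deconvolution per optical slice, maximum-intensity
z-projection, high-boost unsharp masking, and median-deviation outlier-pixel
removal.  All operations preserve array shape and nonnegativity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology, restoration

__all__ = [
    "ImageStack",
    "PreprocessConfig",
    "richardson_lucy",
    "max_project",
    "unsharp_mask",
    "remove_outliers",
    "preprocess",
]


@dataclass
class ImageStack:
    """A 2-D image or 3-D z-stack with physical pixel calibration."""

    data: np.ndarray
    pixel_size_um: float = 0.07
    z_step_um: float | None = 0.5
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError("data must be 2-D or 3-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and >= 0")


@dataclass
class PreprocessConfig:
    """Parameters of the deconvolve / project / deblur / denoise chain."""

    rl_iterations: int = 30
    unsharp_radius_px: float = 2.0
    unsharp_amount: float = 1.0
    outlier_radius_px: int = 2
    outlier_threshold: float = 50.0

    def __post_init__(self) -> None:
        if self.rl_iterations < 0:
            raise ValueError("rl_iterations must be >= 0")
        if self.unsharp_radius_px <= 0 or self.outlier_radius_px < 1:
            raise ValueError("radii must be positive")
        if self.unsharp_amount < 0:
            raise ValueError("unsharp_amount must be >= 0")


def _check_psf(psf: np.ndarray) -> np.ndarray:
    psf = np.asarray(psf, dtype=float)
    if psf.ndim != 2:
        raise ValueError("psf must be a 2-D kernel")
    if np.any(psf < 0) or not np.isclose(psf.sum(), 1.0, atol=1e-6):
        raise ValueError("psf must be nonnegative and normalized to sum 1")
    return psf


def richardson_lucy(image: np.ndarray, psf: np.ndarray, iterations: int = 30,
                    ) -> np.ndarray:
    """Richardson-Lucy deconvolution of a 2-D image or per-slice of a stack.

    ``iterations=0`` returns the input unchanged.  The estimate is not
    clipped, so the intensity scale of the input is preserved.
    """
    psf = _check_psf(psf)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    image = np.asarray(image, dtype=float)
    if iterations == 0:
        return image.copy()
    if image.ndim == 3:
        return np.stack(
            [richardson_lucy(sl, psf, iterations) for sl in image], axis=0
        )
    out = restoration.richardson_lucy(image, psf, num_iter=iterations, clip=False)
    return np.clip(out, 0, None)


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection over z; 2-D input passes through."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3:
        raise ValueError("expected a 2-D image or 3-D stack")
    return stack.max(axis=0)


def unsharp_mask(image: np.ndarray, radius_px: float, amount: float) -> np.ndarray:
    """High-boost sharpening: image + amount * (image - blur(image)).

    ``radius_px`` is the Gaussian blur sigma in pixels; the result is clipped
    at zero.  ``amount=0`` is the identity.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    image = np.asarray(image, dtype=float)
    if amount == 0:
        return image.copy()
    blurred = ndimage.gaussian_filter(image, sigma=radius_px)
    return np.clip(image + amount * (image - blurred), 0, None)


def remove_outliers(image: np.ndarray, radius_px: int, threshold: float,
                    which: str = "bright") -> np.ndarray:
    """Replace pixels deviating from their neighborhood median.

    A pixel whose deviation from the median of the disk-shaped neighborhood
    of ``radius_px`` exceeds ``threshold`` is replaced by that median; all
    other pixels are untouched.  ``which`` selects bright-only (default),
    dark-only, or two-sided replacement.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if which not in ("bright", "dark", "both"):
        raise ValueError("which must be 'bright', 'dark' or 'both'")
    image = np.asarray(image, dtype=float)
    footprint = morphology.disk(radius_px)
    med = ndimage.median_filter(image, footprint=footprint, mode="reflect")
    dev = image - med
    if which == "bright":
        mask = dev > threshold
    elif which == "dark":
        mask = -dev > threshold
    else:
        mask = np.abs(dev) > threshold
    out = image.copy()
    out[mask] = med[mask]
    return out


def preprocess(stack: np.ndarray, psf: np.ndarray,
               config: PreprocessConfig | None = None) -> np.ndarray:
    """Full conditioning chain: deconvolve slices, project, deblur, denoise."""
    if config is None:
        config = PreprocessConfig()
    img = richardson_lucy(stack, psf, config.rl_iterations)
    img = max_project(img)
    img = unsharp_mask(img, config.unsharp_radius_px, config.unsharp_amount)
    img = remove_outliers(img, config.outlier_radius_px, config.outlier_threshold)
    return img
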