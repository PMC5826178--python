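"""Grayscale conversion and image enhancement for membrane-stained tissue.

Two enhanced images are produced from every input: an illumination-corrected
image (consumed by the thresholding branch of membrane segmentation) and a
histogram-equalized image (consumed by the edge-detection branch).

Illumination correction is a difference-of-Gaussians (DoG) filter: the image
is convolved with the difference of a wide and a narrow truncated Gaussian,
``I * (g2 - g1)``.  The wide Gaussian estimates the slowly varying
illumination field (brightfield images are typically darker in the corners
than at the center); subtracting it keeps only high-frequency structure such
as the stained membrane, which comes out as a positive response on a
near-zero background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure

__all__ = [
    "GaussianSpec",
    "to_gray",
    "gaussian_kernel",
    "illumination_correct",
    "equalize_histogram",
]

#: BT.601 luma weights for R, G, B.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GaussianSpec:
    """Parameters of one truncated Gaussian filter.

    Parameters
    ----------
    sigma:
        Standard deviation in pixels; must be positive.
    kernel_size:
        Nominal window size in pixels.  The realized kernel is square with
        odd side length (``kernel_size`` itself if odd, else
        ``kernel_size + 1``) so that it has a well-defined center pixel.
    """

    sigma: float
    kernel_size: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.kernel_size < 1:
            raise ValueError(f"kernel_size must be >= 1, got {self.kernel_size}")

    @property
    def side(self) -> int:
        """Realized (odd) side length of the kernel window."""
        h = int(self.kernel_size)
        return h if h % 2 == 1 else h + 1


#: Narrow Gaussian: light denoising, retains nearly all image content.
DEFAULT_G1 = GaussianSpec(sigma=0.5, kernel_size=3)
#: Wide Gaussian: estimates the low-frequency illumination field.
DEFAULT_G2 = GaussianSpec(sigma=30.0, kernel_size=60)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an H x W x 3 RGB image to 8-bit grayscale.

    Uses BT.601 luminance weights (0.299, 0.587, 0.114) with round-half-up
    to integer, so stained (dark) membrane stays darker than the bright
    background after conversion.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(
            f"expected an H x W x 3 color image, got shape {img.shape}"
        )
    luma = img.astype(np.float64) @ _LUMA_WEIGHTS
    return np.floor(luma + 0.5).clip(0, 255).astype(np.uint8)


def _gaussian_profile_1d(spec: GaussianSpec) -> np.ndarray:
    """Unnormalized 1-D Gaussian samples on the centered odd window."""
    r = spec.side // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    return np.exp(-(x**2) / (2.0 * spec.sigma**2))


def gaussian_kernel(spec: GaussianSpec) -> np.ndarray:
    """Build the 2-D Gaussian kernel for ``spec``, normalized to sum to 1.

    The kernel is sampled as ``exp(-(x^2 + y^2) / (2 sigma^2)) / (2 pi sigma^2)``
    on a centered square window of odd side length and then renormalized so
    its weights sum to exactly 1 (truncation makes the analytic normalization
    constant slightly off).
    """
    p = _gaussian_profile_1d(spec)
    kernel = np.outer(p, p) / (2.0 * np.pi * spec.sigma**2)
    return kernel / kernel.sum()


def _separable_convolve(img: np.ndarray, spec: GaussianSpec) -> np.ndarray:
    """Convolve with the normalized truncated Gaussian, reflect padding.

    The truncated Gaussian kernel is exactly separable (it is the outer
    product of its normalized 1-D profiles), so two 1-D passes reproduce the
    full 2-D convolution.
    """
    p = _gaussian_profile_1d(spec)
    p = p / p.sum()
    out = ndi.convolve1d(img, p, axis=0, mode="reflect")
    return ndi.convolve1d(out, p, axis=1, mode="reflect")


def illumination_correct(
    img: np.ndarray,
    g1: GaussianSpec = DEFAULT_G1,
    g2: GaussianSpec = DEFAULT_G2,
    return_signed: bool = False,
) -> np.ndarray:
    """Flatten uneven illumination with a difference-of-Gaussians filter.

    Computes ``I * (g2 - g1)`` where ``*`` is convolution with reflect
    padding.  On images with dark membrane on a bright background the
    membrane yields a positive response and the illumination gradient is
    suppressed.

    Parameters
    ----------
    img:
        2-D grayscale image.
    g1, g2:
        Narrow and wide Gaussian specs (defaults: sigma 0.5 / size 3 and
        sigma 30 / size 60).
    return_signed:
        If True, return the raw signed float response.  Otherwise negative
        values are clipped to 0 and the result is scaled linearly so its
        maximum maps to 255, returned as uint8 (all zeros if the response
        is nowhere positive).
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    f = img.astype(np.float64)
    signed = _separable_convolve(f, g2) - _separable_convolve(f, g1)
    if return_signed:
        return signed
    pos = np.clip(signed, 0.0, None)
    peak = pos.max()
    if peak <= 1e-9:  # nowhere positive (up to convolution round-off)
        return np.zeros(img.shape, dtype=np.uint8)
    return np.floor(pos * (255.0 / peak) + 0.5).astype(np.uint8)


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Global histogram equalization of an 8-bit grayscale image.

    Enhances contrast ahead of edge detection.  The transfer function is
    the (monotone) empirical CDF followed by a full-range stretch, so pixel
    rank order is preserved and the occupied levels span [0, 255].
    A constant image stays constant.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    eq = exposure.equalize_hist(img, nbins=256)
    lo, hi = eq.min(), eq.max()
    if hi > lo:
        eq = (eq - lo) / (hi - lo)
    return np.floor(eq * 255.0 + 0.5).clip(0, 255).astype(np.uint8)
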