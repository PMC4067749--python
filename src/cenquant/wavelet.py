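"""Stationary (*à trous*) B3-spline wavelet decomposition.

Separates diffraction-scale spots from diffuse nuclear and cellular
background.  Scale ``k`` captures structures of characteristic FWHM about
``2**(k-1)`` pixels; the element-wise sum of all detail scales plus the
smooth residual reproduces the source image exactly (telescoping sum), so
the transform conserves flux.  No thresholding is applied inside scales:
detection lives downstream in photometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "WaveletDecomposition",
    "atrous_decompose",
    "extract_spot_image",
    "max_feasible_scales",
    "ScaleLimitError",
]

#: B3-spline refinement kernel applied separably.
B3_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


class ScaleLimitError(ValueError):
    """Image too small for the requested number of scales."""


def max_feasible_scales(shape: tuple[int, int]) -> int:
    """Largest ``n_scales`` such that the dilation step fits in the image."""
    m = min(shape)
    n = 1
    while 2 ** n <= m:
        n += 1
    return n


def _dilated_smooth(image: np.ndarray, step: int) -> np.ndarray:
    """Separable convolution with the B3 kernel dilated by ``step``."""
    kernel = np.zeros(4 * step + 1)
    kernel[:: step] = B3_KERNEL
    out = ndi.convolve1d(image, kernel, axis=0, mode="mirror")
    return ndi.convolve1d(out, kernel, axis=1, mode="mirror")


@dataclass
class WaveletDecomposition:
    """Ordered detail scales plus smooth residual of one 2D frame."""

    scales: list[np.ndarray]
    residual: np.ndarray
    source_shape: tuple[int, int]

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def reconstruct(self) -> np.ndarray:
        """Sum of all scales and the residual (equals the source image)."""
        return np.sum(self.scales, axis=0) + self.residual


def atrous_decompose(image: np.ndarray, n_scales: int = 8) -> WaveletDecomposition:
    """Decompose a 2D frame into ``n_scales`` detail scales and a residual.

    ``smooth_0 = image``; ``smooth_k`` convolves ``smooth_{k-1}`` with the
    B3-spline kernel dilated by ``2**(k-1)`` (mirror boundary); detail scale
    ``k`` is ``smooth_{k-1} - smooth_k``; the residual is the last smooth.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("atrous_decompose expects a single 2D frame")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    feasible = max_feasible_scales(image.shape)
    if n_scales > feasible:
        raise ScaleLimitError(
            f"image of shape {image.shape} supports at most {feasible} scales "
            f"(requested {n_scales})"
        )
    smooth = image
    scales: list[np.ndarray] = []
    for k in range(1, n_scales + 1):
        nxt = _dilated_smooth(smooth, 2 ** (k - 1))
        scales.append(smooth - nxt)
        smooth = nxt
    return WaveletDecomposition(scales=scales, residual=smooth, source_shape=image.shape)


def extract_spot_image(
    dec: WaveletDecomposition, scale_ids: set[int] | tuple[int, ...] = (1, 2, 3)
) -> np.ndarray:
    """Element-wise sum of the selected detail scales (1-based ids).

    The default (scales 1+2+3) keeps objects up to ~4 pixels FWHM across;
    ``source - spot_image`` is the complementary background image.
    """
    ids = sorted(set(int(i) for i in scale_ids))
    if not ids:
        raise ValueError("scale_ids must not be empty")
    if ids[0] < 1 or ids[-1] > dec.n_scales:
        raise ValueError(
            f"scale ids {ids} outside valid range 1..{dec.n_scales}"
        )
    return np.sum([dec.scales[i - 1] for i in ids], axis=0)


def spot_and_background(
    image: np.ndarray,
    scale_ids: set[int] | tuple[int, ...] = (1, 2, 3),
    n_scales: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: decompose and split one frame into spot + background."""
    if n_scales is None:
        n_scales = min(8, max_feasible_scales(np.shape(image)))
    dec = atrous_decompose(image, n_scales)
    spot = extract_spot_image(dec, scale_ids)
    return spot, np.asarray(image, dtype=np.float64) - spot
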