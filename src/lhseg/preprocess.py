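"""Pre-segmentation smoothing.

A single 3x3 Gaussian convolution applied independently to each 2D slice
reduces the intensity heterogeneity that would otherwise fragment the
region-merging segmentation, while the small support preserves object
edges.  Smoothing never mixes information across z: depth-dependent
signal loss makes adjacent slices systematically dimmer/brighter and
blurring across them would bias edge positions.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve

from .stack import ChannelRole, VolumeStack

__all__ = ["gaussian_kernel_3x3", "smooth_slice", "gaussian_smooth"]

DEFAULT_SIGMA = 0.8


def gaussian_kernel_3x3(sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Discretely sampled 3x3 Gaussian kernel, normalized to sum 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.array([-1.0, 0.0, 1.0])
    k1 = np.exp(-(x**2) / (2.0 * sigma**2))
    kernel = np.outer(k1, k1)
    return kernel / kernel.sum()


def smooth_slice(image: np.ndarray, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Convolve one 2D slice with the 3x3 Gaussian (reflect borders).

    Integer inputs are rounded back to the input dtype so per-slice total
    intensity is conserved up to rounding; float inputs pass through.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("smooth_slice expects a 2D image")
    kernel = gaussian_kernel_3x3(sigma)
    out = convolve(image.astype(np.float64), kernel, mode="reflect")
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return out.astype(image.dtype)


def gaussian_smooth(
    stack: VolumeStack, channel: ChannelRole, sigma: float = DEFAULT_SIGMA
) -> VolumeStack:
    """Return a copy of the stack with one channel smoothed slice-by-slice."""
    idx = stack.channel_index(channel)
    data = stack.data.copy()
    for z in range(stack.n_slices):
        data[idx, z] = smooth_slice(data[idx, z], sigma)
    return VolumeStack(data, stack.spacing, list(stack.channels))
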