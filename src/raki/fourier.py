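"""Centered, unitary 2D Fourier helpers.

k-space arrays are stored centered: the DC coefficient sits at index
``n // 2`` on each spatial axis. All transforms are unitary (``norm="ortho"``)
unless noted otherwise.
"""

from __future__ import annotations

import numpy as np

SPATIAL_AXES = (-3, -2)  # [..., PE, RO, channel]


def fft2c(x: np.ndarray, axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Image -> centered k-space, unitary."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifft2c(x: np.ndarray, axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Centered k-space -> image, unitary."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def cconv2(x: np.ndarray, h: np.ndarray, axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Centered circular 2D convolution with zero lag at index ``n // 2``.

    Scaled so that convolving with a one-pixel delta at the center index is
    the identity. Computed through the convolution theorem, which makes it
    exactly (to rounding) the inverse transform of a k-space product.
    """
    n = x.shape[axes[0]] * x.shape[axes[1]]
    return np.sqrt(n) * ifft2c(fft2c(x, axes=axes) * fft2c(h, axes=axes), axes=axes)


def pe_shift_ramp(npe: int, r: int) -> np.ndarray:
    """Image-domain phase ramp equivalent to a +r circular shift of centered
    k-space along the phase-encoding axis (shift theorem)."""
    p = np.arange(npe)
    return np.exp(2j * np.pi * r * (p - npe // 2) / npe)
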