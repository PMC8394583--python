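"""Centered, unitary 2-D Fourier transforms.

All k-space in this package uses the convention that the DC sample sits at
index ``n // 2`` along each axis and that the transform is orthonormal
(``norm="ortho"``), so Parseval's identity holds exactly and forward/inverse
round-trips are lossless to machine precision.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c"]


def fft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered orthonormal 2-D FFT over the last two axes (image -> k-space)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered orthonormal 2-D inverse FFT (k-space -> image)."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )
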