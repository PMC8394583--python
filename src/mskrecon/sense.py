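"""SENSE forward/adjoint operators, coil-sensitivity estimation, bias correction.

The SENSE signal model expresses each receiver coil's k-space as the masked
Fourier transform of the sensitivity-weighted image,

    y_c = M F (s_c * x),

with ``M`` the sampling mask, ``F`` the centered unitary 2-D FFT and ``s_c``
the coil's complex spatial sensitivity.  With root-sum-of-squares (RSS)
normalized sensitivities the stacked operator A satisfies ||A|| <= 1, which
every gradient-descent-style reconstruction in this package relies on.

Sensitivities are estimated from the autocalibration (ACS) block by the
classical low-resolution method: window the ACS along the phase-encode
direction, zero-pad to the full matrix, inverse-transform, and divide each
low-resolution coil image by their RSS (guarded by a floor).  An
eigen-decomposition (ESPIRiT-style) estimator could be swapped in behind the
same signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import get_window

from .fourier import fft2c, ifft2c
from .sampling import SamplingPattern

__all__ = [
    "CoilSensitivities",
    "BiasField",
    "estimate_sensitivities",
    "forward",
    "adjoint",
    "rss_combine",
    "bias_correct",
]

#: division guard used for RSS normalization and bias correction
DEFAULT_FLOOR = 0.05


@dataclass
class CoilSensitivities:
    """Per-coil complex sensitivity maps, RSS-normalized on their support.

    ``maps`` has shape ``(n_coils, n_pe, n_ro)``; ``support`` is the boolean
    region where the pre-normalization RSS exceeded the floor.  On support the
    per-pixel RSS of ``maps`` is 1; outside it the maps are 0.
    """

    maps: np.ndarray
    support: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[-2:]


@dataclass
class BiasField:
    """Smooth positive multiplicative intensity field; divided out for display."""

    field: np.ndarray
    floor: float = 1e-3

    @property
    def shape(self) -> tuple[int, int]:
        return self.field.shape


def estimate_sensitivities(
    acs_block: np.ndarray,
    matrix: tuple[int, int],
    window: str = "hamming",
    floor: float = DEFAULT_FLOOR,
) -> CoilSensitivities:
    """Estimate coil sensitivity maps from the fully sampled ACS block.

    Parameters
    ----------
    acs_block : np.ndarray
        ``(n_coils, acs_width, n_ro)`` central k-space lines.
    matrix : tuple
        Full matrix size ``(n_pe, n_ro)`` to which the ACS is zero-padded.
    window : str
        Apodization window applied along the phase-encode direction before
        zero-padding (any name :func:`scipy.signal.windows.get_window` knows).
    floor : float
        Support threshold and division guard, as a fraction of the maximum
        RSS of the low-resolution coil images.
    """
    acs_block = np.asarray(acs_block)
    if acs_block.ndim != 3:
        raise ValueError("acs_block must be (n_coils, acs_width, n_ro)")
    n_coils, acs_width, n_ro = acs_block.shape
    n_pe_full, n_ro_full = matrix
    if acs_width < 8:
        raise ValueError(f"ACS too narrow for sensitivity estimation: {acs_width} < 8")
    if n_ro != n_ro_full:
        raise ValueError(f"ACS readout extent {n_ro} != matrix readout {n_ro_full}")

    w = get_window(window, acs_width, fftbins=False)
    padded = np.zeros((n_coils, n_pe_full, n_ro_full), dtype=complex)
    start = n_pe_full // 2 - acs_width // 2
    padded[:, start : start + acs_width, :] = acs_block * w[:, None]

    low_res = ifft2c(padded)
    rss = np.sqrt(np.sum(np.abs(low_res) ** 2, axis=0))
    guard = floor * rss.max()
    if guard == 0:
        raise ValueError("ACS block is identically zero")
    support = rss > guard
    maps = low_res / np.maximum(rss, guard)
    maps *= support
    return CoilSensitivities(maps=maps, support=support)


def forward(
    image: np.ndarray, sens: CoilSensitivities, pattern: SamplingPattern
) -> np.ndarray:
    """SENSE forward operator: ``mask * F(s_c * x)`` per coil."""
    if image.shape != sens.shape:
        raise ValueError(f"image shape {image.shape} != sensitivity shape {sens.shape}")
    if image.shape[0] != pattern.n_pe:
        raise ValueError("image PE extent does not match pattern")
    return fft2c(sens.maps * image) * pattern.mask[:, None]


def adjoint(
    kspace: np.ndarray, sens: CoilSensitivities, pattern: SamplingPattern
) -> np.ndarray:
    """Exact adjoint of :func:`forward`: conj-sensitivity-weighted coil sum."""
    if kspace.shape != sens.maps.shape:
        raise ValueError(
            f"k-space shape {kspace.shape} != sensitivity maps shape {sens.maps.shape}"
        )
    coil_imgs = ifft2c(kspace * pattern.mask[:, None])
    return np.sum(np.conj(sens.maps) * coil_imgs, axis=0)


def rss_combine(coil_images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares magnitude combination over the coil axis."""
    coil_images = np.asarray(coil_images)
    if coil_images.ndim < 3 or coil_images.shape[0] < 1:
        raise ValueError("expected (n_coils, n_pe, n_ro) with >= 1 coil")
    return np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))


def bias_correct(image: np.ndarray, bias: BiasField) -> np.ndarray:
    """Divide an image by the bias field (guarded by the field's floor)."""
    if image.shape != bias.shape:
        raise ValueError(f"image shape {image.shape} != bias shape {bias.shape}")
    return image / np.maximum(bias.field, bias.floor)
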