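"""GRAPPA: k-space parallel imaging, the standard (non-DL) baseline.

GRAPPA synthesizes each missing phase-encode line as a learned linear
combination of acquired neighboring lines across all coils.  The combination
weights are calibrated by least squares on the fully sampled autocalibration
(ACS) block, one weight set per missing-line offset ``d = 1..R-1`` relative to
the regular acquired grid, then applied across the whole of k-space.  The
default kernel uses 4 source lines x 5 readout taps with a trace-normalized
Tikhonov term for the calibration fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import KSpaceData
from .fourier import ifft2c
from .sampling import SamplingPattern, extract_acs
from .sense import BiasField, bias_correct, rss_combine

__all__ = ["GrappaKernel", "calibrate", "apply", "reconstruct_grappa"]


@dataclass
class GrappaKernel:
    """Calibrated interpolation weights.

    ``weights[d]`` maps the flattened all-coil source block (n_coils x
    n_source_lines x n_taps values) to each coil's sample on a line at offset
    ``d`` above the nearest acquired grid line.
    """

    R: int
    n_source_lines: int
    n_taps: int
    lam: float
    weights: dict[int, np.ndarray]
    fit_residual: dict[int, float]

    @property
    def line_offsets(self) -> np.ndarray:
        """Source-line block offsets in units of R (e.g. [-1, 0, 1, 2])."""
        return np.arange(self.n_source_lines) - (self.n_source_lines - 1) // 2


def calibrate(
    acs_block: np.ndarray,
    R: int,
    kernel_geometry: tuple[int, int] = (4, 5),
    lam: float = 1e-5,
) -> GrappaKernel:
    """Fit GRAPPA weights on the ACS block.

    For every missing-line offset ``d`` in ``1..R-1``, slide the source
    geometry over the ACS and solve the Tikhonov-regularized least squares

        min_w ||A w - b||^2 + lam * (tr(A^H A)/n_unknowns) * ||w||^2

    jointly for all target coils.  Warns when the system has fewer than 10x
    more equations than unknowns; raises when underdetermined or when fewer
    than two coils are available (a single coil cannot resolve aliasing).
    """
    acs_block = np.asarray(acs_block)
    n_coils, n_acs, n_ro = acs_block.shape
    if n_coils < 2:
        raise ValueError("GRAPPA calibration requires >= 2 coils")
    if R < 2:
        raise ValueError("nothing to calibrate for R < 2")
    nb, ntaps = kernel_geometry
    line_off = (np.arange(nb) - (nb - 1) // 2) * R
    tap_off = np.arange(ntaps) - ntaps // 2

    weights: dict[int, np.ndarray] = {}
    residuals: dict[int, float] = {}
    n_unknowns = n_coils * nb * ntaps
    for d in range(1, R):
        src_rows = line_off - d  # relative to the target row
        t_lo = max(0, -src_rows.min())
        t_hi = n_acs - max(0, src_rows.max())
        ro_lo, ro_hi = -tap_off.min(), n_ro - tap_off.max()
        n_t, n_r = t_hi - t_lo, ro_hi - ro_lo
        n_eq = n_t * n_r
        if n_t <= 0 or n_r <= 0 or n_eq < n_unknowns:
            raise ValueError(
                f"ACS too small: {max(n_eq, 0)} equations for {n_unknowns} "
                f"unknowns at offset d={d}"
            )
        if n_eq < 10 * n_unknowns:
            warnings.warn(
                f"GRAPPA calibration poorly conditioned: only {n_eq} equations "
                f"for {n_unknowns} unknowns (offset d={d})",
                stacklevel=2,
            )
        T = np.arange(t_lo, t_hi)
        RO = np.arange(ro_lo, ro_hi)
        # source tensor: (n_t, n_r, n_coils, nb, ntaps) -> (n_eq, n_unknowns)
        rows = T[:, None, None] + src_rows[None, None, :]
        cols = RO[None, :, None] + tap_off[None, None, :]
        src = acs_block[:, rows[..., :, None], cols[..., None, :]]
        A = np.moveaxis(src, 0, 2).reshape(n_eq, n_unknowns)
        B = acs_block[:, T[:, None], RO[None, :]].reshape(n_coils, n_eq).T
        AhA = A.conj().T @ A
        reg = lam * (np.trace(AhA).real / n_unknowns)
        W = np.linalg.solve(AhA + reg * np.eye(n_unknowns), A.conj().T @ B)
        weights[d] = W
        b_energy = np.linalg.norm(B)
        residuals[d] = float(np.linalg.norm(A @ W - B) / max(b_energy, 1e-30))
    return GrappaKernel(
        R=R,
        n_source_lines=nb,
        n_taps=ntaps,
        lam=lam,
        weights=weights,
        fit_residual=residuals,
    )


def apply(
    kspace: np.ndarray, kernel: GrappaKernel, pattern: SamplingPattern
) -> np.ndarray:
    """Synthesize every missing line within the retained phase-resolution band.

    Acquired samples pass through untouched; sources falling outside the
    matrix (or outside the band) contribute zeros.
    """
    if pattern.R != kernel.R:
        raise ValueError(f"pattern R={pattern.R} != kernel R={kernel.R}")
    n_coils, n_pe, n_ro = kspace.shape
    out = kspace.copy()
    if kernel.R == 1:
        return out
    nb, ntaps = kernel.n_source_lines, kernel.n_taps
    line_off = kernel.line_offsets * kernel.R
    tap_off = np.arange(ntaps) - ntaps // 2
    band = pattern.band
    pad = ntaps // 2
    padded = np.pad(kspace, ((0, 0), (0, 0), (pad, pad)))
    RO = np.arange(n_ro) + pad
    missing = [
        t for t in range(band.start, band.stop) if not pattern.mask[t]
    ]
    by_offset: dict[int, list[int]] = {}
    for t in missing:
        d = (t - pattern.offset) % kernel.R
        by_offset.setdefault(d, []).append(t)
    for d, targets in by_offset.items():
        T = np.asarray(targets)
        rows = T[:, None] + (line_off - d)[None, :]  # (n_t, nb)
        valid = (rows >= 0) & (rows < n_pe)
        rows_c = np.clip(rows, 0, n_pe - 1)
        # (n_coils, n_t, nb, n_ro, ntaps)
        src = padded[:, rows_c[..., None, None], RO[None, None, :, None] + tap_off]
        src = src * valid[None, :, :, None, None]
        # -> (n_t, n_ro, n_coils, nb, ntaps) -> (n_t * n_ro, n_unknowns)
        S = src.transpose(1, 3, 0, 2, 4).reshape(
            len(T) * n_ro, n_coils * nb * ntaps
        )
        synth = (S @ kernel.weights[d]).reshape(len(T), n_ro, n_coils)
        out[:, T, :] = np.moveaxis(synth, 2, 0)
    return out


def reconstruct_grappa(
    y: KSpaceData,
    kernel_geometry: tuple[int, int] = (4, 5),
    lam: float = 1e-5,
    bias: BiasField | None = None,
) -> np.ndarray:
    """Full baseline reconstruction: calibrate on the ACS, fill missing lines,
    inverse-transform per coil and combine by root-sum-of-squares.

    An optional bias field is divided out of the combined magnitude, matching
    the homogenization applied to the network reconstruction so the two are
    comparable.
    """
    pattern = y.pattern
    if pattern.R > 1:
        acs = extract_acs(y.kspace, pattern)
        kernel = calibrate(acs, pattern.R, kernel_geometry, lam)
        filled = apply(y.kspace, kernel, pattern)
    else:
        filled = y.kspace
    img = rss_combine(ifft2c(filled))
    if bias is not None:
        img = bias_correct(img, bias)
    return img
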