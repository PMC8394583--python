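"""Pseudo-replica SNR maps.

The pseudo-multiple-replica method estimates per-pixel SNR of an arbitrary
reconstruction by Monte Carlo: add many synthetic complex Gaussian noise
realizations (matching the acquisition's noise level) to the measured
k-space, reconstruct each replica, and take the pixelwise standard deviation
of the replica magnitude stack as the noise estimate.  The signal is the
magnitude of the unperturbed reconstruction (a mean-of-replicas signal
variant is available via ``signal="replica_mean"``).

Magnitude statistics are used, matching clinical display; at low SNR the
magnitude noise distribution is Rician, so the std underestimates the
underlying complex noise there — comparisons should be read on high-signal
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .containers import KSpaceData
from .sampling import apply_mask

__all__ = ["SNRMap", "pseudo_replica_snr", "compare_snr"]

#: reported in place of infinite SNR where the replica std is exactly zero
SNR_CAP = np.inf


@dataclass
class SNRMap:
    """Per-pixel SNR plus the parameters it was estimated with."""

    snr: np.ndarray
    signal: np.ndarray
    noise_std: np.ndarray
    n_replicas: int
    noise_sigma: float
    label: str = ""


def pseudo_replica_snr(
    recon: Callable[[KSpaceData], np.ndarray],
    y: KSpaceData,
    noise_sigma: float,
    n_replicas: int = 100,
    seed: int = 0,
    label: str = "",
    signal: str = "unperturbed",
) -> SNRMap:
    """Estimate an SNR map for ``recon`` on acquisition ``y``.

    ``recon`` maps a :class:`KSpaceData` to a real (magnitude) image and must
    be deterministic.  Noise is added on sampled lines only; the whole
    procedure is deterministic under ``seed``.  Pixels whose replica std is
    exactly zero (e.g. ``noise_sigma = 0``) are flagged by an infinite SNR.
    """
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    base = np.abs(np.asarray(recon(y), dtype=float))
    if not np.all(np.isfinite(base)):
        raise ValueError("reconstruction returned non-finite values")
    rng = np.random.default_rng(seed)
    stack = np.empty((n_replicas, *base.shape))
    for r in range(n_replicas):
        eps = noise_sigma * (
            rng.standard_normal(y.kspace.shape)
            + 1j * rng.standard_normal(y.kspace.shape)
        )
        y_r = KSpaceData(
            kspace=y.kspace + apply_mask(eps, y.pattern),
            pattern=y.pattern,
            noise_sigma=y.noise_sigma,
            seed=y.seed,
            sens=y.sens,
            bias=y.bias,
        )
        stack[r] = np.abs(np.asarray(recon(y_r), dtype=float))
    noise_std = stack.std(axis=0, ddof=1)
    sig = stack.mean(axis=0) if signal == "replica_mean" else base
    # identical replicas leave only rounding residue in the std; flag those
    tiny = 1e-12 * max(float(sig.max()), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise_std > tiny, sig / np.maximum(noise_std, tiny), SNR_CAP)
    return SNRMap(
        snr=snr,
        signal=sig,
        noise_std=noise_std,
        n_replicas=n_replicas,
        noise_sigma=noise_sigma,
        label=label,
    )


def compare_snr(map_a: SNRMap, map_b: SNRMap, roi: np.ndarray) -> dict:
    """ROI summary of two SNR maps: means, their ratio, and per-map
    homogeneity as the coefficient of variation (std/mean) over the ROI."""
    if map_a.snr.shape != map_b.snr.shape or roi.shape != map_a.snr.shape:
        raise ValueError("maps and ROI must share one geometry")
    roi = roi.astype(bool)
    if not roi.any():
        raise ValueError("empty ROI")
    a, b = map_a.snr[roi], map_b.snr[roi]
    mean_a, mean_b = float(a.mean()), float(b.mean())
    return {
        "mean_a": mean_a,
        "mean_b": mean_b,
        "ratio": mean_a / mean_b,
        "cv_a": float(a.std() / mean_a),
        "cv_b": float(b.std() / mean_b),
    }
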