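"""Multi-scale structural similarity (MS-SSIM) with an analytic gradient.

Single-scale SSIM compares local luminance, contrast and structure through
Gaussian-windowed means and (co)variances:

    l  = (2 mu_p mu_t + C1) / (mu_p^2 + mu_t^2 + C1)
    cs = (2 sigma_pt + C2) / (sigma_p^2 + sigma_t^2 + C2)

with C1 = (k1 L)^2, C2 = (k2 L)^2 for data range L.  The multi-scale index
averages the contrast/structure term over a dyadic pyramid (2x2 mean pooling
between scales) and applies the luminance term only at the coarsest scale:

    MS-SSIM = l_M^w * prod_j cs_j^w ,   uniform weights w = 1/M.

Defaults: 3 scales (the toolkit's images are small), 11-tap Gaussian window
(sigma 1.5), k1 = 0.01, k2 = 0.03.  Filtering uses zero padding, which makes
the windowing operator self-adjoint, so the hand-derived gradient used in
training reuses the same filter.  Scale means are clamped at a small epsilon
before the geometric mean (gradient zero when clamped), guarding against
negative contrast terms on adversarial inputs.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate1d

__all__ = ["msssim", "msssim_and_grad"]

_EPS = 1e-6


def _gauss(win: int, sigma: float) -> np.ndarray:
    x = np.arange(win) - (win - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def _filt(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    y = correlate1d(x, k, axis=0, mode="constant")
    return correlate1d(y, k, axis=1, mode="constant")


def _pool(x: np.ndarray) -> np.ndarray:
    h2, w2 = x.shape[0] // 2, x.shape[1] // 2
    return x[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))


def _pool_bwd(dy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    dx = np.zeros(shape)
    up = np.repeat(np.repeat(dy, 2, axis=0), 2, axis=1) / 4.0
    dx[: up.shape[0], : up.shape[1]] = up
    return dx


def _scale_stats(p, t, k, C1, C2):
    mu_p, mu_t = _filt(p, k), _filt(t, k)
    sp = _filt(p * p, k) - mu_p**2
    st = _filt(t * t, k) - mu_t**2
    spt = _filt(p * t, k) - mu_p * mu_t
    cs_num, cs_den = 2.0 * spt + C2, sp + st + C2
    l_num, l_den = 2.0 * mu_p * mu_t + C1, mu_p**2 + mu_t**2 + C1
    return mu_p, mu_t, cs_num, cs_den, l_num, l_den


def _forward(p, t, data_range, n_scales, win, sigma, k1, k2):
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if min(p.shape) // 2 ** (n_scales - 1) < win:
        raise ValueError(
            f"image of shape {p.shape} too small for {n_scales} scales with "
            f"window {win}"
        )
    k = _gauss(win, sigma)
    C1, C2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    levels = []
    pj, tj = np.asarray(p, float), np.asarray(t, float)
    for j in range(n_scales):
        stats = _scale_stats(pj, tj, k, C1, C2)
        levels.append((pj, tj, stats))
        if j < n_scales - 1:
            pj, tj = _pool(pj), _pool(tj)
    w = 1.0 / n_scales
    cs_bars = [max(float(np.mean(s[2] / s[3])), _EPS) for _, _, s in levels]
    l_bar = max(float(np.mean(levels[-1][2][4] / levels[-1][2][5])), _EPS)
    value = l_bar**w * float(np.prod([c**w for c in cs_bars]))
    return value, (levels, cs_bars, l_bar, k, C1, C2, w)


def msssim(
    p: np.ndarray,
    t: np.ndarray,
    data_range: float,
    n_scales: int = 3,
    win: int = 11,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Multi-scale SSIM between two real images, in (0, 1]."""
    value, _ = _forward(p, t, data_range, n_scales, win, sigma, k1, k2)
    return value


def msssim_and_grad(
    p: np.ndarray,
    t: np.ndarray,
    data_range: float,
    n_scales: int = 3,
    win: int = 11,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> tuple[float, np.ndarray]:
    """MS-SSIM and its gradient with respect to the first argument."""
    value, (levels, cs_bars, l_bar, k, C1, C2, w) = _forward(
        p, t, data_range, n_scales, win, sigma, k1, k2
    )
    n_scales = len(levels)
    grad = None  # accumulated from coarsest to finest
    for j in reversed(range(n_scales)):
        pj, tj, (mu_p, mu_t, cs_num, cs_den, l_num, l_den) = levels[j]
        npx = pj.size
        # d value / d cs_bar_j (zero if the mean was clamped)
        raw_cs = float(np.mean(cs_num / cs_den))
        dval_dcs = value * w / cs_bars[j] if raw_cs > _EPS else 0.0
        dcs = np.full(pj.shape, dval_dcs / npx)
        # cs = N/D with N = 2 spt + C2, D = sp + st + C2
        dN = dcs / cs_den
        dD = -dcs * cs_num / cs_den**2
        dspt = 2.0 * dN
        dsp = dD
        # spt = G*(p t) - mu_p mu_t ; sp = G*(p^2) - mu_p^2
        dpj = tj * _filt(dspt, k) + 2.0 * pj * _filt(dsp, k)
        dmu_p = -mu_t * dspt - 2.0 * mu_p * dsp
        if j == n_scales - 1:
            raw_l = float(np.mean(l_num / l_den))
            dval_dl = value * w / l_bar if raw_l > _EPS else 0.0
            dl = np.full(pj.shape, dval_dl / npx)
            dmu_p += dl * (2.0 * mu_t * l_den - l_num * 2.0 * mu_p) / l_den**2
        dpj += _filt(dmu_p, k)
        # chain through the pooling pyramid back to full resolution
        for jj in reversed(range(j)):
            dpj = _pool_bwd(dpj, levels[jj][0].shape)
        grad = dpj if grad is None else grad + dpj
    return value, grad
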