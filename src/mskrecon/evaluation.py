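"""Image-quality metrics, acquisition-time arithmetic and reader-study statistics.

Three unrelated-looking concerns live together here because they are all
"evaluation": PSNR/NRMSE between reconstructions and ground truth, the
per-protocol acquisition-time savings of the accelerated sequences, and the
two statistics used for ordinal reader scores — the Wilcoxon signed-rank test
for paired 4-point Likert data and Cohen's kappa for inter-rater agreement.

The Wilcoxon implementation averages tied ranks and uses the exact sign-flip
null distribution up to 25 non-tied pairs (computed by convolution over the
doubled, hence integer, rank values), switching to the tie-corrected normal
approximation with continuity correction above that.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "psnr",
    "nrmse",
    "amplitude_fit",
    "SequenceTiming",
    "parse_ta",
    "load_timing_table",
    "time_saving",
    "summarize_savings",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "KappaResult",
    "cohen_kappa",
]

PSNR_CAP_DB = 300.0


def nrmse(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized root-mean-square error ||a - b|| / ||b||."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))


def psnr(a: np.ndarray, b: np.ndarray, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio of ``a`` against reference ``b``, in dB.

    ``peak`` defaults to ``max(|b|)``. Identical inputs are capped at 300 dB.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if peak is None:
        peak = float(np.abs(b).max())
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 20.0 * np.log10(peak) - 10.0 * np.log10(mse))


def amplitude_fit(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Return ``a`` rescaled by the least-squares real amplitude onto ``b``.

    Used before comparing reconstructions from different methods, so no method
    gains or loses dB from a trivial global scaling.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    denom = float(np.sum(a * a))
    if denom == 0.0:
        return a
    return a * (float(np.sum(a * b)) / denom)


# ---------------------------------------------------------------------------
# acquisition-time savings


@dataclass(frozen=True)
class SequenceTiming:
    """One protocol's acquisition times: conventional vs accelerated, seconds."""

    region: str
    sequence: str
    orientation: str
    ta_standard: float
    ta_dl: float

    @property
    def label(self) -> str:
        return f"{self.region} {self.sequence} {self.orientation}"


def parse_ta(text: str) -> float:
    """Parse an acquisition time like ``'2:23'`` (min:sec) into seconds."""
    m, s = str(text).strip().split(":")
    return 60.0 * int(m) + float(s)


def load_timing_table(path: str | Path | None = None) -> list[SequenceTiming]:
    """Load a timing table CSV (columns region, sequence, orientation,
    ta_standard, ta_dl in min:sec).  Without a path, the packaged table of the
    twelve 3 T musculoskeletal TSE protocols is used."""
    if path is None:
        ref = resources.files("mskrecon.data").joinpath("table1_timings.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return [
        SequenceTiming(
            region=str(r.region),
            sequence=str(r.sequence),
            orientation=str(r.orientation),
            ta_standard=parse_ta(r.ta_standard),
            ta_dl=parse_ta(r.ta_dl),
        )
        for r in df.itertuples()
    ]


def time_saving(t: SequenceTiming) -> float:
    """Acquisition-time saving in percent: ``100 * (1 - ta_dl/ta_standard)``."""
    if t.ta_standard <= 0 or t.ta_dl <= 0:
        raise ValueError(f"acquisition times must be positive: {t}")
    return 100.0 * (1.0 - t.ta_dl / t.ta_standard)


def summarize_savings(table: list[SequenceTiming]) -> dict:
    """Per-entry savings plus extrema; reported values rounded to integer %."""
    if not table:
        raise ValueError("empty timing table")
    per_entry = [
        {"label": t.label, "percent": time_saving(t), "percent_rounded": int(round(time_saving(t)))}
        for t in table
    ]
    raw = [e["percent"] for e in per_entry]
    return {
        "per_entry": per_entry,
        "max_percent": int(round(max(raw))),
        "min_percent": int(round(min(raw))),
        "max_percent_raw": max(raw),
        "min_percent_raw": min(raw),
    }


# ---------------------------------------------------------------------------
# reader-study statistics


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ : sum of ranks of positive differences
    p_value: float
    n_used: int  # pairs remaining after dropping zero differences
    method: str  # "exact" or "normal"


def _exact_sf_cdf(ranks: np.ndarray, w_plus: float) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) under random sign flips with these ranks.

    Ranks are averaged over ties, hence multiples of 1/2; doubling makes them
    integers, and the null distribution of 2*W+ is built by convolution.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    dist = np.zeros(int(r2.sum()) + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: len(dist) - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(np.rint(2.0 * w_plus))
    return float(dist[: w2 + 1].sum()), float(dist[w2:].sum())


def wilcoxon_signed_rank(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> WilcoxonResult:
    """Wilcoxon signed-rank test for paired (ordinal) samples.

    Zero differences are dropped; tied absolute differences get averaged
    ranks.  The statistic is W+, the rank sum of pairs where ``a > b``.  The
    p-value uses the exact sign-flip distribution for up to 25 non-tied pairs
    and the tie-corrected normal approximation with continuity correction
    beyond.  ``alternative`` is ``"two-sided"``, ``"greater"`` (a > b) or
    ``"less"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expected two equal-length 1-D score vectors")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all pairs are tied; the signed-rank test is undefined")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= 25:
        cdf, sf = _exact_sf_cdf(ranks, w_plus)
        method = "exact"
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(cdf, sf))
    else:
        method = "normal"
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        if alternative == "greater":
            p = float(norm.sf((w_plus - mu - 0.5) / sigma))
        elif alternative == "less":
            p = float(norm.cdf((w_plus - mu + 0.5) / sigma))
        else:
            z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
            p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_plus, p_value=p, n_used=n, method=method)


KAPPA_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "(almost) perfect"),
)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    band: str


def kappa_band(kappa: float) -> str:
    """Map a kappa value to the conventional agreement band."""
    for hi, label in KAPPA_BANDS:
        if kappa <= hi + 1e-12:
            return label
    return KAPPA_BANDS[-1][1]


def cohen_kappa(ratings_a, ratings_b) -> KappaResult:
    """Unweighted Cohen's kappa between two raters: (p_o - p_e) / (1 - p_e).

    Raises when chance agreement p_e = 1 (each rater constant), where kappa
    is undefined.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("expected two equal-length non-empty rating vectors")
    cats = np.unique(np.concatenate([a, b]))
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    k = len(cats)
    conf = np.zeros((k, k))
    np.add.at(conf, (ai, bi), 1.0)
    n = conf.sum()
    p_o = np.trace(conf) / n
    p_e = float(np.sum(conf.sum(axis=1) * conf.sum(axis=0)) / n**2)
    if p_e >= 1.0 - 1e-15:
        raise ValueError("chance agreement p_e = 1; kappa is undefined")
    kappa = float((p_o - p_e) / (1.0 - p_e))
    return KappaResult(kappa=kappa, band=kappa_band(kappa))
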