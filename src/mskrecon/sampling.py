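"""Regular Cartesian undersampling patterns with an autocalibration region.

Acquisition time in Cartesian TSE imaging is proportional to the number of
phase-encoding (PE) lines acquired, so acceleration is expressed entirely as a
per-line boolean mask: the readout direction is always fully sampled.  A
pattern is the union of

* a regular grid of lines congruent to ``offset`` modulo the acceleration
  factor ``R`` (the parallel-imaging part),
* a contiguous, fully sampled autocalibration (ACS) block centered on the
  k-space center line, used to calibrate coil sensitivities and GRAPPA
  kernels,

restricted to the retained phase-resolution band: a fraction of the k-space
periphery may be skipped entirely ("phase resolution" < 100%), trading
resolution along PE for speed.  Skipped peripheral lines are zero-filled, not
cropped, so one matrix size flows through the whole pipeline.

The k-space center line is index ``n_pe // 2`` (0-based), matching the
centered FFT layout of :mod:`mskrecon.fourier`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SamplingPattern",
    "make_regular_mask",
    "apply_mask",
    "extract_acs",
    "nominal_scan_time_factor",
]


@dataclass(frozen=True)
class SamplingPattern:
    """A per-phase-encode-line sampling mask and the parameters that built it.

    Attributes
    ----------
    n_pe, n_ro : int
        Matrix size (phase-encode lines x readout samples).
    R : int
        Integer acceleration factor of the regular grid (>= 1).
    acs_width : int
        Number of contiguous fully sampled central lines.
    phase_resolution : float
        Fraction in (0, 1] of PE lines retained before regular undersampling.
    offset : int
        Phase of the regular grid in [0, R).
    mask : np.ndarray
        Boolean, shape ``(n_pe,)``; True where the line is acquired.
    """

    n_pe: int
    n_ro: int
    R: int
    acs_width: int
    phase_resolution: float
    offset: int
    mask: np.ndarray = field(repr=False)

    @property
    def center_line(self) -> int:
        return self.n_pe // 2

    @property
    def acs_slice(self) -> slice:
        start = self.center_line - self.acs_width // 2
        return slice(start, start + self.acs_width)

    @property
    def band(self) -> slice:
        """Retained phase-resolution band (low-index, high-index exclusive)."""
        # tiny epsilon guards the floor against binary-fraction wobble
        # (e.g. 65 * (1 - 0.8) = 12.999...)
        n_removed = int(np.floor(self.n_pe * (1.0 - self.phase_resolution) + 1e-9))
        lo = n_removed // 2
        hi = n_removed - lo  # odd leftover removed from the high-index edge
        return slice(lo, self.n_pe - hi)

    def sampled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def n_sampled(self) -> int:
        return int(self.mask.sum())

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_pe": self.n_pe,
            "n_ro": self.n_ro,
            "R": self.R,
            "acs_width": self.acs_width,
            "phase_resolution": self.phase_resolution,
            "offset": self.offset,
            "sampled_indices": self.sampled_indices().tolist(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "SamplingPattern":
        mask = np.zeros(d["n_pe"], dtype=bool)
        mask[np.asarray(d["sampled_indices"], dtype=int)] = True
        return cls(
            n_pe=d["n_pe"],
            n_ro=d["n_ro"],
            R=d["R"],
            acs_width=d["acs_width"],
            phase_resolution=d["phase_resolution"],
            offset=d["offset"],
            mask=mask,
        )

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SamplingPattern":
        p = Path(text_or_path)
        if p.exists():
            text_or_path = p.read_text()
        return cls.from_dict(json.loads(str(text_or_path)))


def make_regular_mask(
    n_pe: int,
    R: int,
    acs_width: int,
    phase_resolution: float = 1.0,
    offset: int = 0,
    n_ro: int | None = None,
) -> SamplingPattern:
    """Build a regular undersampling pattern with a centered ACS block.

    Parameters
    ----------
    n_pe : int
        Number of phase-encoding lines of the full matrix.
    R : int
        Integer acceleration factor (>= 1). Lines congruent to ``offset``
        modulo ``R`` are acquired.
    acs_width : int
        Width of the fully sampled central autocalibration block (may be 0).
    phase_resolution : float
        Fraction in (0, 1] of lines retained; ``floor(n_pe*(1-p))`` peripheral
        lines are dropped, split as evenly as possible between the two edges
        (the odd leftover from the high-index edge).
    offset : int
        Phase of the regular grid, in ``[0, R)``.
    n_ro : int, optional
        Readout extent stored with the pattern (defaults to ``n_pe``).
    """
    if not (isinstance(R, (int, np.integer)) and not isinstance(R, bool)):
        raise TypeError(f"R must be an integer, got {R!r}")
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    if not 0 <= acs_width <= n_pe:
        raise ValueError(f"acs_width must be in [0, n_pe], got {acs_width}")
    if not 0.0 < phase_resolution <= 1.0:
        raise ValueError(f"phase_resolution must be in (0, 1], got {phase_resolution}")
    if not 0 <= offset < R:
        raise ValueError(f"offset must be in [0, R), got {offset}")

    pattern = SamplingPattern(
        n_pe=n_pe,
        n_ro=n_pe if n_ro is None else n_ro,
        R=int(R),
        acs_width=acs_width,
        phase_resolution=float(phase_resolution),
        offset=offset,
        mask=np.zeros(n_pe, dtype=bool),
    )
    band = pattern.band
    band_width = band.stop - band.start
    if acs_width > band_width:
        raise ValueError(
            f"acs_width={acs_width} exceeds retained phase-resolution band "
            f"width {band_width}"
        )
    acs = pattern.acs_slice
    if acs_width > 0 and (acs.start < band.start or acs.stop > band.stop):
        raise ValueError(
            "centered ACS block does not fit inside the retained "
            f"phase-resolution band [{band.start}, {band.stop})"
        )

    idx = np.arange(n_pe)
    mask = (idx % R == offset) & (idx >= band.start) & (idx < band.stop)
    if acs_width > 0:
        mask[acs] = True
    pattern.mask[:] = mask
    return pattern


def apply_mask(kspace: np.ndarray, pattern: SamplingPattern) -> np.ndarray:
    """Zero every unsampled phase-encoding line (retrospective undersampling).

    ``kspace`` has shape ``(..., n_pe, n_ro)``; sampled lines pass through
    bit-identically.
    """
    if kspace.shape[-2] != pattern.n_pe:
        raise ValueError(
            f"k-space PE extent {kspace.shape[-2]} != pattern n_pe {pattern.n_pe}"
        )
    return kspace * pattern.mask[:, None]


def extract_acs(kspace: np.ndarray, pattern: SamplingPattern) -> np.ndarray:
    """Return the fully sampled central calibration block, all readout samples."""
    if pattern.acs_width < 1:
        raise ValueError("pattern has no ACS block (acs_width = 0)")
    if kspace.shape[-2] != pattern.n_pe:
        raise ValueError(
            f"k-space PE extent {kspace.shape[-2]} != pattern n_pe {pattern.n_pe}"
        )
    return kspace[..., pattern.acs_slice, :]


def nominal_scan_time_factor(pattern: SamplingPattern) -> float:
    """Fraction of the full acquisition time this pattern requires.

    Scan time is proportional to the acquired line count, so the factor is
    simply ``n_sampled / n_pe`` (in (0, 1]).
    """
    return pattern.n_sampled / pattern.n_pe
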