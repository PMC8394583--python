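"""Synthetic multi-coil Cartesian TSE-like acquisitions.

Everything in this package trains and tests on generated data, so this module
defines the study conditions: piecewise-smooth 2-D ellipse phantoms (standing
in for musculoskeletal TSE slices), smooth complex coil sensitivities on a
ring around the FOV, a smooth multiplicative bias field, and the SENSE forward
model with i.i.d. complex Gaussian k-space noise on the sampled lines.
Defaults follow the accelerated-TSE protocol this toolkit models: acceleration
factor R = 4 with a 16-line autocalibration block.

All randomness is driven by explicit integer seeds; identical arguments give
bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import KSpaceData
from .fourier import fft2c
from .sampling import SamplingPattern, apply_mask, make_regular_mask
from .sense import BiasField, CoilSensitivities

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "AcquisitionSpec",
    "TrainingItem",
    "TrainingSet",
    "render_phantom",
    "simulate_sensitivities",
    "simulate_bias_field",
    "simulate_acquisition",
    "make_training_set",
    "random_phantom",
    "knee_like_phantom",
]


def _grid(matrix: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Normalized pixel-center coordinates in [-1, 1), origin at the FFT center."""
    n_pe, n_ro = matrix
    y = (np.arange(n_pe) - n_pe // 2) / (n_pe / 2)
    x = (np.arange(n_ro) - n_ro // 2) / (n_ro / 2)
    return np.meshgrid(y, x, indexing="ij")


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse: center, semi-axes and rotation in normalized
    [-1, 1] coordinates, plus the intensity added inside it."""

    cy: float
    cx: float
    a: float  # semi-axis along the (rotated) y direction
    b: float  # semi-axis along the (rotated) x direction
    theta: float = 0.0  # rotation, radians
    intensity: float = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """A piecewise-constant phantom: sum of ellipse intensities per pixel,
    optional fine sinusoidal texture on the support and a smooth linear phase
    ramp (cycles across the FOV) making the image genuinely complex."""

    matrix: tuple[int, int]
    ellipses: tuple[Ellipse, ...]
    texture_amplitude: float = 0.0
    phase_ramp: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Receive-chain and noise model parameters.

    ``noise_sigma`` is the standard deviation per real/imaginary component of
    the complex Gaussian k-space noise; under the unitary FFT convention it
    is also the per-coil image-domain noise std, so the default 0.015 yields
    roughly 30 dB input SNR for the unit-intensity phantoms used here.
    ``seed`` fixes all randomness derived from the spec.
    """

    n_coils: int = 8
    coil_width: float = 0.9  # Gaussian sensitivity width, normalized units
    ring_radius: float = 1.2  # coil-center ring radius, normalized units
    phase_amplitude: float = 1.0  # per-coil linear phase slope, radians across FOV
    bias_order: int = 2
    bias_amplitude: float = 0.3
    noise_sigma: float = 0.015
    seed: int = 0


# ---------------------------------------------------------------------------
# phantom rendering


def render_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render a :class:`PhantomSpec` to a complex image.

    Each pixel's value is the sum of the intensities of the ellipses whose
    interior contains the pixel center; texture and the phase ramp are applied
    on the resulting support.
    """
    if len(spec.ellipses) < 1:
        raise ValueError("phantom needs at least one ellipse")
    Y, X = _grid(spec.matrix)
    img = np.zeros(spec.matrix, dtype=float)
    for e in spec.ellipses:
        if e.a <= 0 or e.b <= 0:
            raise ValueError(f"degenerate ellipse with non-positive axis: {e}")
        dy, dx = Y - e.cy, X - e.cx
        u = np.cos(e.theta) * dy + np.sin(e.theta) * dx
        v = -np.sin(e.theta) * dy + np.cos(e.theta) * dx
        img += e.intensity * ((u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0)
    if spec.texture_amplitude:
        img += (
            spec.texture_amplitude
            * (img != 0)
            * np.cos(6.5 * np.pi * Y)
            * np.cos(4.5 * np.pi * X)
        )
    gy, gx = spec.phase_ramp
    return img * np.exp(1j * np.pi * (gy * Y + gx * X))


# ---------------------------------------------------------------------------
# receive chain


def simulate_sensitivities(
    acq: AcquisitionSpec, matrix: tuple[int, int]
) -> CoilSensitivities:
    """Smooth complex coil maps: Gaussian magnitudes centered on a ring around
    the FOV, per-coil linear phase, RSS-normalized to 1 at every pixel.

    The coil-average phase ramp is subtracted before normalization (coil
    phases are only ever defined relative to a reference), so a single coil
    yields the identity map.
    """
    if acq.n_coils < 1:
        raise ValueError("need at least one coil")
    Y, X = _grid(matrix)
    thetas = 2.0 * np.pi * np.arange(acq.n_coils) / acq.n_coils
    mags = np.empty((acq.n_coils, *matrix))
    phases = np.empty((acq.n_coils, *matrix))
    for c, th in enumerate(thetas):
        cy, cx = acq.ring_radius * np.sin(th), acq.ring_radius * np.cos(th)
        mags[c] = np.exp(-((Y - cy) ** 2 + (X - cx) ** 2) / (2.0 * acq.coil_width**2))
        phases[c] = acq.phase_amplitude * (np.cos(th) * X + np.sin(th) * Y) + 0.5 * th
    phases -= phases.mean(axis=0)
    maps = mags * np.exp(1j * phases)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    # Gaussians are strictly positive, so rss > 0 everywhere; full support.
    maps = maps / rss
    return CoilSensitivities(maps=maps, support=np.ones(matrix, dtype=bool))


def simulate_bias_field(
    acq: AcquisitionSpec,
    matrix: tuple[int, int],
    coefficients: np.ndarray | None = None,
) -> BiasField:
    """Exponentiated low-order polynomial bias field, normalized to mean 1.

    ``coefficients`` orders the monomials ``y**i * x**j`` for ``i + j`` from 1
    to ``bias_order`` (no constant term, which the mean normalization would
    cancel anyway), lexicographic in ``(i, j)``.  When omitted they are drawn
    from ``acq.seed`` and scaled by ``bias_amplitude``.
    """
    if acq.bias_amplitude < 0:
        raise ValueError("bias_amplitude must be >= 0")
    exponents = [
        (i, j)
        for total in range(1, acq.bias_order + 1)
        for i in range(total + 1)
        for j in [total - i]
    ]
    if coefficients is None:
        rng = np.random.default_rng([acq.seed, 0x1A5])
        coefficients = acq.bias_amplitude * rng.standard_normal(len(exponents))
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (len(exponents),):
        raise ValueError(
            f"expected {len(exponents)} coefficients for order {acq.bias_order}"
        )
    Y, X = _grid(matrix)
    log_field = np.zeros(matrix)
    for c, (i, j) in zip(coefficients, exponents):
        log_field += c * Y**i * X**j
    b = np.exp(log_field)
    b /= b.mean()
    return BiasField(field=b)


# ---------------------------------------------------------------------------
# forward model


def simulate_acquisition(
    image: np.ndarray,
    sens: CoilSensitivities,
    bias: BiasField,
    pattern: SamplingPattern,
    noise_sigma: float,
    seed: int,
) -> KSpaceData:
    """Run the SENSE forward model and add sampled-line k-space noise.

    Per coil: ``k_c = mask * F(bias * s_c * image)`` plus i.i.d. complex
    Gaussian noise (std ``noise_sigma`` per component) on sampled lines only.
    The noise realization depends only on ``seed`` and the matrix size, not on
    the mask, so retrospectively changing the pattern reuses the same draws.
    """
    if image.shape != sens.shape or image.shape != bias.shape:
        raise ValueError("image / sensitivities / bias shapes disagree")
    if image.shape[0] != pattern.n_pe or image.shape[1] != pattern.n_ro:
        raise ValueError("image shape does not match sampling pattern")
    kspace = apply_mask(fft2c(sens.maps * (bias.field * image)), pattern)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = noise_sigma * (
            rng.standard_normal(kspace.shape) + 1j * rng.standard_normal(kspace.shape)
        )
        kspace = kspace + apply_mask(noise, pattern)
    return KSpaceData(
        kspace=kspace,
        pattern=pattern,
        noise_sigma=noise_sigma,
        seed=seed,
        sens=sens,
        bias=bias,
    )


# ---------------------------------------------------------------------------
# training corpora


@dataclass
class TrainingItem:
    """One self-consistent tuple: ground-truth image, its noiseless fully
    sampled multi-coil k-space, and the acquisition it will be measured with."""

    image: np.ndarray
    kspace_full: np.ndarray
    pattern: SamplingPattern
    sens: CoilSensitivities
    bias: BiasField
    noise_sigma: float
    seed: int
    split: str = "train"

    def acquire(self) -> KSpaceData:
        """Retrospectively undersample and add the item's noise realization."""
        return simulate_acquisition(
            self.image, self.sens, self.bias, self.pattern, self.noise_sigma, self.seed
        )


@dataclass
class TrainingSet:
    items: list[TrainingItem] = field(default_factory=list)

    def subset(self, split: str) -> list[TrainingItem]:
        return [it for it in self.items if it.split == split]

    @property
    def train(self) -> list[TrainingItem]:
        return self.subset("train")

    @property
    def val(self) -> list[TrainingItem]:
        return self.subset("val")

    @property
    def test(self) -> list[TrainingItem]:
        return self.subset("test")


#: default randomization ranges standing in for the anatomical diversity of a
#: clinical training corpus (several body regions and contrasts)
DEFAULT_PHANTOM_RANGES: dict = {
    "n_inner": (2, 6),  # inclusive range of inner structures
    "body_axis": (0.55, 0.8),
    "body_intensity": (0.6, 0.9),
    "inner_axis": (0.06, 0.3),
    "inner_intensity": (-0.4, 0.5),
    "texture": (0.0, 0.06),
    "phase_ramp": (-1.5, 1.5),
}


def random_phantom(
    rng: np.random.Generator,
    matrix: tuple[int, int],
    ranges: dict | None = None,
) -> PhantomSpec:
    """Draw a random anatomical-ish phantom: one body ellipse plus a few
    inner structures, random texture and phase ramp."""
    r = dict(DEFAULT_PHANTOM_RANGES)
    if ranges:
        r.update(ranges)
    body = Ellipse(
        cy=rng.uniform(-0.08, 0.08),
        cx=rng.uniform(-0.08, 0.08),
        a=rng.uniform(*r["body_axis"]),
        b=rng.uniform(*r["body_axis"]),
        theta=rng.uniform(0, np.pi),
        intensity=rng.uniform(*r["body_intensity"]),
    )
    ellipses = [body]
    for _ in range(rng.integers(r["n_inner"][0], r["n_inner"][1] + 1)):
        ellipses.append(
            Ellipse(
                cy=rng.uniform(-0.4, 0.4),
                cx=rng.uniform(-0.4, 0.4),
                a=rng.uniform(*r["inner_axis"]),
                b=rng.uniform(*r["inner_axis"]),
                theta=rng.uniform(0, np.pi),
                intensity=rng.uniform(*r["inner_intensity"]),
            )
        )
    return PhantomSpec(
        matrix=matrix,
        ellipses=tuple(ellipses),
        texture_amplitude=rng.uniform(*r["texture"]),
        phase_ramp=(rng.uniform(*r["phase_ramp"]), rng.uniform(*r["phase_ramp"])),
    )


def knee_like_phantom(matrix: tuple[int, int] = (96, 96)) -> PhantomSpec:
    """Fixed sagittal-knee-like phantom used for SNR-map comparisons: two
    bone-like ellipses with a thin bright cartilage-like interface inside a
    soft-tissue body."""
    return PhantomSpec(
        matrix=matrix,
        ellipses=(
            Ellipse(0.0, 0.0, 0.78, 0.62, 0.15, 0.7),  # soft tissue body
            Ellipse(-0.33, -0.05, 0.28, 0.20, 0.25, -0.35),  # femur-like
            Ellipse(0.38, 0.02, 0.22, 0.26, -0.1, -0.30),  # tibia-like
            Ellipse(0.02, 0.0, 0.06, 0.30, 0.0, 0.45),  # cartilage-like band
            Ellipse(-0.05, 0.42, 0.10, 0.07, 0.0, 0.25),  # small structure
        ),
        texture_amplitude=0.04,
        phase_ramp=(0.6, -0.4),
    )


def make_training_set(
    n_items: int,
    phantom_ranges: dict | None = None,
    acq: AcquisitionSpec | None = None,
    R: int = 4,
    acs_width: int = 16,
    matrix: tuple[int, int] = (96, 96),
    phase_resolution: float = 1.0,
    seed: int = 0,
    splits: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> TrainingSet:
    """Generate a reproducible phantom corpus with train/val/test labels.

    The acquisition defaults match the accelerated protocol the network is
    meant for: R = 4 with a 16-line ACS block.  Coil sensitivities are shared
    across items (one scanner, one coil array); the bias field and phantom are
    redrawn per item (one per subject).
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    acq = acq or AcquisitionSpec()
    rng = np.random.default_rng(seed)
    pattern = make_regular_mask(
        matrix[0], R, acs_width, phase_resolution=phase_resolution, n_ro=matrix[1]
    )
    sens = simulate_sensitivities(acq, matrix)

    n_val = max(1, round(splits[1] * n_items)) if n_items >= 3 else 0
    n_test = max(1, round(splits[2] * n_items)) if n_items >= 3 else 0
    n_train = n_items - n_val - n_test
    labels = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test

    n_bias_coeffs = sum(t + 1 for t in range(1, acq.bias_order + 1))
    items = []
    for label in labels:
        spec = random_phantom(rng, matrix, phantom_ranges)
        image = render_phantom(spec)
        coeffs = acq.bias_amplitude * rng.standard_normal(n_bias_coeffs)
        bias = simulate_bias_field(acq, matrix, coefficients=coeffs)
        item_seed = int(rng.integers(0, 2**31 - 1))
        kspace_full = fft2c(sens.maps * (bias.field * image))
        items.append(
            TrainingItem(
                image=image,
                kspace_full=kspace_full,
                pattern=pattern,
                sens=sens,
                bias=bias,
                noise_sigma=acq.noise_sigma,
                seed=item_seed,
                split=label,
            )
        )
    return TrainingSet(items=items)
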