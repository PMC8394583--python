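"""The k-space container and its HDF5 persistence.

:class:`KSpaceData` is the unit of work for every reconstruction: multi-coil
complex Cartesian k-space together with its sampling pattern, the noise level
it was (or is believed to have been) acquired at, and optionally the coil
sensitivities and bias field that belong to it.  On disk it is a flat
HDF5 layout in the spirit of raw-data containers such as ISMRMRD: datasets
``kspace`` (coil x pe x ro, complex), ``mask``, optional ``sens``/``support``
and ``bias``, with acquisition parameters as root attributes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .sampling import SamplingPattern
from .sense import BiasField, CoilSensitivities

__all__ = ["KSpaceData", "save_kspace", "load_kspace",
           "save_training_item", "load_training_item"]


@dataclass
class KSpaceData:
    """Multi-coil k-space plus everything needed to reconstruct it."""

    kspace: np.ndarray  # (n_coils, n_pe, n_ro) complex
    pattern: SamplingPattern
    noise_sigma: float = 0.0
    seed: int | None = None
    sens: CoilSensitivities | None = None
    bias: BiasField | None = None

    @property
    def n_coils(self) -> int:
        return self.kspace.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.kspace.shape[-2:]


def save_kspace(path: str | Path, data: KSpaceData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=np.asarray(data.kspace, dtype=np.complex128))
        f.create_dataset("mask", data=data.pattern.mask.astype(np.uint8))
        if data.sens is not None:
            f.create_dataset("sens", data=data.sens.maps.astype(np.complex128))
            f.create_dataset("support", data=data.sens.support.astype(np.uint8))
        if data.bias is not None:
            f.create_dataset("bias", data=data.bias.field.astype(np.float64))
            f.attrs["bias_floor"] = data.bias.floor
        p = data.pattern
        f.attrs.update(
            {
                "n_pe": p.n_pe,
                "n_ro": p.n_ro,
                "R": p.R,
                "acs_width": p.acs_width,
                "phase_resolution": p.phase_resolution,
                "offset": p.offset,
                "noise_sigma": data.noise_sigma,
            }
        )
        if data.seed is not None:
            f.attrs["seed"] = data.seed


def load_kspace(path: str | Path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        kspace = f["kspace"][...]
        mask = f["mask"][...].astype(bool)
        a = dict(f.attrs)
        pattern = SamplingPattern(
            n_pe=int(a["n_pe"]),
            n_ro=int(a["n_ro"]),
            R=int(a["R"]),
            acs_width=int(a["acs_width"]),
            phase_resolution=float(a["phase_resolution"]),
            offset=int(a["offset"]),
            mask=mask,
        )
        sens = None
        if "sens" in f:
            sens = CoilSensitivities(
                maps=f["sens"][...], support=f["support"][...].astype(bool)
            )
        bias = None
        if "bias" in f:
            bias = BiasField(
                field=f["bias"][...], floor=float(a.get("bias_floor", 1e-3))
            )
        return KSpaceData(
            kspace=kspace,
            pattern=pattern,
            noise_sigma=float(a.get("noise_sigma", 0.0)),
            seed=int(a["seed"]) if "seed" in a else None,
            sens=sens,
            bias=bias,
        )


def save_training_item(path: str | Path, item) -> None:
    """Persist a simulated training tuple (ground truth + noiseless full
    k-space + acquisition context) for the command-line workflow."""
    with h5py.File(path, "w") as f:
        f.create_dataset("truth", data=np.asarray(item.image, dtype=np.complex128))
        f.create_dataset(
            "kspace_full", data=np.asarray(item.kspace_full, dtype=np.complex128)
        )
        f.create_dataset("mask", data=item.pattern.mask.astype(np.uint8))
        f.create_dataset("sens", data=item.sens.maps.astype(np.complex128))
        f.create_dataset("support", data=item.sens.support.astype(np.uint8))
        f.create_dataset("bias", data=item.bias.field.astype(np.float64))
        p = item.pattern
        f.attrs.update(
            {
                "n_pe": p.n_pe,
                "n_ro": p.n_ro,
                "R": p.R,
                "acs_width": p.acs_width,
                "phase_resolution": p.phase_resolution,
                "offset": p.offset,
                "noise_sigma": item.noise_sigma,
                "seed": item.seed,
                "split": item.split,
                "bias_floor": item.bias.floor,
            }
        )


def load_training_item(path: str | Path):
    from .synthetic import TrainingItem  # local import to avoid a cycle

    with h5py.File(path, "r") as f:
        a = dict(f.attrs)
        pattern = SamplingPattern(
            n_pe=int(a["n_pe"]),
            n_ro=int(a["n_ro"]),
            R=int(a["R"]),
            acs_width=int(a["acs_width"]),
            phase_resolution=float(a["phase_resolution"]),
            offset=int(a["offset"]),
            mask=f["mask"][...].astype(bool),
        )
        return TrainingItem(
            image=f["truth"][...],
            kspace_full=f["kspace_full"][...],
            pattern=pattern,
            sens=CoilSensitivities(
                maps=f["sens"][...], support=f["support"][...].astype(bool)
            ),
            bias=BiasField(
                field=f["bias"][...], floor=float(a.get("bias_floor", 1e-3))
            ),
            noise_sigma=float(a["noise_sigma"]),
            seed=int(a["seed"]),
            split=str(a.get("split", "train")),
        )
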