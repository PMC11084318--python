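"""Synthetic well-plate radiographs emulating the physical experiment.

The physical study radiographs a 96-well plate holding two rows of contrast
solutions on a general-purpose radiographic system at 46/80/95/100 kVp with
automatic exposure control (AEC).  This module emulates that acquisition so
the ROI analysis stage can run without access to the deposited experimental
images:

* energy-integrating polychromatic projection of the well-plate phantom,
* AEC emulation: incident fluence is scaled so the mean background signal
  (plate without wells) lands on a fixed target digital number,
* Poisson noise at the emulated photon-count level, then 16-bit quantization.

Raw-detector grey-value polarity is used (more photons = larger digital
number).  Scatter and detector blur are not modelled.  Every image is
deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .phantom import PhantomSpec, build_wellplate_phantom
from .projector import (
    AcquisitionGeometry,
    PathLengthSet,
    project_polychromatic,
    radiograph_geometry,
)
from .spectra import Spectrum, spectrum_for_kvp

__all__ = [
    "AcquisitionProtocol",
    "DigitalRadiograph",
    "ProtocolError",
    "simulate_radiograph",
    "generate_study",
    "read_manifest",
]

DIGITAL_MAX = 65535


class ProtocolError(ValueError):
    """Raised when an acquisition protocol cannot be realized."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Acquisition settings of one synthetic radiograph."""

    kvp: float
    spectrum: Optional[Spectrum] = None  # default: bundled fixture for kvp
    aec_target: float = 0.6 * DIGITAL_MAX  # mean background digital number
    photons_background: float = 10_000.0  # mean photon count behind the plate
    seed: int = 0
    noise: bool = True
    geometry: AcquisitionGeometry = field(default_factory=radiograph_geometry)

    def __post_init__(self) -> None:
        if not 0 < self.aec_target <= DIGITAL_MAX:
            raise ProtocolError("AEC target outside the digital range")
        if self.photons_background <= 0:
            raise ProtocolError("photon budget must be positive")

    def resolved_spectrum(self) -> Spectrum:
        return self.spectrum if self.spectrum is not None else spectrum_for_kvp(self.kvp)


@dataclass(frozen=True)
class DigitalRadiograph:
    """16-bit synthetic radiograph with its acquisition metadata."""

    values: np.ndarray  # uint16
    protocol: AcquisitionProtocol
    background_mean: float  # realized mean background DN
    gain_dn_per_photon: float


def simulate_radiograph(plate: PhantomSpec, protocol: AcquisitionProtocol,
                        paths: Optional[PathLengthSet] = None) -> DigitalRadiograph:
    """Simulate one AEC-controlled radiograph of the well plate.

    The background region (plate base present, no liquid column) defines the
    AEC reference: its mean signal is scaled to ``aec_target`` digital numbers
    at ``photons_background`` mean counts per pixel, fixing the DN-per-photon
    gain.  Poisson noise (if enabled) is applied in the photon-count domain.
    """
    spectrum = protocol.resolved_spectrum()
    paths = paths or PathLengthSet(plate, protocol.geometry)
    intensity = project_polychromatic(plate, protocol.geometry, spectrum,
                                      weighting="energy", paths=paths)
    background = paths.slab_mask & ~paths.disk_mask
    if not np.any(background):
        raise ProtocolError("plate layout leaves no background region for AEC")
    mean_bg_rel = float(intensity.values[background].mean())
    if mean_bg_rel <= 0:
        raise ProtocolError("AEC target unreachable: opaque background")
    counts = intensity.values * (protocol.photons_background / mean_bg_rel)
    if protocol.noise:
        rng = np.random.default_rng(protocol.seed)
        counts = rng.poisson(counts).astype(float)
    gain = protocol.aec_target / protocol.photons_background  # DN per photon
    dn = np.clip(np.round(counts * gain), 0, DIGITAL_MAX).astype(np.uint16)
    return DigitalRadiograph(
        values=dn,
        protocol=protocol,
        background_mean=float(dn[background].mean()),
        gain_dn_per_photon=gain,
    )


def generate_study(
    out_dir,
    kvps: Sequence[float] = (46.0, 80.0, 95.0, 100.0),
    replicates: int = 1,
    base_seed: int = 0,
    plate: Optional[PhantomSpec] = None,
    noise: bool = True,
    aec_target: float = 0.6 * DIGITAL_MAX,
    photons_background: float = 10_000.0,
) -> pd.DataFrame:
    """Write one synthetic radiograph per (kVp, replicate) plus a manifest.

    Seeds are derived deterministically as ``base_seed + 1000*k + r`` for the
    k-th kVp and r-th replicate.  Returns the manifest (also written as TSV).
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plate = plate if plate is not None else build_wellplate_phantom()
    paths: dict = {}
    rows = []
    for k, kvp in enumerate(kvps):
        for r in range(replicates):
            seed = base_seed + 1000 * k + r
            protocol = AcquisitionProtocol(
                kvp=float(kvp), seed=seed, noise=noise, aec_target=aec_target,
                photons_background=photons_background)
            key = protocol.geometry
            if key not in paths:
                paths[key] = PathLengthSet(plate, protocol.geometry)
            image = simulate_radiograph(plate, protocol, paths=paths[key])
            name = f"radiograph_{int(kvp):03d}kvp_rep{r:02d}.tif"
            target = out / name
            if target.exists():
                raise FileExistsError(f"output name collision: {target}")
            tifffile.imwrite(target, image.values)
            rows.append(dict(
                filename=name, kvp=float(kvp), replicate=r, seed=seed,
                noise=noise, aec_target=aec_target,
                photons_background=photons_background,
                background_mean=image.background_mean,
                gain_dn_per_photon=image.gain_dn_per_photon,
            ))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_manifest(out_dir) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / "manifest.tsv", sep="\t")
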