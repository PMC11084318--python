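"""Analytic cone-beam Beer-Lambert projection of phantoms.

A point source at the origin casts one ray per detector pixel (through the
pixel center) onto a flat detector perpendicular to the beam axis.  Because
all primitives are homogeneous, the line integral along a ray is an exact
finite sum

    integral mu dl  =  mu_slab * (L_slab - L_replaced) + sum_d mu_d * L_d

over closed-form chord lengths L, where disks embedded in a slab replace the
slab material.  Polychromatic intensity follows Beer's law summed over the
spectrum, ``I = sum_E W(E) exp(-integral mu(E) dl)``, with fluence weighting
``W = S(E)`` (photon counting) or energy-integrating weighting
``W = S(E) * E``.  Flat-field convention: no inverse-square falloff or
obliquity, so ``I0`` is the same for every pixel and air pixels read exactly
``I0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .materials import solution_mu
from .phantom import PhantomSpec, primitive_chords
from .spectra import Spectrum

__all__ = [
    "AcquisitionGeometry",
    "LineIntegralImage",
    "IntensityImage",
    "project_line_integrals",
    "project_polychromatic",
    "effective_line_integral",
    "PathLengthSet",
    "write_line_integral_tiff",
    "write_intensity_tiff",
    "read_image",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Cone-beam geometry: source at origin, detector plane at z = D2."""

    source_to_object: float  # D1, mm
    source_to_detector: float  # D2, mm
    pixel_pitch: float  # mm
    detector_shape: Tuple[int, int]  # (rows, cols)

    def __post_init__(self) -> None:
        if not 0 < self.source_to_object < self.source_to_detector:
            raise ValueError("require 0 < D1 < D2")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def magnification(self) -> float:
        """Nominal magnification of the object entrance plane."""
        return self.source_to_detector / self.source_to_object

    def pixel_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """Detector pixel center coordinates (x, y) in mm, row-major grids."""
        rows, cols = self.detector_shape
        x = (np.arange(cols) - (cols - 1) / 2.0) * self.pixel_pitch
        y = (np.arange(rows) - (rows - 1) / 2.0) * self.pixel_pitch
        return np.meshgrid(x, y)

    def detector_to_object_xy(self, x_det, y_det, z_obj: float):
        """Back-project detector coordinates to the plane z = z_obj."""
        s = z_obj / self.source_to_detector
        return x_det * s, y_det * s

    def object_to_detector_xy(self, x_obj, y_obj, z_obj: float):
        """Forward-project an object point to the detector plane."""
        s = self.source_to_detector / z_obj
        return x_obj * s, y_obj * s


# Geometries matching the two acquisition setups of the study.
def simulation_geometry(shape: Tuple[int, int] = (4000, 4000),
                        pitch: float = 0.1) -> AcquisitionGeometry:
    """D1 = 100 cm, D2 = 130 cm; default detector 4000x4000 at 0.1 mm."""
    return AcquisitionGeometry(1000.0, 1300.0, pitch, shape)


def radiograph_geometry(shape: Tuple[int, int] = (380, 1240),
                        pitch: float = 0.148) -> AcquisitionGeometry:
    """D1 = 100 cm, D2 = 110 cm; detector 1240x380 at 0.148 mm."""
    return AcquisitionGeometry(1000.0, 1100.0, pitch, shape)


@dataclass(frozen=True)
class LineIntegralImage:
    """Per-pixel values of integral mu dl (dimensionless)."""

    values: np.ndarray
    energy: float | str  # keV, or "effective" for -ln(I/I0) of a polychromatic image
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        if np.any(self.values < -1e-12):
            raise ValueError("line integrals must be non-negative")


@dataclass(frozen=True)
class IntensityImage:
    """Detector signal I with its flat-field reference I0 (scalar)."""

    values: np.ndarray
    i0: float
    geometry: AcquisitionGeometry
    spectrum_label: str = ""


class PathLengthSet:
    """Chord lengths (mm) of every primitive for each detector ray, cached.

    Materials are energy-independent geometry, so path lengths are computed
    once per (phantom, geometry) and reused across all spectrum energies.
    """

    def __init__(self, phantom: PhantomSpec, geometry: AcquisitionGeometry):
        self.phantom = phantom
        self.geometry = geometry
        rows, cols = geometry.detector_shape
        xg, yg = geometry.pixel_centers()
        directions = np.stack(
            [xg.ravel(), yg.ravel(),
             np.full(xg.size, geometry.source_to_detector)], axis=-1)
        origins = np.zeros(3)
        # aggregate chord lengths per distinct material to keep the energy
        # loop and the memory footprint independent of the primitive count
        terms: dict = {}

        def add(material, chords):
            key = id(material)
            if key not in terms:
                terms[key] = (material, np.zeros((rows, cols)))
            terms[key][1][:] += chords

        slab_total = np.zeros((rows, cols))
        disk_total = np.zeros((rows, cols))
        for s in phantom.slabs:
            chords = primitive_chords(origins, directions, s).reshape(rows, cols)
            slab_total += chords
            add(s.material, chords)
        for d in phantom.disks:
            chords = primitive_chords(origins, directions, d).reshape(rows, cols)
            disk_total += chords
            add(d.material, chords)
            host = phantom.embedding_slab(d)
            if host is not None:
                add(host.material, -chords)
        self.material_terms: List[Tuple[object, np.ndarray]] = list(terms.values())
        self.slab_mask = slab_total > 0
        self.disk_mask = disk_total > 0

    def line_integral(self, energy: float) -> np.ndarray:
        """Sum of mu * chord over materials at one energy (chords mm -> cm)."""
        out = np.zeros(self.geometry.detector_shape)
        for material, length in self.material_terms:
            out += solution_mu(material, energy) * (length / 10.0)
        return out


def project_line_integrals(phantom: PhantomSpec, geometry: AcquisitionGeometry,
                           energy: float,
                           paths: Optional[PathLengthSet] = None) -> LineIntegralImage:
    """Monoenergetic line-integral image of a phantom."""
    paths = paths or PathLengthSet(phantom, geometry)
    return LineIntegralImage(paths.line_integral(energy), float(energy), geometry)


def project_polychromatic(phantom: PhantomSpec, geometry: AcquisitionGeometry,
                          spectrum: Spectrum, weighting: str = "fluence",
                          paths: Optional[PathLengthSet] = None) -> IntensityImage:
    """Polychromatic intensity image, ``I = sum_E W(E) exp(-line integral)``.

    ``weighting="fluence"`` models a photon-counting detector (W = S);
    ``weighting="energy"`` an energy-integrating one (W = S * E).
    """
    if weighting not in ("fluence", "energy"):
        raise ValueError("weighting must be 'fluence' or 'energy'")
    paths = paths or PathLengthSet(phantom, geometry)
    active = spectrum.fluence > 0
    energies = spectrum.energies[active]
    if energies.size == 0:
        raise ValueError("spectrum has no positive-fluence bins")
    weights = spectrum.fluence[active].copy()
    if weighting == "energy":
        weights = weights * energies
    out = np.zeros(geometry.detector_shape)
    for e, w in zip(energies, weights):
        out += w * np.exp(-paths.line_integral(float(e)))
    return IntensityImage(out, i0=float(weights.sum()), geometry=geometry,
                          spectrum_label=spectrum.label)


def effective_line_integral(image: IntensityImage) -> LineIntegralImage:
    """Per-pixel ``-ln(I / I0)``; equals the monoenergetic line integral for
    a single-line spectrum."""
    if np.any(image.values <= 0):
        raise ValueError("intensity image contains non-positive pixels")
    vals = -np.log(image.values / image.i0)
    # clamp the tiny negative round-off in air pixels
    vals[np.abs(vals) < 1e-12] = 0.0
    return LineIntegralImage(vals, "effective", image.geometry)


def write_line_integral_tiff(image: LineIntegralImage, path) -> None:
    import tifffile

    tifffile.imwrite(path, image.values.astype(np.float32))


def write_intensity_tiff(image: IntensityImage, path) -> None:
    """16-bit TIFF, linearly scaled; the scale factor is stored in the
    ImageDescription tag as JSON."""
    import json

    import tifffile

    scale = 65535.0 / float(image.values.max())
    data = np.round(image.values * scale).astype(np.uint16)
    tifffile.imwrite(path, data,
                     description=json.dumps({"scale": scale, "i0": image.i0}))


def read_image(path) -> np.ndarray:
    """Read a TIFF/PNG image as a float array."""
    import tifffile

    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        return np.asarray(tifffile.imread(p), dtype=float)
    import imageio.v3 as iio

    return np.asarray(iio.imread(p), dtype=float)
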